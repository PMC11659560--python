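# hdcyto

End-to-end analysis of high-dimensional cytometry (HDC) data — conventional
flow, spectral flow, mass cytometry (CyTOF) and antibody-capture
(CITE-seq/Ab-seq) single-cell panels — for researchers who want to go from
exported FCS/CSV files to interpreted biology without stitching together half
a dozen packages. Everything operates on one container, the `CytoTable`,
which keeps raw, transformed and batch-corrected marker matrices in separate
slots, alongside annotations, embeddings, clusterings, trained models and a
provenance log.

## What it does

* **Ingestion** — FCS 3.0/3.1 or CSV exports plus a sample-metadata table;
  unique cell ids `<file>_<event index>`; optional seeded per-file
  subsampling.
* **Transforms** — autologicle (biexponential with per-marker estimation of
  the linearization width *W* from negative events), arcsinh with cofactor 5
  (the CyTOF convention), and CLR for antibody-capture counts:
  `yᵢ = ln((xᵢ+1) / gm(x+1))`.
* **Dimensionality reduction** — per-cell PCA and sample-level (pseudobulk)
  PCA with loading inspection, UMAP (with a retained model for out-of-sample
  projection), tSNE, diffusion maps.
* **Clustering** — PhenoGraph-style community detection (exact kNN graph,
  Jaccard edge weights `w(u,v) = |N(u)∩N(v)| / |N(u)∪N(v)|`, Louvain or
  Leiden) and FlowSOM-style SOM metaclustering cut to a fixed cluster count.
* **Batch alignment** — Harmony-style iterative soft k-means with a diversity
  penalty and per-cluster ridge removal of batch offsets, on expression or
  PCs, written to a *separate* corrected slot; mixing quantified with the
  Local Inverse Simpson's Index, `LISIᵢ = 1 / Σ_l p_{il}²` (1 = unmixed,
  #batches = perfectly mixed).
* **Pseudotime** — minimum spanning tree over cluster centroids, lineages as
  root→leaf paths, per-cell arc-length pseudotime, pseudotime-ordered
  expression matrices.
* **Group statistics** — per-sample frequency tables, confusion matrices,
  Welch t / Wilcoxon / Kruskal–Wallis / ANOVA / Friedman with Bonferroni
  correction and matched post-hoc tests, group-mean heatmap tables, Tukey
  box-plot statistics as data.
* **Reference projection** — retained UMAP + kNN label classifier (k = 5 on
  transformed expression) with per-marker AUC importance; projection QC by
  reference-vs-projected LISI.
* **Clinical classification** — elastic-net logistic per-cell model, sample
  score = mean cell probability, sample-level logistic on that score, a
  decision-tree surrogate for interpretation, and 100-permutation 80/20
  evaluation with balanced training and unbalanced testing.

## Worked example

Simulate a PBMC-like dataset (six samples, two groups) and run the core
pipeline from the shell:

```sh
hdcyto simulate --preset pbmc_like --out data --seed 3
hdcyto run pipeline.yaml
```

with `pipeline.yaml`:

```yaml
seed: 7
stages:
  - stage: ingest
    params: {meta: data/metadata.csv, data_dir: data, subsample: 800, out: arch}
  - stage: transform
    params: {archive: arch, method: arcsinh}
  - stage: dimred
    params: {archive: arch, method: pca}
  - stage: dimred
    params: {archive: arch, method: umap, ret_model: true}
  - stage: cluster
    params: {archive: arch, method: phenograph, k: 20}
  - stage: lisi
    params: {archive: arch, embedding: umap, label_var: group}
  - stage: diff
    params: {archive: arch, label_var: phenograph, group_var: group}
  - stage: inspect
    params: {archive: arch}
```

prints:

```
ingested 4800 cells from 6 files -> arch
arcsinh applied to 12 markers
pca done
umap done
phenograph: 6 clusters
mean LISI = 1.8688, median = 1.9225
 label test  statistic    p_raw    p_adj
     1    t -19.107783 0.000333 0.001998
     2    t  12.056188 0.002643 0.015856
     3    t   0.419455 0.696559 1.000000
     4    t   0.337100 0.753371 1.000000
     5    t   1.152037 0.315696 1.000000
     6    t   2.785430 0.056954 0.341726
integrity: OK (0 violations)
```

Reading the output: the six PhenoGraph clusters recover the six simulated
populations; the group LISI near 2 on the UMAP says the two experimental
groups overlap (cells mix freely, i.e. the groups differ in composition,
not in where cells sit); and the Welch t-tests on per-sample cluster
frequencies flag the two clusters whose abundance was shifted between groups
(Bonferroni-adjusted p = 0.002 and 0.016), while the other clusters stay at
p ≈ 1. The `inspect` stage verifies that every cell-indexed slot in the
archive is still aligned.

The same workflow is available as a library (`hdcyto.read_samples`,
`hdcyto.run_phenograph`, …); every operation takes and returns a
`CytoTable`.

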