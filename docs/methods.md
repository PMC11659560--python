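# Methods

This note documents the models, algorithms and numerical choices behind
`hdcyto`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## The container and its contracts

A `CytoTable` holds cell-indexed slots (raw/transformed/corrected expression,
annotation, embeddings, clusterings) that must share one cell-id ordering,
plus per-sample metadata in bijection with the annotation's sample ids.
Corrected data never overwrites originals: batch correction writes to
`expr_corrected` / `pca_corrected` and every downstream operation takes an
explicit slot argument, so corrected and original views coexist (this was a
genuinely open design point; coexistence was chosen because evaluating a
correction requires the uncorrected baseline). All joins are by cell id,
never positional. Subsetting carries expression values over bit-identically
— cytometry intensities are comparable across subsets, so no re-scaling is
applied — and drops trained models and embeddings, which refer to the full
dataset. Serialization is a single directory of delimited text tables plus a
JSON manifest (floats printed with 17 significant digits, so a round-trip is
value-exact); fitted models are pickled alongside for pipeline continuity.

## Ingestion

FCS 3.0/3.1 list-mode files with float events are read by a small built-in
parser (reader/writer pair; the writer emits float32, the FCS convention, so
write/read round-trips are exact to ~1e-7 relative). Values are taken as
stored: compensation/unmixing is assumed done upstream, and basic pre-gating
(debris, doublets, dead cells) is recommended before import. Stain names
($PnS) are preferred over detector names ($PnN), with a flag to flip.
Subsampling happens at ingest (before transformation), drawing
`min(subsample_n, events)` events per file without replacement from an
independent per-file stream derived from the global seed, preserving event
order.

## Transforms

**Autologicle.** The logicle scale is the inverse of the biexponential
`B(y) = a·e^{by} − c·e^{−dy} + f` with coefficients determined by the
top-of-scale value `T` (default 262144), decades `M` (4.5), extra negative
decades `A` (0) and linearization width `W`; the display coordinate is
normalized to [0, 1] over the `M + A` decades, so `B⁻¹(T) = 1` exactly and
data value 0 sits at `(A + W)/(M + A)`. Per marker, `W` is estimated from
the negative events as `W = max(0, (M − log10(T/|r|))/2)` with `r` the 5th
percentile of the negatives; fewer than 10 negative events falls back to
`W = 0.5`, and estimates above `M/2` are clamped with a warning (the
quantile and fallback follow common practice; the estimation is pooled
across files so intensities stay comparable, with per-file estimation left
out deliberately). The inverse is evaluated by vectorized bisection driven
to float64 resolution (~80 halvings), making the forward/inverse round-trip
accurate to ~1e-9 in data units over [−1000, T].

**Arcsinh.** `asinh(x/5)` by default — cofactor 5 is the mass-cytometry
convention; the cofactor is a parameter for fluorescence data where larger
values (100–150) are customary.

**CLR.** For antibody-capture counts, `yᵢ = ln((xᵢ+pc)/gm_j(x_j+pc))` per
cell with pseudocount 1; the per-cell margin is the default (each cell's
values sum to zero) with a per-marker option. Zero counts with a zero
pseudocount are an error.

All transforms are strictly monotone per marker (for CLR, holding the other
markers fixed), so rank order of raw intensities is preserved.

## Dimensionality reduction

Per-cell PCA centers (and optionally unit-scales) markers; scores, loadings
and explained variance are stored, with a deterministic sign convention (the
largest-|loading| marker of each component is made positive). Pseudobulk PCA
ordinates samples by their mean marker expression, unit-scaled by default
because samples are few and markers heterogeneous; an unscaled mode is
provided for the case where raw between-sample variance is the object of
interest. UMAP (defaults: 15 neighbors, min_dist 0.1, first 15 PCs when run
on PCA input) can retain its fitted transform for out-of-sample projection;
with a fixed seed and one thread the embedding is reproducible. tSNE
(perplexity 30, capped at (n−1)/3) has no out-of-sample transform. The
diffusion map uses a Gaussian kernel with the median pairwise distance as
bandwidth, row-normalizes to a transition matrix, and diagonalizes through
the symmetric conjugate; it is dense (O(n²)) and intended for at most a few
thousand cells — subsample first.

## Clustering

PhenoGraph-style clustering builds the exact Euclidean kNN graph (default
k = 30; larger k merges, smaller k splits), weights edges by the Jaccard
overlap of neighbor sets, and optimizes modularity with Louvain (Leiden
behind a flag — it optimizes a related but different objective and may
partition more finely). The seed fixes both graph tie-breaking and the
community sweep, so runs are reproducible; labels are integers 1..C ordered
by decreasing cluster size.

FlowSOM-style clustering trains a 10×10 online SOM (10 passes, learning rate
decaying linearly 0.05→0.01, Gaussian neighborhood shrinking linearly from
half the grid diagonal to one unit — the schedule is fixed here since only
the grid and cluster count are conventionally reported), hierarchically
clusters the codebook (average linkage, Euclidean — the customary choice)
and cuts to exactly the requested number of metaclusters; cells inherit
their best-matching unit's metacluster, and a metacluster that captures no
cells is flagged with a warning rather than an error.

Both methods honor marker include/exclude lists: excluded markers are
absent from the distance computations entirely.

## Batch alignment and LISI

The alignment iterates (a) soft k-means assignment with an entropy-style
diversity penalty — responsibilities are multiplied by
`((E_kb + 1)/(O_kb + 1))^θ`, where `O` and `E` are observed and expected
soft batch counts per cluster, so clusters over-representing a batch repel
further cells of that batch — and (b) per-cluster ridge-regularized linear
removal of batch offsets (intercept unpenalized, λ = 1), subtracted with
responsibility weights. Defaults: θ = 2, bandwidth σ = 0.1 on z-scored
data, K = min(100, n/30) soft clusters, at most 10 iterations or until
fewer than 1e-4 of hard assignments change. K trades bias against variance:
with very many clusters the per-cluster batch-offset estimates get noisy and
the correction jitters cells even without a batch effect; matching K to the
plausible number of populations keeps the no-op displacement below σ.
A single batch level is a warned no-op (corrected = original). Differential
expression on corrected intensities is possible but the corrected slot
should be used cautiously for that purpose — offsets estimated from the
batch structure can absorb or inflate genuine group differences.

LISI (local inverse Simpson's index) measures the effective number of label
categories around each cell: a Gaussian kernel over the 3·perplexity nearest
neighbors, bandwidth bisected until the weight entropy equals
log(perplexity) (tolerance 1e-5, ≤ 50 halvings; exact distance ties are
snapped to zero before the search so diverging bandwidths cannot amplify
float noise), then `LISI = 1/Σ_l p_l²`. Two equally sized, identically
distributed batches score close to 2 (slightly below, since the kernel is
finite); completely separated groups score 1. When comparing groups of
unequal size (reference vs projected data), the larger side is subsampled to
the smaller first — the inverse Simpson index of a 3:1 mixture is bounded
near 1.6 even under perfect mixing, which would misread as failure.

## Pseudotime

Trajectories are read from the minimum spanning tree over cluster centroids
in a chosen embedding. The root is either given or chosen as the MST vertex
minimizing total path length to all leaves; lineages are root→leaf paths,
optionally restricted to given end clusters. Per-cell pseudotime is the arc
length from the root to the cell's cluster centroid plus the cell's signed
projection onto that cluster's *incoming* segment, clamped at zero; root
cells project onto the mean outgoing direction of the root's MST neighbors
(also clamped). This local projection was chosen over orthogonal projection
onto the full centroid polyline because it depends only on the lineage
prefix up to the cell's own cluster: lineages sharing their first m clusters
assign identical pseudotime to cells of those clusters (exactly, not
approximately), which makes the per-cell mean over lineages well defined at
branch points. The cost is that a cell far off its cluster's local segment
is not snapped to the globally nearest point of the path — immaterial for
ordering-level claims, which is what the synthetic tests check. Pseudotime
is invariant to rigid rotation and translation of the embedding. Cells whose
cluster lies on no lineage carry NaN, not 0 — averaging in zeros would
invent early positions for unrelated cells. No principal-curve smoothing or
branch-significance testing is attempted.

## Group statistics

Abundance tables are per-sample label percentages (rows sum to 100; absent
labels are 0). The confusion matrix first computes the fraction of each
group's cells falling in each label — so unequal group sizes do not distort
composition — then renormalizes each label row to sum to 1 for
comparability across labels; this two-step reading of "fraction of samples
from the respective condition contributing to each cluster" is an
interpretation and is flagged as such. Frequency tests run per label on
per-sample frequencies: Welch's t (unequal variances — the reference
behavior of the common default) for two groups, Kruskal–Wallis for more,
with Wilcoxon/ANOVA/Friedman selectable and a paired mode; omnibus p values
are Bonferroni-corrected across labels (`p_adj = min(1, m·p)`), and >2-group
tests attach pairwise post-hoc tests of the same family (Kruskal–Wallis →
pairwise Wilcoxon, ANOVA → pairwise Welch t), Bonferroni-corrected within
label. Box-plot summaries are exported Tukey-style as data (median,
quartiles, whiskers at the most extreme points within 1.5·IQR, outliers
listed). A long-format export of counts and frequencies is provided for
external GLM-based differential-abundance frameworks, which are otherwise
out of scope.

## Reference projection and label transfer

A reference bundles the retained UMAP transform, a Euclidean kNN classifier
(k = 5, chosen as a robust small default and exposed as a flag) fit on
transformed marker expression — not PCs, so a query needs only the shared
panel — per-marker importance, and the recorded transform stack. Because
the reference UMAP is usually fit on PCA scores, the model also captures the
PCA rotation (loadings, centering, optional scaling) and replays it on query
expression before the UMAP transform. Importance is the univariate
one-vs-rest ROC-AUC separability `mean_c 2·|AUC_c − 0.5|` in [0, 1] — kNN
itself has no native importance, and this filter-style score matches what
generic training frameworks report for it. Projection predicts by majority
vote of the k nearest reference cells with ties broken by the smallest
summed neighbor distance (deterministic), and reports the vote fraction as
confidence. Queries missing training markers, or carrying a different
recorded transform stack, are rejected. Reference and query must come from
the same experimental design; no cross-panel projection is attempted.

## Clinical sample classification

The two-stage classifier scores each cell's association with the outcome
and averages the signal per sample: an elastic-net logistic model (saga,
l1_ratio 0.5, fixed C = 1; a cross-validated option selects C over a small
grid — fixed strength is the default because the evaluation protocol
retrains the model on every one of 100 permutations, where per-permutation
CV adds cost without changing the sample-level calls) is fit on all
training cells with the sample-level outcome as each cell's response; the
per-sample mean of the cell probabilities is the sample score; a logistic
model on that scalar gives the sample probability, thresholded at 0.5. A
depth-3 decision tree fit to the cell probabilities serves as an
interpretable surrogate of the per-cell rules, and per-marker importance is
the magnitude of the standardized cell-model coefficient. With balancing
on, majority-class training samples are down-sampled to the minority count
(seeded). Evaluation mirrors the clinical benchmarking protocol: the
*samples* are split 80/20, only the training side is balanced, the test
side keeps its natural imbalance, and accuracy/sensitivity/specificity
(disease = positive; by default the minority class) are reported per
permutation over 100 randomized splits.

## Synthetic data

The generator draws Gaussian populations with marker-signature means on the
transformed scale (a raw-scale mode emits `5·sinh(values)` so the arcsinh
stack can be exercised end to end), multinomial population counts per
sample, per-batch shift/scale effects, per-class population-frequency
multipliers and mean shifts, and trajectory chains in which designated
gradient markers are linear in a latent progression `t` recorded as
`true_pseudotime`. Ground truth lives only in the annotation. Frozen
fixtures: `pbmc_like` (6 populations, 12 markers, 6 samples × 2000 cells,
two groups with composition shifts), `batch_shift` (two batches, +2 offset
on one marker), `two_class_outcome` (20 samples × 2000 cells; a "blast"
population at exactly 40% in disease vs 5% in control, the strong-effect
regime), `linear_trajectory` and `branched_trajectory` (continuum designs —
the spatial axis is itself gradient-driven, as in a real differentiation
continuum; discrete blobs would decouple within-cluster position from
progression and no ordering method could recover it). The
`separated_mixture_design` helper builds equal-frequency mixtures from
deterministic binary marker signatures, re-drawn from a fixed internal
stream until every pairwise centroid distance exceeds the requested number
of pooled SDs; the caller's seed drives only the cell draws.

What the generator does **not** emulate: spillover/spectral overlap,
heavy-tailed or zero-inflated intensity distributions, doublets and debris,
acquisition drift within a file, or cross-panel differences. Tests passing
on these simulations therefore validate the algorithms' contracts and
recovery behavior under clean conditions, not robustness to every artifact
of real cytometry data.

## Problem sizes and evaluation

The label-transfer evaluations use 20,000 cells over 20 markers (5
populations at ≥ 6 pooled SDs separation; 15 populations at ≥ 4), an 80/20
cell split, and report held-out accuracy; the clinical classifier is
trained on 5+5 samples of 2,000 cells and evaluated on 10 disjoint samples.
Unit tests run the same machinery at a few hundred to a few thousand cells,
the regime where the checked properties (exact recovery, analytic values,
invariances) are sharpest. Statistical calibration (Welch type-I error) uses
1,000 null simulations of 2 groups × 5 samples.

## Known limitations

* All data are held in memory; subsample at ingest for very large studies.
* The diffusion map and the exact kNN graph are dense/quadratic at the
  extremes; PhenoGraph via sklearn's neighbor search handles tens of
  thousands of cells, the diffusion map thousands.
* Batch alignment assumes roughly shared population structure across
  batches and approximately linear (offset-like) batch effects within
  clusters; quantile-normalization-style correction is not implemented.
* Cell-type labels still require manual cluster annotation; no automated
  annotation against a marker database is attempted.
* FlowJo workspace/gating-hierarchy import is out of scope; files are
  expected pre-gated and compensated.
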