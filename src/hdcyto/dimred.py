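"""Dimensionality reduction: PCA (per-cell and pseudobulk), UMAP with a
retained out-of-sample model, tSNE and diffusion maps.

Every operation accepts either the original or the batch-corrected input slot
and records which one was used; corrected results live in their own named
reductions (``pca_corrected``, ``umap_corrected``, ...) so that original and
corrected views coexist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .core import CytoTable, Reduction

__all__ = [
    "PseudobulkPCA",
    "run_pca",
    "run_pseudobulk_pca",
    "run_umap",
    "run_tsne",
    "run_dm",
    "pca_loadings",
]


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Deterministic sign convention: the largest-|loading| marker of each PC
    is made positive (in place)."""
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0


@dataclass
class PseudobulkPCA:
    sample_means: pd.DataFrame  # samples x markers
    coords: pd.DataFrame  # samples x PCs
    loadings: pd.DataFrame  # markers x PCs
    explained_variance: np.ndarray


def _input_matrix(
    table: CytoTable, input_slot: str, markers: list[str] | None, n_pc: int | None
) -> np.ndarray:
    mat = table.get_matrix(input_slot)
    if input_slot in ("expr", "expr_corrected") and markers is not None:
        mat = mat[markers]
    x = mat.to_numpy(dtype=float)
    if input_slot.startswith("pca"):
        # default to the first 15 PCs when the caller does not say otherwise
        k = n_pc if n_pc is not None else min(15, x.shape[1])
        x = x[:, :k]
    return x


def run_pca(
    table: CytoTable,
    markers: list[str] | None = None,
    n_pc: int | None = None,
    scale: bool = False,
    input_slot: str = "expr",
) -> CytoTable:
    """Per-cell PCA on the chosen expression slot (centering only by default).

    Scores, loadings and the per-PC explained variance are stored under
    ``pca`` (or ``pca_corrected`` for corrected input).
    """
    if input_slot not in ("expr", "expr_corrected"):
        raise ValueError("run_pca input_slot must be 'expr' or 'expr_corrected'")
    mat = table.get_matrix(input_slot)
    markers = markers or list(mat.columns)
    x = mat[markers].to_numpy(dtype=float)
    n_pc = n_pc or min(len(markers), x.shape[0])
    if n_pc > len(markers):
        raise ValueError(f"n_pc={n_pc} exceeds marker count {len(markers)}")
    if scale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [markers[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant markers cannot be unit-scaled: {bad}")
        x = (x - x.mean(axis=0)) / sd
    pca = PCA(n_components=n_pc, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T.copy()
    _fix_signs(loadings, scores)

    name = "pca" if input_slot == "expr" else "pca_corrected"
    cols = [f"PC{i + 1}" for i in range(n_pc)]
    out = table.copy()
    out.reductions[name] = Reduction(
        coords=pd.DataFrame(scores, index=table.cell_ids, columns=cols),
        kind="pca",
        input_slot=input_slot,
        corrected=input_slot == "expr_corrected",
        extras={
            "loadings": pd.DataFrame(loadings, index=markers, columns=cols),
            "explained_variance": pca.explained_variance_,
            "scaled": scale,
        },
    )
    out.log_event("run_pca", n_pc=n_pc, scale=scale, input_slot=input_slot,
                  markers=markers)
    return out


def run_pseudobulk_pca(
    table: CytoTable, group_by: str = "sample_id", scale: bool = True
) -> PseudobulkPCA:
    """Sample-level ordination: mean marker expression per sample, then PCA.

    Markers are unit-scaled by default (samples are few and markers
    heterogeneous); ``scale=False`` keeps raw between-sample variances, which
    lets a single strongly shifted marker dominate PC1.  Needs at least three
    samples.
    """
    if table.expr is None:
        raise ValueError("expr slot is empty: transform first")
    means = table.expr.groupby(table.anno[group_by]).mean()
    if len(means) < 3:
        raise ValueError(f"pseudobulk PCA needs >= 3 samples, got {len(means)}")
    x = means.to_numpy(dtype=float)
    centered = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0  # constant markers contribute nothing
        z = centered / sd
    else:
        z = centered
    n_pc = min(z.shape)
    pca = PCA(n_components=n_pc, svd_solver="full")
    with np.errstate(invalid="ignore"):  # zero total variance is a valid input
        scores = pca.fit_transform(z)
    loadings = pca.components_.T.copy()
    _fix_signs(loadings, scores)
    cols = [f"PC{i + 1}" for i in range(n_pc)]
    return PseudobulkPCA(
        sample_means=means,
        coords=pd.DataFrame(scores, index=means.index, columns=cols),
        loadings=pd.DataFrame(loadings, index=means.columns, columns=cols),
        explained_variance=pca.explained_variance_,
    )


def run_umap(
    table: CytoTable,
    input_slot: str = "pca",
    n_pc: int | None = None,
    seed: int = 0,
    ret_model: bool = False,
    n_threads: int = 1,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    markers: list[str] | None = None,
) -> CytoTable:
    """2-D UMAP of the chosen slot; with ``ret_model`` the fitted reducer is
    retained in ``models`` for out-of-sample projection of new data.

    With a fixed seed and a single thread the embedding is identical across
    runs.
    """
    import umap  # deferred: slow import

    x = _input_matrix(table, input_slot, markers, n_pc)
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
        n_jobs=n_threads,
    )
    coords = reducer.fit_transform(x)
    corrected = input_slot.endswith("corrected")
    name = "umap_corrected" if corrected else "umap"
    out = table.copy()
    out.reductions[name] = Reduction(
        coords=pd.DataFrame(coords, index=table.cell_ids, columns=["UMAP1", "UMAP2"]),
        kind="umap",
        input_slot=input_slot,
        corrected=corrected,
        seed=seed,
        extras={"n_input_dims": x.shape[1]},
    )
    if ret_model:
        out.models[name] = reducer
    out.log_event(
        "run_umap", seed=seed, input_slot=input_slot, n_pc=n_pc,
        n_neighbors=n_neighbors, min_dist=min_dist, ret_model=ret_model,
    )
    return out


def run_tsne(
    table: CytoTable,
    input_slot: str = "pca",
    seed: int = 0,
    perplexity: float = 30.0,
    n_pc: int | None = None,
    markers: list[str] | None = None,
) -> CytoTable:
    """2-D tSNE of the chosen slot (no out-of-sample model)."""
    x = _input_matrix(table, input_slot, markers, n_pc)
    perplexity = min(perplexity, (x.shape[0] - 1) / 3.0)
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    )
    coords = tsne.fit_transform(x)
    corrected = input_slot.endswith("corrected")
    name = "tsne_corrected" if corrected else "tsne"
    out = table.copy()
    out.reductions[name] = Reduction(
        coords=pd.DataFrame(coords, index=table.cell_ids, columns=["tSNE1", "tSNE2"]),
        kind="tsne",
        input_slot=input_slot,
        corrected=corrected,
        seed=seed,
        extras={"perplexity": perplexity},
    )
    out.log_event("run_tsne", seed=seed, input_slot=input_slot, perplexity=perplexity)
    return out


def diffusion_map(
    x: np.ndarray, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diffusion map of a point set.

    Gaussian kernel with the median pairwise distance as bandwidth; the
    row-normalized transition matrix is diagonalized through its symmetric
    conjugate.  Returns (components, eigenvalues, transition_row_sums).
    """
    n = x.shape[0]
    if n_components >= n:
        raise ValueError("n_components must be < number of cells")
    d = squareform(pdist(x))
    sigma = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    K = np.exp(-(d**2) / (2.0 * sigma**2))
    deg = K.sum(axis=1)
    P = K / deg[:, None]
    s = 1.0 / np.sqrt(deg)
    S = K * s[:, None] * s[None, :]
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs * s[:, None]
    # skip the trivial constant component
    comps = psi[:, 1 : n_components + 1] * evals[1 : n_components + 1]
    return comps, evals, P.sum(axis=1)


def run_dm(
    table: CytoTable,
    input_slot: str = "pca",
    n_components: int = 3,
    n_pc: int | None = None,
    markers: list[str] | None = None,
) -> CytoTable:
    """Diffusion-map coordinates of the chosen slot (dense; intended for
    datasets of at most a few thousand cells, subsample first otherwise)."""
    x = _input_matrix(table, input_slot, markers, n_pc)
    comps, evals, rowsums = diffusion_map(x, n_components=n_components)
    corrected = input_slot.endswith("corrected")
    name = "dm_corrected" if corrected else "dm"
    out = table.copy()
    out.reductions[name] = Reduction(
        coords=pd.DataFrame(
            comps, index=table.cell_ids,
            columns=[f"DC{i + 1}" for i in range(n_components)],
        ),
        kind="dm",
        input_slot=input_slot,
        corrected=corrected,
        extras={"eigenvalues": evals[: n_components + 1], "rowsum_max_dev": float(np.max(np.abs(rowsums - 1.0)))},
    )
    out.log_event("run_dm", input_slot=input_slot, n_components=n_components)
    return out


def pca_loadings(table: CytoTable, pc: str | int, name: str = "pca") -> pd.DataFrame:
    """Markers ranked by signed loading on one principal component."""
    if name not in table.reductions:
        raise ValueError(f"no reduction named {name!r}: run PCA first")
    loadings: pd.DataFrame = table.reductions[name].extras["loadings"]
    col = f"PC{pc}" if isinstance(pc, int) else pc
    if col not in loadings.columns:
        raise ValueError(f"unknown principal component {col!r}")
    out = loadings[[col]].rename(columns={col: "loading"})
    return out.sort_values("loading", ascending=False)
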