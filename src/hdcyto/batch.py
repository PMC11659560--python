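"""Batch alignment and mixing diagnostics.

``harmonize`` removes batch-specific offsets with an iterative soft-k-means
scheme (diversity-penalized cluster assignment followed by per-cluster
ridge-regularized removal of batch offsets).  Corrected values are written to
a *separate* slot (``expr_corrected`` or ``pca_corrected``); the originals
are never touched, so correction quality can always be compared against the
uncorrected data.

``compute_lisi`` is the Local Inverse Simpson's Index: the effective number
of label categories in each cell's neighborhood.  1 means completely unmixed;
a value equal to the number of batches means perfect mixing (so two equally
sized, identically distributed batches score close to 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .core import CytoTable, Reduction

__all__ = ["HarmonyParams", "LisiResult", "harmonize", "compute_lisi", "lisi_per_cell"]


@dataclass
class HarmonyParams:
    batch_var: str = "batch"
    on: str = "pca"  # or "expr"
    theta: float = 2.0
    n_soft_clusters: int | None = None  # default min(100, n // 30)
    sigma: float = 0.1
    ridge_lambda: float = 1.0
    max_iter: int = 10
    tol: float = 1e-4
    seed: int = 0

    def validate(self) -> None:
        if self.theta < 0 or self.sigma <= 0 or self.max_iter < 1:
            raise ValueError("require theta >= 0, sigma > 0, max_iter >= 1")
        if self.on not in ("pca", "expr"):
            raise ValueError("on must be 'pca' or 'expr'")


@dataclass
class LisiResult:
    per_cell: pd.Series
    label_var: str
    perplexity: float
    mean: float
    median: float


def _soft_kmeans_correct(
    z: np.ndarray, batches: np.ndarray, params: HarmonyParams
) -> np.ndarray:
    """One full run of the diversity-penalized correction on z-scored data."""
    n, d = z.shape
    batch_levels, batch_idx = np.unique(batches, return_inverse=True)
    n_b = batch_levels.size
    onehot = np.zeros((n, n_b))
    onehot[np.arange(n), batch_idx] = 1.0
    frac_b = onehot.mean(axis=0)  # dataset-wide batch proportions

    K = params.n_soft_clusters or max(2, min(100, n // 30))
    km = KMeans(n_clusters=K, n_init=1, random_state=params.seed).fit(z)
    centers = km.cluster_centers_

    from scipy.spatial.distance import cdist

    phi = np.hstack([np.ones((n, 1)), onehot])
    z_corr = z.copy()
    prev_assign = None
    for _ in range(params.max_iter):
        d2 = cdist(z_corr, centers, metric="sqeuclidean")
        logits = -d2 / params.sigma
        R = np.exp(logits - logits.max(axis=1, keepdims=True))
        R /= R.sum(axis=1, keepdims=True)
        O_kb = R.T @ onehot  # observed soft counts per cluster x batch
        E_kb = R.sum(axis=0)[:, None] * frac_b[None, :]
        penalty = np.power((E_kb + 1.0) / (O_kb + 1.0), params.theta)
        R = R * penalty[:, batch_idx].T
        R /= R.sum(axis=1, keepdims=True)

        assign = R.argmax(axis=1)
        # per-cluster ridge removal of batch offsets
        z_corr = z.copy()
        for k in range(K):
            r = R[:, k]
            wphi = phi * r[:, None]
            A = phi.T @ wphi
            A[1:, 1:] += params.ridge_lambda * np.eye(n_b)
            B = wphi.T @ z
            W = np.linalg.solve(A + 1e-12 * np.eye(n_b + 1), B)
            z_corr -= r[:, None] * (onehot @ W[1:, :])
        centers = (R.T @ z_corr) / np.maximum(R.sum(axis=0)[:, None], 1e-12)

        if prev_assign is not None:
            changed = np.mean(assign != prev_assign)
            if changed < params.tol:
                break
        prev_assign = assign
    return z_corr


def harmonize(table: CytoTable, params: HarmonyParams | None = None) -> CytoTable:
    """Batch-align expression values or PC scores.

    With a single batch level nothing can be corrected: a warning is emitted
    and the corrected slot is an exact copy of the original.
    """
    params = params or HarmonyParams()
    params.validate()
    if params.batch_var not in table.anno.columns:
        raise ValueError(f"batch variable {params.batch_var!r} not in anno")
    batches = table.anno[params.batch_var].to_numpy()

    src = table.get_matrix("expr" if params.on == "expr" else "pca")
    x = src.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")

    out = table.copy()
    if np.unique(batches).size < 2:
        warnings.warn("single batch level: corrected output equals input", stacklevel=2)
        corrected = src.copy()
    else:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        z = (x - mu) / sd
        z_corr = _soft_kmeans_correct(z, batches, params)
        corrected = pd.DataFrame(
            z_corr * sd + mu, index=src.index, columns=src.columns
        )

    if params.on == "expr":
        out.expr_corrected = corrected
    else:
        red = table.reductions["pca"]
        out.reductions["pca_corrected"] = Reduction(
            coords=corrected,
            kind="pca",
            input_slot="pca",
            corrected=True,
            seed=params.seed,
            extras={"harmonized": True},
        )
    out.log_event(
        "harmonize", seed=params.seed, on=params.on, batch_var=params.batch_var,
        theta=params.theta, sigma=params.sigma, max_iter=params.max_iter,
    )
    return out


def lisi_per_cell(
    coords: np.ndarray, labels: np.ndarray, perplexity: float = 30.0
) -> np.ndarray:
    """LISI for each row of ``coords``.

    Gaussian kernel over the 3*perplexity nearest neighbors with the
    bandwidth bisected until the neighbor-weight entropy equals
    log(perplexity) (tolerance 1e-5, at most 50 halvings); the index is the
    inverse Simpson concentration of the label mix under those weights.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    n = coords.shape[0]
    levels, lab_idx = np.unique(labels, return_inverse=True)
    if levels.size == 1:
        return np.ones(n)
    k = int(min(3 * perplexity, n - 1))
    if n < 3 * perplexity:
        warnings.warn(
            f"fewer than 3*perplexity={int(3 * perplexity)} cells; "
            "LISI estimates will be coarse",
            stacklevel=2,
        )
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    dist, idx = dist[:, 1:], idx[:, 1:]
    d2 = dist**2
    target = np.log(perplexity)

    out = np.empty(n)
    for i in range(n):
        lo, hi = 0.0, np.inf
        beta = 1.0
        row = d2[i] - d2[i].min()
        # exact distance ties carry float noise that diverging beta would
        # amplify into spurious weight differences
        row[row < 1e-12 * (d2[i].max() + 1e-300)] = 0.0
        for _ in range(50):
            w = np.exp(-beta * row)
            sw = w.sum()
            p = w / sw
            h = -np.sum(p * np.log(np.maximum(p, 1e-300)))
            if abs(h - target) < 1e-5:
                break
            if h > target:  # too flat -> sharpen
                lo = beta
                beta = beta * 2.0 if np.isinf(hi) else 0.5 * (lo + hi)
            else:
                hi = beta
                beta = 0.5 * (lo + hi)
        probs = np.bincount(lab_idx[idx[i]], weights=p, minlength=levels.size)
        out[i] = 1.0 / np.sum(probs**2)
    return out


def compute_lisi(
    coords: np.ndarray | pd.DataFrame,
    labels: np.ndarray | pd.Series,
    perplexity: float = 30.0,
    label_var: str = "batch",
) -> LisiResult:
    """LISI summary over all cells (see :func:`lisi_per_cell`)."""
    index = coords.index if isinstance(coords, pd.DataFrame) else None
    vals = lisi_per_cell(
        np.asarray(coords, dtype=float), np.asarray(labels), perplexity
    )
    ser = pd.Series(vals, index=index, name="lisi")
    return LisiResult(
        per_cell=ser,
        label_var=label_var,
        perplexity=perplexity,
        mean=float(ser.mean()),
        median=float(ser.median()),
    )
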