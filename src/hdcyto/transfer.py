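"""Annotated-reference training, out-of-sample projection and label transfer.

A :class:`ReferenceModel` bundles the retained UMAP transform, a kNN label
classifier fit on transformed marker expression (not PCs, so projection only
needs the shared panel), a per-marker importance score, and the provenance
needed to refuse mismatched queries.  New samples are embedded into the
reference UMAP, labeled by majority vote of the k nearest reference cells,
and the projection is quality-controlled with LISI between reference and
projected cells (≈2 for a well-mixed projection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import NearestNeighbors

from .batch import LisiResult, compute_lisi
from .cluster import _get_labels
from .core import CytoTable

__all__ = ["ReferenceModel", "train_reference", "project", "evaluate_projection",
           "marker_importance"]


@dataclass
class ReferenceModel:
    umap_model: object
    knn_k: int
    training_markers: list[str]
    label_var: str
    class_levels: list
    importance: pd.Series  # per training marker, in [0, 1]
    training_accuracy: float
    seed: int
    transform_ops: list[str] = field(default_factory=list)
    # how to rebuild the UMAP input from query expression (the reference
    # embedding is usually computed on PCA scores, queries arrive as markers)
    umap_input: str = "expr"
    pca_loadings: pd.DataFrame | None = None
    pca_center: np.ndarray | None = None
    pca_sd: np.ndarray | None = None
    umap_n_dims: int | None = None
    _train_x: np.ndarray | None = None
    _train_y: np.ndarray | None = None
    _nn: NearestNeighbors | None = None

    def umap_input_matrix(self, expr: pd.DataFrame) -> np.ndarray:
        """Map query expression to the space the retained UMAP was fit on."""
        if self.umap_input.startswith("pca"):
            pca_markers = list(self.pca_loadings.index)
            x = expr[pca_markers].to_numpy(dtype=float) - self.pca_center
            if self.pca_sd is not None:
                x = x / self.pca_sd
            scores = x @ self.pca_loadings.to_numpy()
            return scores[:, : self.umap_n_dims]
        return expr[self.training_markers].to_numpy(dtype=float)


def marker_importance(x: np.ndarray, y: np.ndarray, markers: list[str]) -> pd.Series:
    """Univariate one-vs-rest AUC separability per marker, scaled to [0, 1].

    For each class the marker's ROC AUC against the rest is folded to
    ``2*|AUC - 0.5|``; the score is the mean over classes.  A marker with an
    identical distribution in every class scores ~0.
    """
    classes = np.unique(y)
    scores = np.zeros(len(markers))
    for j in range(len(markers)):
        aucs = []
        for c in classes:
            aucs.append(abs(roc_auc_score(y == c, x[:, j]) - 0.5) * 2.0)
        scores[j] = float(np.mean(aucs))
    return pd.Series(scores, index=markers, name="importance")


def _knn_predict(
    nn: NearestNeighbors, train_y: np.ndarray, x: np.ndarray, k: int,
    class_levels: list,
) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote over the k nearest training cells.

    Ties are broken by the smallest summed neighbor distance, which makes
    prediction deterministic given (model, input).  Returns (labels,
    vote-fraction confidence in [1/k, 1]).
    """
    dist, idx = nn.kneighbors(x, n_neighbors=k)
    votes = train_y[idx]  # (n, k)
    pred = np.empty(x.shape[0], dtype=object)
    conf = np.empty(x.shape[0])
    for i in range(x.shape[0]):
        vals, counts = np.unique(votes[i], return_counts=True)
        top = counts.max()
        tied = vals[counts == top]
        if tied.size == 1:
            pred[i] = tied[0]
        else:
            sums = {
                v: dist[i][votes[i] == v].sum() for v in tied
            }
            pred[i] = min(sums, key=lambda v: (sums[v], str(v)))
        conf[i] = top / k
    return pred, conf


def train_reference(
    table: CytoTable,
    label_var: str,
    knn_k: int = 5,
    holdout_frac: float = 0.2,
    seed: int = 0,
    markers: list[str] | None = None,
) -> ReferenceModel:
    """Fit the reference: kNN label classifier + retained UMAP + importances.

    The classifier is Euclidean kNN on transformed expression, fit on a
    random (1 - holdout_frac) of cells; accuracy on the held-out fraction is
    reported.  Requires a UMAP trained with a retained model.
    """
    if "umap" not in table.models:
        raise ValueError("no retained UMAP model: run_umap(..., ret_model=True) first")
    if table.expr is None:
        raise ValueError("expr slot is empty: transform first")
    labels = _get_labels(table, label_var)
    markers = markers or table.markers
    x = table.expr[markers].to_numpy(dtype=float)
    y = labels.to_numpy()

    counts = pd.Series(y).value_counts()
    small = counts[counts < knn_k]
    if len(small):
        warnings.warn(
            f"labels with fewer than k={knn_k} cells: {list(small.index)}",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    n = x.shape[0]
    perm = rng.permutation(n)
    n_hold = int(round(holdout_frac * n))
    hold, train = perm[:n_hold], perm[n_hold:]

    nn = NearestNeighbors(n_neighbors=knn_k).fit(x[train])
    class_levels = sorted(np.unique(y), key=str)
    if n_hold:
        pred, _ = _knn_predict(nn, y[train], x[hold], knn_k, class_levels)
        acc = float(np.mean(pred == y[hold]))
    else:
        acc = float("nan")

    # refit on all cells so the deployed model uses every annotated cell
    nn_full = NearestNeighbors(n_neighbors=knn_k).fit(x)
    transform_ops = [r["operation"] for r in table.log
                     if r["operation"] in ("autologicle", "arcsinh_transform", "clr_transform")]

    umap_red = table.reductions.get("umap")
    umap_input = umap_red.input_slot if umap_red is not None else "expr"
    pca_load = pca_center = pca_sd = None
    umap_n_dims = umap_red.extras.get("n_input_dims") if umap_red is not None else None
    if umap_input.startswith("pca"):
        pca_red = table.reductions[umap_input]
        pca_load = pca_red.extras["loadings"]
        src = table.expr[list(pca_load.index)].to_numpy(dtype=float)
        pca_center = src.mean(axis=0)
        if pca_red.extras.get("scaled"):
            pca_sd = src.std(axis=0, ddof=1)
    return ReferenceModel(
        umap_model=table.models["umap"],
        knn_k=knn_k,
        training_markers=list(markers),
        label_var=label_var,
        class_levels=class_levels,
        importance=marker_importance(x, y, list(markers)),
        training_accuracy=acc,
        seed=seed,
        transform_ops=transform_ops,
        umap_input=umap_input,
        pca_loadings=pca_load,
        pca_center=pca_center,
        pca_sd=pca_sd,
        umap_n_dims=umap_n_dims,
        _train_x=x,
        _train_y=y,
        _nn=nn_full,
    )


def project(new_table: CytoTable, model: ReferenceModel) -> CytoTable:
    """Embed new cells into the reference UMAP and transfer labels.

    The query must carry every training marker with the same transform stack
    applied (checked against recorded provenance).  Adds ``predicted_label``
    and ``prediction_confidence`` to the annotation and a ``umap_projected``
    reduction.
    """
    if new_table.expr is None:
        raise ValueError("expr slot is empty: apply the reference's transform first")
    missing = [m for m in model.training_markers if m not in new_table.expr.columns]
    if missing:
        raise ValueError(f"markers required by the reference are missing: {missing}")
    query_ops = [r["operation"] for r in new_table.log
                 if r["operation"] in ("autologicle", "arcsinh_transform", "clr_transform")]
    if query_ops != model.transform_ops:
        raise ValueError(
            f"transform mismatch: reference used {model.transform_ops}, "
            f"query used {query_ops}"
        )

    x = new_table.expr[model.training_markers].to_numpy(dtype=float)
    coords = model.umap_model.transform(model.umap_input_matrix(new_table.expr))
    pred, conf = _knn_predict(model._nn, model._train_y, x, model.knn_k,
                              model.class_levels)

    out = new_table.copy()
    from .core import Reduction

    out.reductions["umap_projected"] = Reduction(
        coords=pd.DataFrame(coords, index=new_table.cell_ids,
                            columns=["UMAP1", "UMAP2"]),
        kind="umap",
        input_slot="expr",
        corrected=False,
        seed=model.seed,
        extras={"projected": True},
    )
    out.anno["predicted_label"] = pred
    out.anno["prediction_confidence"] = conf
    out.log_event("project", k=model.knn_k, label_var=model.label_var)
    return out


def evaluate_projection(
    reference_table: CytoTable,
    projected_table: CytoTable,
    label_var: str | None = None,
    reference_embedding: str = "umap",
    projected_embedding: str = "umap_projected",
    perplexity: float = 30.0,
    equalize: bool = True,
    seed: int = 0,
) -> tuple[LisiResult, pd.DataFrame | None]:
    """LISI between reference and projected cells in the shared embedding.

    Values near 2 mean the projected cells interleave with the reference;
    near 1 means they land apart.  Because the inverse Simpson index of two
    unequal groups is bounded below 2 even under perfect mixing, the larger
    side is subsampled to the smaller (seeded) before scoring unless
    ``equalize=False``.  With ``label_var`` a per-label breakdown is added
    (reference labels vs predicted labels of the projection).
    """
    ref = reference_table.get_matrix(reference_embedding)
    proj = projected_table.get_matrix(projected_embedding)
    if list(ref.columns) != list(proj.columns):
        raise ValueError("embeddings are not comparable (different coordinates)")
    ref_xy, proj_xy = ref.to_numpy(float), proj.to_numpy(float)
    ref_keep = np.arange(len(ref_xy))
    proj_keep = np.arange(len(proj_xy))
    if equalize and len(ref_xy) != len(proj_xy):
        rng = np.random.default_rng(seed)
        n = min(len(ref_xy), len(proj_xy))
        if len(ref_xy) > n:
            ref_keep = np.sort(rng.choice(len(ref_xy), n, replace=False))
        else:
            proj_keep = np.sort(rng.choice(len(proj_xy), n, replace=False))
    ref_xy, proj_xy = ref_xy[ref_keep], proj_xy[proj_keep]
    coords = np.vstack([ref_xy, proj_xy])
    origin = np.array(["reference"] * len(ref_xy) + ["projected"] * len(proj_xy))
    overall = compute_lisi(coords, origin, perplexity=perplexity, label_var="origin")

    per_label = None
    if label_var is not None:
        ref_labels = _get_labels(reference_table, label_var).to_numpy()[ref_keep]
        proj_labels = projected_table.anno["predicted_label"].to_numpy()[proj_keep]
        all_labels = np.concatenate([ref_labels, proj_labels])
        rows = []
        for lab in sorted(pd.unique(all_labels), key=str):
            sel = all_labels == lab
            if np.unique(origin[sel]).size < 2:
                rows.append({"label": lab, "mean_lisi": 1.0, "n_cells": int(sel.sum())})
                continue
            res = compute_lisi(coords[sel], origin[sel], perplexity=perplexity)
            rows.append({"label": lab, "mean_lisi": res.mean, "n_cells": int(sel.sum())})
        per_label = pd.DataFrame(rows).set_index("label")
    return overall, per_label
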