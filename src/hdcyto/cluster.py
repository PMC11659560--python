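"""Clustering: kNN-graph community detection (PhenoGraph-style) and
self-organizing-map metaclustering (FlowSOM-style), plus cluster summaries
and manual annotation.

Both algorithms honor marker include/exclude: excluded markers play no part
in the distance computations.  Cluster labels are integers 1..C, relabeled by
decreasing cluster size so label 1 is always the largest cluster.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.neighbors import NearestNeighbors

from .core import CytoTable

__all__ = [
    "ClusterParams",
    "run_phenograph",
    "run_flowsom",
    "cluster_marker_summary",
    "annotate_clusters",
    "knn_jaccard_graph",
    "train_som",
]


@dataclass
class ClusterParams:
    method: str
    k: int = 30
    grid_x: int = 10
    grid_y: int = 10
    n_metaclusters: int | None = None
    input_slot: str = "pca"
    markers_used: list[str] | None = None
    seed: int = 0
    extras: dict = field(default_factory=dict)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Map community labels to 1..C by decreasing size (ties by old label)."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    mapping = {old: i + 1 for i, old in enumerate(order)}
    return np.array([mapping[v] for v in labels], dtype=int)


def knn_jaccard_graph(x: np.ndarray, k: int):
    """Exact Euclidean kNN graph with Jaccard-weighted edges.

    Edge weight between u and v is |N(u) ∩ N(v)| / |N(u) ∪ N(v)| over the
    k-neighbor sets (self excluded).  Returns an igraph Graph.
    """
    import igraph

    n = x.shape[0]
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto").fit(x)
    _, idx = nn.kneighbors(x)
    # self may sit anywhere in its own neighbor row when duplicate points exist
    neigh: list[set[int]] = []
    for i, row in enumerate(idx):
        ordered = [int(j) for j in row if j != i][:k]
        neigh.append(set(ordered))

    edges: dict[tuple[int, int], float] = {}
    for u in range(n):
        for v in neigh[u]:
            a, b = (u, v) if u < v else (v, u)
            if (a, b) in edges:
                continue
            inter = len(neigh[a] & neigh[b])
            union = len(neigh[a] | neigh[b])
            if inter:
                edges[(a, b)] = inter / union
    g = igraph.Graph(n=n, edges=list(edges.keys()))
    g.es["weight"] = list(edges.values())
    return g


def run_phenograph(
    table: CytoTable,
    input_slot: str = "pca",
    k: int = 30,
    seed: int = 0,
    n_pc: int | None = None,
    markers: list[str] | None = None,
    flavor: str = "louvain",
    name: str = "phenograph",
) -> CytoTable:
    """Community detection on the Jaccard-weighted kNN graph.

    Louvain modularity optimization by default (Leiden behind
    ``flavor='leiden'``); larger ``k`` gives broader clusters, smaller ``k``
    finer ones.  The seed fixes both graph tie-breaking and the community
    sweep order, so repeated runs are identical.
    """
    from .dimred import _input_matrix

    x = _input_matrix(table, input_slot, markers, n_pc)
    if k >= x.shape[0]:
        raise ValueError(f"k={k} must be < number of cells ({x.shape[0]})")
    g = knn_jaccard_graph(x, k)

    if flavor == "louvain":
        import igraph

        igraph.set_random_number_generator(random.Random(seed))
        part = g.community_multilevel(weights="weight")
        labels = np.asarray(part.membership)
        modularity = g.modularity(part.membership, weights="weight")
    elif flavor == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            g, leidenalg.ModularityVertexPartition, weights="weight", seed=seed
        )
        labels = np.asarray(part.membership)
        modularity = part.quality()
    else:
        raise ValueError("flavor must be 'louvain' or 'leiden'")

    labels = _relabel_by_size(labels)
    out = table.copy()
    out.clusterings[name] = pd.Series(labels, index=table.cell_ids, name=name)
    out.log_event(
        "run_phenograph", seed=seed, k=k, input_slot=input_slot, flavor=flavor,
        n_clusters=int(labels.max()), modularity=float(modularity),
    )
    return out


def train_som(
    x: np.ndarray,
    grid: tuple[int, int] = (10, 10),
    rlen: int = 10,
    alpha: tuple[float, float] = (0.05, 0.01),
    seed: int = 0,
) -> np.ndarray:
    """Online self-organizing map training.

    ``rlen`` passes over the data; the learning rate decays linearly from
    ``alpha[0]`` to ``alpha[1]`` and the Gaussian neighborhood radius from
    roughly the grid diameter to one unit.  Returns the codebook
    (grid_x*grid_y, n_features).
    """
    rng = np.random.default_rng(seed)
    gx, gy = grid
    n_units = gx * gy
    units = np.array([(i, j) for i in range(gx) for j in range(gy)], dtype=float)
    grid_d2 = ((units[:, None, :] - units[None, :, :]) ** 2).sum(-1)
    codes = x[rng.choice(x.shape[0], size=n_units, replace=x.shape[0] < n_units)].astype(
        float
    )
    n_steps = rlen * x.shape[0]
    order = np.concatenate([rng.permutation(x.shape[0]) for _ in range(rlen)])
    r0 = max(np.sqrt(gx**2 + gy**2) / 2.0, 1.0)
    for step, i in enumerate(order):
        frac = step / max(n_steps - 1, 1)
        lr = alpha[0] + (alpha[1] - alpha[0]) * frac
        radius = r0 + (1.0 - r0) * frac
        xi = x[i]
        bmu = int(np.argmin(((codes - xi) ** 2).sum(axis=1)))
        h = np.exp(-grid_d2[bmu] / (2.0 * radius**2))
        codes += (lr * h)[:, None] * (xi - codes)
    return codes


def run_flowsom(
    table: CytoTable,
    input_slot: str = "pca",
    grid: tuple[int, int] = (10, 10),
    n_metaclusters: int | None = None,
    seed: int = 0,
    n_pc: int | None = None,
    markers: list[str] | None = None,
    name: str = "flowsom",
) -> CytoTable:
    """SOM codebook clustering cut to a fixed number of metaclusters.

    The trained codebook is hierarchically clustered (average linkage,
    Euclidean) and cut to exactly ``n_metaclusters``; every cell inherits the
    metacluster of its best-matching unit.  A metacluster that captures no
    cells is reported with a warning.
    """
    from .dimred import _input_matrix

    if n_metaclusters is None or n_metaclusters < 2:
        raise ValueError("n_metaclusters >= 2 is required")
    if n_metaclusters > grid[0] * grid[1]:
        raise ValueError(
            f"n_metaclusters={n_metaclusters} exceeds grid size {grid[0] * grid[1]}"
        )
    x = _input_matrix(table, input_slot, markers, n_pc)
    codes = train_som(x, grid=grid, seed=seed)
    z = linkage(codes, method="average", metric="euclidean")
    unit_meta = fcluster(z, t=n_metaclusters, criterion="maxclust")

    d2 = ((x[:, None, :] - codes[None, :, :]) ** 2).sum(-1)
    bmu = np.argmin(d2, axis=1)
    labels = unit_meta[bmu]
    realized = np.unique(labels)
    if realized.size < n_metaclusters:
        empty = sorted(set(range(1, n_metaclusters + 1)) - set(realized))
        warnings.warn(
            f"metaclusters with no cells: {empty}", stacklevel=2
        )
    labels = _relabel_by_size(labels)
    out = table.copy()
    out.clusterings[name] = pd.Series(labels, index=table.cell_ids, name=name)
    out.log_event(
        "run_flowsom", seed=seed, grid=list(grid), n_metaclusters=n_metaclusters,
        input_slot=input_slot, n_realized=int(realized.size),
    )
    return out


def cluster_marker_summary(
    table: CytoTable, label_var: str, slot: str = "expr"
) -> pd.DataFrame:
    """Mean marker expression per cluster (rows = labels, columns = markers)."""
    labels = _get_labels(table, label_var)
    mat = table.get_matrix(slot)
    return mat.groupby(labels).mean()


def annotate_clusters(
    table: CytoTable, mapping: dict, label_var: str = "phenograph",
    new_column: str = "cell_type",
) -> CytoTable:
    """Assign cell-type names to clusters (many-to-one allowed).

    The mapping must cover every cluster present; unmapped clusters are an
    error listing the offenders.
    """
    labels = _get_labels(table, label_var)
    present = set(labels.unique())
    unmapped = sorted(present - set(mapping))
    if unmapped:
        shown = [int(v) if isinstance(v, (np.integer, int)) else v for v in unmapped]
        raise ValueError(f"clusters without a mapping: {shown}")
    out = table.copy()
    out.anno[new_column] = labels.map(mapping).astype(str)
    out.log_event("annotate_clusters", label_var=label_var, new_column=new_column,
                  mapping={str(k): str(v) for k, v in mapping.items()})
    return out


def _get_labels(table: CytoTable, label_var: str) -> pd.Series:
    if label_var in table.clusterings:
        return table.clusterings[label_var]
    if label_var in table.anno.columns:
        return table.anno[label_var]
    raise ValueError(f"unknown label variable {label_var!r}")
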