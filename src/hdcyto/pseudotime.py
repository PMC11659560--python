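"""Cluster-MST trajectory inference and per-cell pseudotime.

The procedure builds a minimum spanning tree over cluster centroids in a
chosen embedding, reads lineages as root-to-leaf paths, and assigns each
cell an arc-length pseudotime along its lineage.  A cell's pseudotime is the
arc length from the root to its own cluster's centroid plus the signed
projection of the cell onto the *incoming* segment of that cluster (root
cells project onto the mean outgoing direction of the root's MST neighbors,
clamped at zero).  This local projection
depends only on the lineage prefix up to the cell's cluster, so lineages
that share their first m clusters assign identical pseudotime to cells of
those clusters — the property that makes a mean over lineages well defined
at branch points.

Cells whose cluster lies on no lineage carry no pseudotime (NaN), not 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .cluster import _get_labels
from .core import CytoTable

__all__ = [
    "TrajectoryResult",
    "run_pseudotime",
    "sweep_start_clusters",
    "ordered_expression",
]


@dataclass
class TrajectoryResult:
    mst_edges: list[tuple[object, object, float]]  # (cluster u, cluster v, distance)
    lineages: list[list[object]]  # ordered cluster paths, root first
    pseudotime: pd.DataFrame  # cells x lineages; NaN off-lineage
    mean_pseudotime: pd.Series  # NaN for cells on no lineage
    root_cluster: object
    embedding_used: str

    @property
    def total_arc_length(self) -> float:
        return float(sum(w for _, _, w in self.mst_edges))


def _centroid_mst(coords: np.ndarray, labels: np.ndarray):
    levels = pd.unique(labels)
    cents = np.vstack([coords[labels == c].mean(axis=0) for c in levels])
    dmat = squareform(pdist(cents))
    g = nx.Graph()
    for i, ci in enumerate(levels):
        g.add_node(ci, pos=cents[i])
    full = nx.Graph()
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            full.add_edge(levels[i], levels[j], weight=dmat[i, j])
    mst = nx.minimum_spanning_tree(full)
    cent_map = {c: cents[i] for i, c in enumerate(levels)}
    return mst, cent_map


def _default_root(mst: nx.Graph):
    """Root minimizing total weighted path length to all MST leaves."""
    leaves = [v for v in mst.nodes if mst.degree(v) == 1]
    lengths = dict(nx.all_pairs_dijkstra_path_length(mst))
    best, best_cost = None, np.inf
    for cand in sorted(mst.nodes, key=str):
        cost = sum(lengths[cand][leaf] for leaf in leaves)
        if cost < best_cost - 1e-12:
            best, best_cost = cand, cost
    return best


def run_pseudotime(
    table: CytoTable,
    embedding: str,
    cluster_var: str,
    start_cluster=None,
    end_clusters: list | None = None,
) -> TrajectoryResult:
    """Infer lineages and per-cell pseudotime on an existing embedding.

    With ``start_cluster`` unset the root is the MST vertex minimizing total
    path length to all leaves; ``end_clusters`` restricts lineages to the
    root-to-leaf paths that terminate there.
    """
    coords_df = table.get_matrix(embedding)
    coords = coords_df.to_numpy(dtype=float)
    labels = _get_labels(table, cluster_var).to_numpy()
    levels = pd.unique(labels)
    if levels.size < 2:
        raise ValueError("pseudotime needs at least 2 clusters")
    if start_cluster is not None and start_cluster not in levels:
        raise ValueError(f"start cluster {start_cluster!r} not in {cluster_var}")
    if end_clusters:
        missing = [c for c in end_clusters if c not in levels]
        if missing:
            raise ValueError(f"end clusters not in {cluster_var}: {missing}")

    mst, cent = _centroid_mst(coords, labels)
    root = start_cluster if start_cluster is not None else _default_root(mst)

    leaves = [v for v in mst.nodes if mst.degree(v) == 1 and v != root]
    if not leaves:  # root is the single hub of a 2-node tree
        leaves = [v for v in mst.nodes if v != root]
    paths = [nx.shortest_path(mst, root, leaf, weight="weight") for leaf in leaves]
    if end_clusters:
        paths = [p for p in paths if p[-1] in end_clusters]
        if not paths:
            raise ValueError("no root-to-leaf path ends at the requested end clusters")
    paths.sort(key=lambda p: [str(c) for c in p])

    # Root cells project onto the mean outgoing direction of the root's MST
    # neighbors; this depends only on the tree and the root, never on which
    # lineage is being scored, so all lineages agree on root-cell pseudotime.
    neigh_dirs = []
    for nb in mst.neighbors(root):
        v = cent[nb] - cent[root]
        neigh_dirs.append(v / np.linalg.norm(v))
    root_dir = np.mean(neigh_dirs, axis=0)
    nrm = np.linalg.norm(root_dir)
    root_dir = root_dir / nrm if nrm > 1e-12 else neigh_dirs[0]

    pt = pd.DataFrame(
        np.nan, index=coords_df.index,
        columns=[f"lineage_{i + 1}" for i in range(len(paths))],
    )
    for li, path in enumerate(paths):
        seg_starts = np.zeros(len(path))  # arc length from root to each cluster centroid
        for j in range(1, len(path)):
            seg_starts[j] = seg_starts[j - 1] + float(
                np.linalg.norm(cent[path[j]] - cent[path[j - 1]])
            )
        col = pt.columns[li]
        for j, cl in enumerate(path):
            sel = labels == cl
            if not sel.any():
                continue
            x = coords[sel]
            if j == 0:
                vals = np.maximum((x - cent[cl]) @ root_dir, 0.0)
            else:
                seg = cent[path[j]] - cent[path[j - 1]]
                direction = seg / np.linalg.norm(seg)
                proj = (x - cent[cl]) @ direction
                vals = np.maximum(seg_starts[j] + proj, 0.0)
            pt.loc[sel, col] = vals

    mean_pt = pt.mean(axis=1, skipna=True)
    edges = [(u, v, float(d["weight"])) for u, v, d in mst.edges(data=True)]
    return TrajectoryResult(
        mst_edges=edges,
        lineages=[list(p) for p in paths],
        pseudotime=pt,
        mean_pseudotime=mean_pt,
        root_cluster=root,
        embedding_used=embedding,
    )


def sweep_start_clusters(
    table: CytoTable, embedding: str, cluster_var: str
) -> pd.DataFrame:
    """Re-infer the trajectory once per candidate root cluster.

    Returns one summary row per candidate (lineage count and total MST arc
    length) to help pick the best-fitting starting point.
    """
    labels = _get_labels(table, cluster_var)
    rows = []
    for cand in pd.unique(labels):
        res = run_pseudotime(table, embedding, cluster_var, start_cluster=cand)
        rows.append(
            {
                "start_cluster": cand,
                "n_lineages": len(res.lineages),
                "total_arc_length": res.total_arc_length,
                "max_pseudotime": float(res.pseudotime.max().max()),
            }
        )
    return pd.DataFrame(rows).set_index("start_cluster")


def ordered_expression(
    table: CytoTable, result: TrajectoryResult, lineage: str, slot: str = "expr"
) -> pd.DataFrame:
    """Expression matrix of one lineage's cells, rows sorted by that
    lineage's pseudotime (ties broken by cell id)."""
    if lineage not in result.pseudotime.columns:
        raise ValueError(
            f"unknown lineage {lineage!r}; have {list(result.pseudotime.columns)}"
        )
    pt = result.pseudotime[lineage].dropna()
    order = pt.to_frame("pt").assign(cid=pt.index).sort_values(["pt", "cid"]).index
    mat = table.get_matrix(slot)
    out = mat.loc[order].copy()
    out.insert(0, "pseudotime", pt.loc[order])
    return out
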