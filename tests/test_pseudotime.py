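import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import hdcyto as h
from hdcyto.core import Reduction

from conftest import make_table


def _line_table(n_per_cluster=300, sigma=0.15, seed=0):
    """Three clusters with centroids (0,0), (1,0), (2,0) in a 2-D embedding."""
    rng = np.random.default_rng(seed)
    xs, labels = [], []
    for i, cx in enumerate([0.0, 1.0, 2.0]):
        pts = rng.normal([cx, 0.0], sigma, size=(n_per_cluster, 2))
        xs.append(pts)
        labels += ["ABC"[i]] * n_per_cluster
    coords = np.vstack(xs)
    t = make_table(n_per_sample=(len(coords),), n_markers=2)
    t.reductions["emb"] = Reduction(
        coords=pd.DataFrame(coords, index=t.cell_ids, columns=["d1", "d2"]),
        kind="umap", input_slot="expr",
    )
    t.anno["cluster"] = labels
    return t, coords


class TestRunPseudotime:
    def test_line_ordering_matches_axis(self):
        t, coords = _line_table()
        res = h.run_pseudotime(t, "emb", "cluster", start_cluster="A")
        rho = spearmanr(res.pseudotime["lineage_1"], coords[:, 0]).statistic
        assert rho >= 0.99

    def test_root_centroid_cells_get_zero(self):
        t, coords = _line_table(n_per_cluster=50)
        # a cell placed at the mean of its cluster mates IS the centroid
        root_cells = (t.anno["cluster"] == "A").to_numpy()
        cid = t.cell_ids[0]
        others = root_cells.copy()
        others[0] = False
        t.reductions["emb"].coords.loc[cid] = coords[others].mean(axis=0)
        res = h.run_pseudotime(t, "emb", "cluster", start_cluster="A")
        assert res.pseudotime.loc[cid, "lineage_1"] == pytest.approx(0.0, abs=1e-10)

    def test_y_topology_gives_two_lineages_from_root(self):
        design = h.make_fixture("branched_trajectory", seed=2)
        design.cells_per_sample = 500
        t = h.simulate(design)
        res = h.run_pseudotime(t, "expr", "true_population", start_cluster="root")
        assert len(res.lineages) == 2
        assert all(lin[0] == "root" for lin in res.lineages)
        assert {lin[-1] for lin in res.lineages} == {"B2", "C2"}

    def test_mst_edge_count_and_connectivity(self):
        t, _ = _line_table(n_per_cluster=40)
        res = h.run_pseudotime(t, "emb", "cluster", start_cluster="A")
        assert len(res.mst_edges) == 2  # clusters - 1

    def test_unknown_start_cluster(self):
        t, _ = _line_table(n_per_cluster=30)
        with pytest.raises(ValueError, match="nope"):
            h.run_pseudotime(t, "emb", "cluster", start_cluster="nope")

    def test_end_cluster_restriction(self):
        design = h.make_fixture("branched_trajectory", seed=3)
        design.cells_per_sample = 400
        t = h.simulate(design)
        res = h.run_pseudotime(t, "expr", "true_population",
                               start_cluster="root", end_clusters=["B2"])
        assert len(res.lineages) == 1
        assert res.lineages[0][-1] == "B2"

    def test_rotation_and_translation_invariance(self):
        t, coords = _line_table(n_per_cluster=60, seed=4)
        res_a = h.run_pseudotime(t, "emb", "cluster", start_cluster="A")
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        t.reductions["emb"].coords.iloc[:, :] = coords @ rot.T + [3.0, -7.0]
        res_b = h.run_pseudotime(t, "emb", "cluster", start_cluster="A")
        assert np.allclose(
            res_a.pseudotime.to_numpy(), res_b.pseudotime.to_numpy(),
            atol=1e-8, equal_nan=True,
        )

    def test_shared_prefix_lineages_agree_exactly(self):
        design = h.make_fixture("branched_trajectory", seed=5)
        design.cells_per_sample = 400
        t = h.simulate(design)
        res = h.run_pseudotime(t, "expr", "true_population", start_cluster="root")
        on_root = (t.anno["true_population"] == "root").to_numpy()
        both = res.pseudotime.loc[on_root]
        assert np.max(np.abs(both["lineage_1"] - both["lineage_2"])) < 1e-10

    def test_off_lineage_cells_have_absent_pseudotime(self):
        design = h.make_fixture("branched_trajectory", seed=6)
        design.cells_per_sample = 300
        t = h.simulate(design)
        res = h.run_pseudotime(t, "expr", "true_population", start_cluster="root")
        on_c = (t.anno["true_population"] == "C2").to_numpy()
        lin_b = [i for i, lin in enumerate(res.lineages) if lin[-1] == "B2"][0]
        assert res.pseudotime.loc[on_c].iloc[:, lin_b].isna().all()
        assert res.mean_pseudotime.loc[on_c].notna().all()  # still on lineage C


class TestSweep:
    def test_one_result_per_candidate_root(self):
        t, _ = _line_table(n_per_cluster=40)
        sweep = h.sweep_start_clusters(t, "emb", "cluster")
        assert len(sweep) == 3

    def test_line_roots_give_expected_lineage_counts(self):
        t, _ = _line_table(n_per_cluster=40)
        sweep = h.sweep_start_clusters(t, "emb", "cluster")
        assert sweep.loc["A", "n_lineages"] == 1
        assert sweep.loc["C", "n_lineages"] == 1
        assert sweep.loc["B", "n_lineages"] == 2

    def test_symmetric_roots_give_identical_totals(self):
        t, _ = _line_table(n_per_cluster=40)
        sweep = h.sweep_start_clusters(t, "emb", "cluster")
        assert sweep.loc["A", "total_arc_length"] == pytest.approx(
            sweep.loc["C", "total_arc_length"]
        )


@pytest.fixture(scope="module")
def line_result():
    design = h.make_fixture("linear_trajectory", seed=7)
    t = h.simulate(design)
    res = h.run_pseudotime(t, "expr", "true_population", start_cluster="A")
    return t, res


class TestOrderedExpression:
    def test_rows_sorted_by_pseudotime(self, line_result):
        t, res = line_result
        ordered = h.ordered_expression(t, res, "lineage_1")
        assert (np.diff(ordered["pseudotime"].to_numpy()) >= 0).all()

    def test_row_count_equals_lineage_cells(self, line_result):
        t, res = line_result
        ordered = h.ordered_expression(t, res, "lineage_1")
        assert len(ordered) == res.pseudotime["lineage_1"].notna().sum()

    def test_gradient_marker_monotone_in_row_order(self, line_result):
        t, res = line_result
        ordered = h.ordered_expression(t, res, "lineage_1")
        rho = spearmanr(np.arange(len(ordered)), ordered["grad_up"]).statistic
        assert rho >= 0.95

    def test_unknown_lineage(self, line_result):
        t, res = line_result
        with pytest.raises(ValueError, match="lineage_9"):
            h.ordered_expression(t, res, "lineage_9")
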