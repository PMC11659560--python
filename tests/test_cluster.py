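import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import hdcyto as h

from conftest import make_table


class TestPhenograph:
    def test_separated_gaussians_recovered_exactly(self, gauss3_table):
        t = h.run_phenograph(gauss3_table, input_slot="expr", k=15, seed=1)
        ari = adjusted_rand_score(
            t.anno["true_population"], t.clusterings["phenograph"]
        )
        assert ari == 1.0

    def test_seed_determinism(self, gauss3_table):
        a = h.run_phenograph(gauss3_table, input_slot="expr", k=15, seed=4)
        b = h.run_phenograph(gauss3_table, input_slot="expr", k=15, seed=4)
        assert (a.clusterings["phenograph"] == b.clusterings["phenograph"]).all()

    def test_k_at_least_cell_count_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="k="):
            h.run_phenograph(tiny_table, input_slot="expr", k=5, seed=0)

    def test_labels_size_ordered_from_one(self, gauss3_table):
        t = h.run_phenograph(gauss3_table, input_slot="expr", k=15, seed=1)
        labels = t.clusterings["phenograph"]
        counts = labels.value_counts().sort_index()
        assert counts.index[0] == 1
        assert list(counts.values) == sorted(counts.values, reverse=True)

    def test_duplicated_points_give_same_partition(self):
        design = h.separated_mixture_design(
            3, n_markers=5, level=6.0, min_separation=8.0,
            n_samples=1, cells_per_sample=120, seed=8,
        )
        t = h.simulate(design)
        base = h.run_phenograph(t, input_slot="expr", k=15, seed=2)

        doubled = t.copy()
        dup = t.expr_raw.copy()
        dup.index = [f"{c}_dup" for c in dup.index]
        doubled.expr_raw = pd.concat([t.expr_raw, dup])
        doubled.expr = doubled.expr_raw.copy()
        anno2 = t.anno.copy()
        anno2.index = dup.index
        doubled.anno = pd.concat([t.anno, anno2])
        # k scales with the doubled density so neighborhoods are comparable
        d2 = h.run_phenograph(doubled, input_slot="expr", k=30, seed=2)
        first_half = d2.clusterings["phenograph"].iloc[: t.n_cells]
        assert adjusted_rand_score(base.clusterings["phenograph"], first_half) == 1.0

    def test_excluded_markers_ignored(self, gauss3_table):
        t = gauss3_table.copy()
        rng = np.random.default_rng(0)
        t.expr["junk"] = rng.normal(scale=50.0, size=t.n_cells)
        t.expr_raw["junk"] = t.expr["junk"]
        used = [m for m in t.markers if m != "junk"]
        a = h.run_phenograph(t, input_slot="expr", k=15, seed=1, markers=used)
        b = h.run_phenograph(gauss3_table, input_slot="expr", k=15, seed=1)
        assert (a.clusterings["phenograph"].to_numpy()
                == b.clusterings["phenograph"].to_numpy()).all()

    def test_leiden_flavor_available(self, gauss3_table):
        # Leiden optimizes a different objective; expect faithful but not
        # necessarily identical recovery, and seed determinism
        a = h.run_phenograph(gauss3_table, input_slot="expr", k=15, seed=1,
                             flavor="leiden")
        b = h.run_phenograph(gauss3_table, input_slot="expr", k=15, seed=1,
                             flavor="leiden")
        ari = adjusted_rand_score(a.anno["true_population"],
                                  a.clusterings["phenograph"])
        assert ari > 0.8
        assert (a.clusterings["phenograph"] == b.clusterings["phenograph"]).all()


class TestFlowSom:
    def test_metacluster_count_is_exact_over_units(self, gauss3_table):
        from scipy.cluster.hierarchy import fcluster, linkage

        from hdcyto.cluster import train_som
        from hdcyto.dimred import _input_matrix

        x = _input_matrix(gauss3_table, "expr", None, None)
        codes = train_som(x, grid=(5, 5), seed=3)
        unit_meta = fcluster(linkage(codes, method="average"), t=5,
                             criterion="maxclust")
        assert len(np.unique(unit_meta)) == 5
        # cells may realize fewer labels; that case is flagged with a warning
        with pytest.warns(UserWarning, match="no cells"):
            t = h.run_flowsom(gauss3_table, input_slot="expr", grid=(5, 5),
                              n_metaclusters=5, seed=3)
        assert t.clusterings["flowsom"].nunique() <= 5

    def test_three_gaussians_recovered(self, gauss3_table):
        t = h.run_flowsom(gauss3_table, input_slot="expr", grid=(6, 6),
                          n_metaclusters=3, seed=3)
        ari = adjusted_rand_score(t.anno["true_population"], t.clusterings["flowsom"])
        assert ari == 1.0

    def test_grid_too_small_rejected(self, gauss3_table):
        with pytest.raises(ValueError, match="grid"):
            h.run_flowsom(gauss3_table, grid=(2, 2), n_metaclusters=5, seed=0)

    def test_seed_determinism(self, gauss3_table):
        a = h.run_flowsom(gauss3_table, input_slot="expr", grid=(4, 4),
                          n_metaclusters=3, seed=9)
        b = h.run_flowsom(gauss3_table, input_slot="expr", grid=(4, 4),
                          n_metaclusters=3, seed=9)
        assert (a.clusterings["flowsom"] == b.clusterings["flowsom"]).all()


class TestSummariesAndAnnotation:
    def test_single_cluster_summary_equals_global_means(self, tiny_table):
        tiny_table.clusterings["c"] = pd.Series(
            1, index=tiny_table.cell_ids, name="c"
        )
        summary = h.cluster_marker_summary(tiny_table, "c")
        assert np.allclose(summary.loc[1].to_numpy(),
                           tiny_table.expr.mean().to_numpy())

    def test_hand_computed_toy_means(self):
        t = make_table(n_per_sample=(4,), n_markers=2)
        t.expr.iloc[:, 0] = [1.0, 3.0, 10.0, 20.0]
        t.expr.iloc[:, 1] = [0.0, 0.0, 2.0, 4.0]
        t.clusterings["c"] = pd.Series([1, 1, 2, 2], index=t.cell_ids)
        summary = h.cluster_marker_summary(t, "c")
        assert summary.loc[1, "m1"] == 2.0
        assert summary.loc[2, "m1"] == 15.0
        assert summary.loc[2, "m2"] == 3.0
        assert len(summary) == 2

    def test_unknown_label_var(self, tiny_table):
        with pytest.raises(ValueError, match="nope"):
            h.cluster_marker_summary(tiny_table, "nope")

    def test_annotation_identity_and_merge(self, tiny_table):
        tiny_table.clusterings["c"] = pd.Series(
            [1, 1, 2, 3, 3], index=tiny_table.cell_ids
        )
        ident = h.annotate_clusters(tiny_table, {1: "1", 2: "2", 3: "3"},
                                    label_var="c")
        assert (ident.anno["cell_type"]
                == tiny_table.clusterings["c"].astype(str)).all()
        merged = h.annotate_clusters(tiny_table, {1: "T", 2: "T", 3: "B"},
                                     label_var="c")
        assert set(merged.anno["cell_type"]) == {"T", "B"}

    def test_unmapped_cluster_reported(self, tiny_table):
        tiny_table.clusterings["c"] = pd.Series(
            [1, 2, 3, 4, 4], index=tiny_table.cell_ids
        )
        with pytest.raises(ValueError, match=r"\[4\]"):
            h.annotate_clusters(tiny_table, {1: "a", 2: "b", 3: "c"}, label_var="c")
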