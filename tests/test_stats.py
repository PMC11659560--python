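import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import hdcyto as h
from hdcyto.stats import frequency_tests, tukey_boxplot_stats

from conftest import make_table


def _labeled_table(labels_per_sample, groups=("a", "b")):
    """Table whose cells carry a fixed label sequence per sample."""
    sizes = [len(v) for v in labels_per_sample.values()]
    t = make_table(n_per_sample=tuple(sizes), n_markers=2)
    lab = np.concatenate([np.array(v, dtype=object) for v in labels_per_sample.values()])
    t.anno["celltype"] = lab
    t.sample_meta["group"] = [groups[i % len(groups)] for i in range(len(sizes))]
    return t


class TestAbundance:
    def test_half_half_sample(self):
        t = _labeled_table({"s1": ["T", "T", "B", "B"], "s2": ["T", "B"]})
        freq = h.abundance_table(t, "celltype")
        assert freq.loc["s1", "T"] == 50.0 and freq.loc["s1", "B"] == 50.0

    def test_rows_sum_to_hundred(self, pbmc_table):
        freq = h.abundance_table(pbmc_table, "true_population")
        assert np.allclose(freq.sum(axis=1), 100.0, atol=1e-9)

    def test_absent_label_is_zero_not_missing(self):
        t = _labeled_table({"s1": ["T", "T"], "s2": ["B", "B"]})
        freq = h.abundance_table(t, "celltype")
        assert freq.loc["s1", "B"] == 0.0


class TestConfusionMatrix:
    def test_identical_composition_gives_uniform_rows(self):
        t = _labeled_table({"s1": ["T", "B"] * 10, "s2": ["T", "B"] * 10})
        t.anno["group"] = np.where(t.anno["sample_id"] == "s1", "g1", "g2")
        cm = h.confusion_matrix(t, "celltype", "group")
        assert np.allclose(cm.to_numpy(), 0.5)

    def test_hand_computed_counts(self):
        # g1: 8 cells in c1, 2 in c2; g2: 2 in c1, 8 in c2
        t = _labeled_table({
            "s1": ["c1"] * 8 + ["c2"] * 2,
            "s2": ["c1"] * 2 + ["c2"] * 8,
        })
        t.anno["group"] = np.where(t.anno["sample_id"] == "s1", "g1", "g2")
        cm = h.confusion_matrix(t, "celltype", "group")
        assert cm.loc["c1", "g1"] == pytest.approx(0.8)
        assert cm.loc["c1", "g2"] == pytest.approx(0.2)

    def test_single_group_gives_all_ones(self):
        t = _labeled_table({"s1": ["c1"] * 5 + ["c2"] * 5})
        t.anno["group"] = "g1"
        cm = h.confusion_matrix(t, "celltype", "group")
        assert np.allclose(cm.to_numpy(), 1.0)


class TestFrequencyTests:
    def test_identical_groups_give_p_one(self):
        freq = pd.DataFrame(
            {"T": [10.0, 12, 11, 10, 12, 11], "B": [90.0, 88, 89, 90, 88, 89]},
            index=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=freq.index)
        for r in frequency_tests(freq, groups):
            assert r.p_raw == pytest.approx(1.0)
            assert r.p_adj == pytest.approx(1.0)

    def test_welch_statistic_against_closed_form(self):
        # (10,12,11) vs (20,22,21): t = 10/sqrt(2/3), Satterthwaite df = 4
        freq = pd.DataFrame({"T": [10.0, 12, 11, 20, 22, 21]},
                            index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=freq.index)
        (res,) = frequency_tests(freq, groups, test="t")
        t_expected = -10.0 / np.sqrt(2.0 / 3.0)
        assert res.statistic == pytest.approx(t_expected, abs=1e-6)
        p_expected = 2 * sps.t.sf(abs(t_expected), df=4)
        assert res.p_raw == pytest.approx(p_expected, rel=1e-6)
        assert res.p_raw == pytest.approx(2.55e-4, rel=0.02)

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(0)
        freq = pd.DataFrame(rng.uniform(5, 15, size=(6, 8)),
                            columns=[f"l{i}" for i in range(8)],
                            index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=freq.index)
        for r in frequency_tests(freq, groups):
            assert r.p_adj == pytest.approx(min(1.0, 8 * r.p_raw))

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(1)
        freq = pd.DataFrame(rng.uniform(0, 30, size=(8, 4)),
                            columns=list("wxyz"),
                            index=[f"s{i}" for i in range(8)])
        g1 = pd.Series(["a"] * 4 + ["b"] * 4, index=freq.index)
        g2 = pd.Series(["b"] * 4 + ["a"] * 4, index=freq.index)
        p1 = [r.p_raw for r in frequency_tests(freq, g1)]
        p2 = [r.p_raw for r in frequency_tests(freq, g2)]
        assert np.allclose(p1, p2)

    def test_three_groups_get_posthoc(self):
        rng = np.random.default_rng(2)
        freq = pd.DataFrame(rng.uniform(0, 30, size=(9, 2)), columns=["T", "B"],
                            index=[f"s{i}" for i in range(9)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=freq.index)
        results = frequency_tests(freq, groups, test="kruskal")
        for r in results:
            assert r.post_hoc is not None and len(r.post_hoc) == 3
            assert (r.post_hoc["p_adj"] <= 1.0).all()

    def test_paired_requires_equal_sizes(self):
        freq = pd.DataFrame({"T": [1.0, 2, 3, 4, 5]},
                            index=[f"s{i}" for i in range(5)])
        groups = pd.Series(["a", "a", "a", "b", "b"], index=freq.index)
        with pytest.raises(ValueError, match="paired"):
            frequency_tests(freq, groups, paired=True)

    def test_welch_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 over 1000 simulated datasets."""
        rng = np.random.default_rng(42)
        rejections = 0
        total = 0
        for _ in range(1000):
            freq = pd.DataFrame(
                rng.normal(20.0, 4.0, size=(10, 3)),
                columns=["a", "b", "c"],
                index=[f"s{i}" for i in range(10)],
            )
            groups = pd.Series(["g1"] * 5 + ["g2"] * 5, index=freq.index)
            for r in frequency_tests(freq, groups, test="t", correction="none"):
                total += 1
                rejections += r.p_raw < 0.05
        rate = rejections / total
        assert 0.03 <= rate <= 0.07


class TestExpressionSummaries:
    def test_single_group_matches_cluster_summary(self, pbmc_table):
        t = pbmc_table.copy()
        t.anno["group"] = "only"
        gm = h.group_marker_means(t, "true_population", "group")
        cs = h.cluster_marker_summary(t, "true_population")
        merged = gm.droplevel("group")
        pd.testing.assert_frame_equal(merged.sort_index(), cs.sort_index())

    def test_hand_toy_group_means(self):
        t = _labeled_table({"s1": ["T", "T"], "s2": ["T", "T"]})
        t.anno["group"] = np.where(t.anno["sample_id"] == "s1", "g1", "g2")
        t.expr.iloc[:, 0] = [1.0, 3.0, 10.0, 30.0]
        gm = h.group_marker_means(t, "celltype", "group")
        assert gm.loc[("T", "g1"), "m1"] == 2.0
        assert gm.loc[("T", "g2"), "m1"] == 20.0

    def test_per_sample_median_cases(self):
        t = _labeled_table({"s1": ["T"], "s2": ["T", "T", "B", "B"]})
        t.expr.iloc[:, 0] = [7.0, 1.0, 3.0, 100.0, 200.0]
        med = h.per_sample_median(t, "m1", "celltype", "T")
        assert med.loc["s1", "median"] == 7.0  # single cell
        assert med.loc["s2", "median"] == 2.0  # midpoint of (1, 3)
        med_b = h.per_sample_median(t, "m1", "celltype", "B")
        assert "s1" not in med_b.index  # label absent -> row absent

    def test_tukey_boxplot_statistics(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 100.0])
        st = tukey_boxplot_stats(x)
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        assert st["median"] == med and st["q1"] == q1 and st["q3"] == q3
        assert st["outliers"] == [100.0]
        assert st["whisker_high"] == 8.0


def test_long_format_export(pbmc_table):
    long = h.to_long_format(pbmc_table, "true_population")
    n_samples = len(pbmc_table.sample_meta)
    n_labels = pbmc_table.anno["true_population"].nunique()
    assert len(long) == n_samples * n_labels
    assert set(["sample_id", "true_population", "n_cells", "frequency_pct", "group"]
               ) <= set(long.columns)
    per_sample = long.groupby("sample_id")["frequency_pct"].sum()
    assert np.allclose(per_sample, 100.0)
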