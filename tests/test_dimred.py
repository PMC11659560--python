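import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import silhouette_score

import hdcyto as h
from hdcyto.dimred import diffusion_map

from conftest import make_table


class TestPca:
    def test_collinear_points_put_all_variance_on_pc1(self):
        t = make_table(n_per_sample=(3,), n_markers=2)
        t.expr.iloc[:, 0] = [0.0, 1.0, 2.0]
        t.expr.iloc[:, 1] = [0.0, 1.0, 2.0]
        out = h.run_pca(t, n_pc=2)
        ev = out.reductions["pca"].extras["explained_variance"]
        assert ev[0] / ev.sum() == pytest.approx(1.0, abs=1e-12)

    def test_scores_are_centered(self, pbmc_table):
        scores = pbmc_table.reductions["pca"].coords.to_numpy()
        assert np.max(np.abs(scores.mean(axis=0))) < 1e-10

    def test_total_variance_preserved_with_all_pcs(self, pbmc_table):
        t = h.run_pca(pbmc_table, n_pc=len(pbmc_table.markers))
        ev = t.reductions["pca"].extras["explained_variance"]
        marker_var = t.expr.var(axis=0, ddof=1).sum()
        assert ev.sum() == pytest.approx(marker_var, rel=1e-10)

    def test_reconstruction_from_loadings(self, pbmc_table):
        t = h.run_pca(pbmc_table, n_pc=len(pbmc_table.markers))
        red = t.reductions["pca"]
        x = t.expr.to_numpy()
        centered = x - x.mean(axis=0)
        recon = red.coords.to_numpy() @ red.extras["loadings"].to_numpy().T
        assert np.max(np.abs(recon - centered)) < 1e-8

    def test_too_many_components_rejected(self, pbmc_table):
        with pytest.raises(ValueError, match="n_pc"):
            h.run_pca(pbmc_table, n_pc=len(pbmc_table.markers) + 1)

    def test_constant_marker_with_scaling_rejected(self, tiny_table):
        tiny_table.expr.iloc[:, 0] = 1.0
        with pytest.raises(ValueError, match="constant"):
            h.run_pca(tiny_table, scale=True)


class TestPseudobulkPca:
    def test_identical_samples_give_zero_coords(self):
        t = make_table(n_per_sample=(4, 4, 4), seed=1)
        first = t.expr.iloc[:4].to_numpy()
        t.expr.iloc[4:8] = first
        t.expr.iloc[8:12] = first
        res = h.run_pseudobulk_pca(t)
        assert np.max(np.abs(res.coords.to_numpy())) < 1e-10

    def test_single_marker_shift_dominates_pc1(self):
        rng = np.random.default_rng(2)
        t = make_table(n_per_sample=(30,) * 6, n_markers=5, seed=2)
        t.expr = pd.DataFrame(
            rng.normal(size=(t.n_cells, 5)), index=t.cell_ids,
            columns=t.expr.columns,
        )
        shift = t.anno["sample_id"].isin(["s1", "s2", "s3"]).to_numpy()
        t.expr.iloc[shift, 2] += 5.0
        # unscaled: a single strongly shifted marker carries the most
        # between-sample variance, so it must dominate PC1
        res = h.run_pseudobulk_pca(t, scale=False)
        top = res.loadings["PC1"].abs().idxmax()
        assert top == t.expr.columns[2]
        # eigen oracle on the centered sample means confirms the axis
        m = res.sample_means.to_numpy()
        c = np.cov((m - m.mean(axis=0)).T)
        lead = np.linalg.eigh(c)[1][:, -1]
        assert np.argmax(np.abs(lead)) == 2

    def test_one_row_per_sample(self, pbmc_table):
        res = h.run_pseudobulk_pca(pbmc_table)
        assert len(res.coords) == len(pbmc_table.sample_meta)

    def test_needs_three_samples(self, tiny_table):
        with pytest.raises(ValueError, match=">= 3 samples"):
            h.run_pseudobulk_pca(tiny_table)


class TestNonlinearEmbeddings:
    def test_umap_shape_determinism_and_separation(self, gauss3_table):
        t = h.run_pca(gauss3_table, n_pc=5)
        a = h.run_umap(t, input_slot="pca", seed=7)
        b = h.run_umap(t, input_slot="pca", seed=7)
        coords = a.reductions["umap"].coords.to_numpy()
        assert coords.shape == (t.n_cells, 2)
        assert np.all(np.isfinite(coords))
        assert np.array_equal(coords, b.reductions["umap"].coords.to_numpy())
        sil = silhouette_score(coords, t.anno["true_population"])
        assert sil > 0.5

    def test_umap_records_model_only_when_requested(self, gauss3_table):
        t = h.run_pca(gauss3_table, n_pc=5)
        assert "umap" not in h.run_umap(t, seed=1).models
        assert "umap" in h.run_umap(t, seed=1, ret_model=True).models

    def test_tsne_shape_determinism_and_separation(self, gauss3_table):
        t = h.run_pca(gauss3_table, n_pc=5)
        a = h.run_tsne(t, input_slot="pca", seed=3, perplexity=20)
        b = h.run_tsne(t, input_slot="pca", seed=3, perplexity=20)
        coords = a.reductions["tsne"].coords.to_numpy()
        assert coords.shape == (t.n_cells, 2) and np.all(np.isfinite(coords))
        assert np.allclose(coords, b.reductions["tsne"].coords.to_numpy())
        assert silhouette_score(coords, t.anno["true_population"]) > 0.5

    def test_missing_input_slot_raises(self, gauss3_table):
        with pytest.raises(ValueError, match="pca"):
            h.run_umap(gauss3_table, input_slot="pca", seed=0)


class TestDiffusionMap:
    def test_transition_rows_stochastic_and_spectrum_bounded(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(150, 4))
        comps, evals, rowsums = diffusion_map(x, n_components=3)
        assert np.max(np.abs(rowsums - 1.0)) < 1e-10
        assert evals[1] <= 1.0 + 1e-12

    def test_line_recovered_monotonically(self):
        rng = np.random.default_rng(1)
        s = np.sort(rng.uniform(0, 10, 200))
        x = np.column_stack([s, 0.01 * rng.normal(size=200)])
        comps, _, _ = diffusion_map(x, n_components=2)
        rho = spearmanr(comps[:, 0], s).statistic
        assert abs(rho) > 0.99

    def test_component_count_limit(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="n_components"):
            diffusion_map(x, n_components=10)


class TestLoadings:
    def test_ranking_matches_eigen_oracle(self, pbmc_table):
        red = pbmc_table.reductions["pca"]
        table = h.pca_loadings(pbmc_table, 1)
        # independent oracle: eigendecomposition of the covariance matrix
        x = pbmc_table.expr.to_numpy()
        c = np.cov((x - x.mean(axis=0)).T)
        w, v = np.linalg.eigh(c)
        lead = v[:, np.argmax(w)]
        if lead[np.argmax(np.abs(lead))] < 0:
            lead = -lead
        oracle = pd.Series(lead, index=pbmc_table.markers).sort_values(ascending=False)
        assert list(table.index[:2]) == list(oracle.index[:2])
        assert list(table.index[-2:]) == list(oracle.index[-2:])

    def test_sign_convention_makes_top_loading_positive(self, pbmc_table):
        loadings = pbmc_table.reductions["pca"].extras["loadings"]
        for col in loadings.columns:
            v = loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_unknown_component_rejected(self, pbmc_table):
        with pytest.raises(ValueError, match="PC99"):
            h.pca_loadings(pbmc_table, 99)
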