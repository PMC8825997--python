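"""Scaling, PCA/Q2, PLS-DA/VIP, clustering and ANOVA feature selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from derep_ms.chemometrics import (
    ParetoScaler,
    PLSDiscriminantAnalysis,
    fisher_lsd,
    fit_pca,
    fit_plsda,
    hca,
    heatmap_data,
    impute_missing,
    pareto_scale,
    q2_crossval,
    top_features_anova,
    vip_scores,
)
from derep_ms.simulate import IntensityDesign, simulate_intensity_matrix


class TestParetoScaling:
    def test_hand_computed_two_point_column(self):
        # column (1, 3): mean 2, sd sqrt(2), scaled = +/- 1/2**0.25
        scaled = pareto_scale(np.array([[1.0], [3.0]]))
        assert np.allclose(np.round(scaled.to_numpy().ravel(), 4), [-0.8409, 0.8409])

    def test_constant_column_flagged_and_zeroed(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        scaler = ParetoScaler().fit(X)
        out = scaler.transform(X)
        assert scaler.zero_variance_mask_.tolist() == [True, False]
        assert np.allclose(out.to_numpy()[:, 0], 0.0)

    @given(seed=st.integers(0, 100))
    @settings(max_examples=20, deadline=None)
    def test_columns_centered(self, seed):
        X = np.random.default_rng(seed).lognormal(3, 1, size=(6, 8))
        assert np.allclose(pareto_scale(X).mean(axis=0), 0.0, atol=1e-10)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pareto_scale(np.array([[1.0, 2.0]]))


class TestPCA:
    def test_rank_one_explains_everything(self):
        X = np.outer([1.0, 2.0, 3.0, 4.0], [0.5, 1.0, 2.0])
        model = fit_pca(X, 1)
        assert model.explained_variance_pct_[0] == pytest.approx(100.0)
        assert model.r2_cum_[-1] == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(4, 3))
        model = fit_pca(X, 2)
        xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(xc.T))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        total = evals.sum()
        assert np.allclose(
            model.explained_variance_pct_[:2], 100 * evals[:2] / total, atol=1e-8
        )
        for a in range(2):
            assert np.allclose(
                np.abs(model.loadings_[:, a]), np.abs(evecs[:, a]), atol=1e-8
            )

    def test_full_rank_variance_sums_to_100(self):
        X = np.random.default_rng(1).normal(size=(5, 8))
        model = fit_pca(X, 4)
        assert model.explained_variance_pct_.sum() == pytest.approx(100.0, abs=1e-6)

    def test_sign_convention_deterministic(self):
        X = np.random.default_rng(2).normal(size=(6, 5))
        l1 = fit_pca(X, 3).loadings_
        l2 = fit_pca(X, 3).loadings_
        assert np.array_equal(l1, l2)
        for a in range(3):
            j = np.argmax(np.abs(l1[:, a]))
            assert l1[j, a] > 0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((4, 3)), 1)

    def test_planted_two_axis_structure_captured(self):
        rng = np.random.default_rng(8)
        t1 = rng.normal(size=5)[:, None] * rng.normal(size=20)[None, :]
        t2 = rng.normal(size=5)[:, None] * rng.normal(size=20)[None, :]
        X = 5 * t1 + 3 * t2 + 0.01 * rng.normal(size=(5, 20))
        model = fit_pca(X, 2)
        assert model.r2_cum_[1] > 0.95


class TestQ2:
    def test_noiseless_rank_one_predictable(self):
        X = np.outer(np.arange(1.0, 7.0), [1.0, 2.0, 3.0, 0.5])
        q2 = q2_crossval(X, 1)
        assert q2[0] >= 0.99

    def test_white_noise_not_predictable(self):
        X = np.random.default_rng(3).normal(size=(10, 50))
        assert q2_crossval(X, 2).max() <= 0.5

    @given(seed=st.integers(0, 50))
    @settings(max_examples=15, deadline=None)
    def test_q2_never_exceeds_r2(self, seed):
        X = np.random.default_rng(seed).normal(size=(8, 6))
        model = fit_pca(X, 2)
        q2 = model.crossval_q2(X)
        assert (q2 <= model.r2_cum_[:2] + 1e-9).all()

    def test_component_count_beyond_refit_rank_rejected(self):
        X = np.random.default_rng(0).normal(size=(4, 6))
        with pytest.raises(ValueError):
            q2_crossval(X, 3)  # LOO refit on 3 samples has rank 2


class TestPLSDA:
    def test_first_component_weights_match_nipals_oracle(self):
        """Independent oracle: scikit-learn's NIPALS PLS2 on the centered
        one-hot response."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 4))
        y = np.array(["a", "a", "a", "b", "b", "b"])
        model = fit_plsda(X, y, n_components=2)
        Y = np.zeros((6, 2))
        Y[np.arange(6), (y == "b").astype(int)] = 1.0
        oracle = sklearn_pls.PLSRegression(n_components=2, scale=False).fit(
            X - X.mean(0), Y - Y.mean(0)
        )
        assert np.allclose(
            np.abs(model.x_weights_[:, 0]), np.abs(oracle.x_weights_[:, 0]), atol=1e-6
        )

    def test_planted_discriminant_selected_and_top_vip(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(10, 8))
        X[5:, 3] += 6.0  # feature 3 separates the groups
        y = ["g1"] * 5 + ["g2"] * 5
        model = fit_plsda(X, y, n_components=2, keep_per_component=2)
        assert 3 in model.selected_features_[0]
        assert int(np.argmax(model.vip_)) == 3

    def test_mean_squared_vip_is_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(9, 12))
        y = ["a", "b", "c"] * 3
        model = fit_plsda(X, y, n_components=3)
        assert (model.vip_**2).mean() == pytest.approx(1.0, abs=1e-6)

    def test_vip_formula_by_hand(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(8, 2))
        y = ["a"] * 4 + ["b"] * 4
        model = fit_plsda(X, y, n_components=2)
        w2 = model.x_weights_**2
        ssy = model.y_variance_explained_
        by_hand = np.sqrt(2 * (w2 @ ssy) / ssy.sum())
        assert np.allclose(model.vip_, by_hand, atol=1e-8)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError, match="class"):
            fit_plsda(X, ["same"] * 5, n_components=1)

    def test_singleton_class_warns(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.warns(UserWarning, match="single sample"):
            fit_plsda(X, ["a", "a", "a", "a", "b"], n_components=1)

    def test_cumulative_fitted_variance_non_decreasing(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(12, 10))
        y = ["a", "b", "c"] * 4
        model = fit_plsda(X, y, n_components=4)
        assert (model.explained_variance_pct_ > -1e-12).all()
        cum = np.cumsum(model.explained_variance_pct_)
        assert (np.diff(cum) >= -1e-9).all()

    def test_predict_recovers_separable_classes(self):
        rng = np.random.default_rng(30)
        X = rng.normal(size=(12, 6))
        X[6:, 0] += 8.0
        y = np.array(["lo"] * 6 + ["hi"] * 6)
        model = fit_plsda(X, y, n_components=2)
        assert (model.predict(X) == y).all()


class TestHCA:
    def test_identical_samples_merge_at_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        tree = hca(X, linkage="average")
        assert tree.heights()[0] == pytest.approx(0.0)

    def test_right_triangle_merge_order(self):
        # pairwise distances 3-4-5: closest pair (d=3) merges first
        X = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        tree = hca(X, metric="euclidean", linkage="average")
        assert sorted(tree.merges[0, :2].astype(int)) == [0, 1]
        assert tree.heights()[0] == pytest.approx(3.0)
        # average linkage: remaining leaf joins at (4 + 5) / 2
        assert tree.heights()[1] == pytest.approx(4.5)

    def test_nan_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="NaN"):
            hca(X)

    def test_newick_export_parses(self):
        X = np.random.default_rng(2).normal(size=(4, 3))
        nwk = hca(X).to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 3

    def test_outlier_profile_joins_last(self):
        design = IntensityDesign(outlier_group=4, seed=0)
        matrix, labels, _ = simulate_intensity_matrix(design)
        scaled = pareto_scale(np.log10(matrix))
        tree = hca(scaled, linkage="ward")
        from scipy.cluster.hierarchy import fcluster

        two = fcluster(tree.merges, 2, criterion="maxclust")
        outlier_mask = (labels == "group5").to_numpy()
        assert set(two[outlier_mask]).isdisjoint(set(two[~outlier_mask]))


class TestAnovaSelection:
    def test_two_group_f_equals_t_squared(self):
        from scipy import stats

        rng = np.random.default_rng(9)
        X = rng.normal(size=(8, 5))
        labels = ["a"] * 4 + ["b"] * 4
        ranked = top_features_anova(X, labels, n=5)
        for j in ranked.index:
            t, p = stats.ttest_ind(X[:4, j], X[4:, j], equal_var=True)
            assert ranked.loc[j, "F"] == pytest.approx(t**2, abs=1e-8)
            assert ranked.loc[j, "p"] == pytest.approx(p, abs=1e-8)

    def test_planted_effect_ranks_first(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(12, 20))
        X[:6, 7] += 5.0
        ranked = top_features_anova(X, ["a"] * 6 + ["b"] * 6, n=20)
        assert ranked.index[0] == 7

    def test_n_larger_than_feature_count_returns_all(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        ranked = top_features_anova(X, ["a", "b"] * 3, n=100)
        assert len(ranked) == 4

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            top_features_anova(np.ones((4, 2)), ["a", "a", "b", "b"], n=0)

    def test_singleton_group_falls_back_with_warning(self):
        X = np.random.default_rng(1).normal(size=(3, 4))
        with pytest.warns(UserWarning, match="variance ranking"):
            ranked = top_features_anova(X, ["a", "a", "b"], n=2)
        assert len(ranked) == 2

    def test_fisher_lsd_pairwise_count(self):
        X = np.random.default_rng(2).normal(size=(9, 3))
        out = fisher_lsd(X, ["a", "b", "c"] * 3, feature=1)
        assert len(out) == 3  # 3 choose 2 group pairs
        assert ((out.p >= 0) & (out.p <= 1)).all()


class TestHeatmap:
    def test_identical_samples_adjacent(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=6)
        X = np.vstack([base, base + 1e-9, rng.normal(size=(3, 6)) * 4])
        hm = heatmap_data(np.abs(X) + 1, ["a", "a", "b", "b", "c"], n_top=6)
        order = hm.sample_order
        assert abs(order.index("0") - order.index("1")) == 1

    def test_row_count_contract(self):
        X = np.abs(np.random.default_rng(6).normal(size=(6, 10))) + 1
        hm = heatmap_data(X, ["a", "a", "a", "b", "b", "b"], n_top=4)
        assert hm.values.shape[0] == 4
        hm_all = heatmap_data(X, ["a", "a", "a", "b", "b", "b"], n_top=99)
        assert hm_all.values.shape[0] == 10

    def test_block_structure_recovered(self):
        rng = np.random.default_rng(7)
        X = rng.lognormal(1, 0.1, size=(6, 8))
        X[:3, :4] *= 10.0
        X[3:, 4:] *= 10.0
        hm = heatmap_data(X, ["a"] * 3 + ["b"] * 3, n_top=8)
        first_half = set(hm.sample_order[:3])
        assert first_half in ({"0", "1", "2"}, {"3", "4", "5"})


class TestImputation:
    def test_half_minimum_fill(self):
        X = pd.DataFrame([[1.0, np.nan], [4.0, 2.0]])
        out = impute_missing(X)
        assert out.iloc[0, 1] == pytest.approx(0.5)
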