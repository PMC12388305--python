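"""UV scaling, PCA, the OPLS estimator and grouped cross-validation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from sakemet.chemometrics import (
    fit_model,
    fit_opls,
    grouped_q2,
    make_grouped_folds,
    pca,
    uv_scale,
)

from conftest import random_regression


class TestUvScale:
    def test_hand_example(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        scaled, params = uv_scale(df)
        np.testing.assert_allclose(scaled["x"], [-1.0, 0.0, 1.0])
        assert params.mean["x"] == 2.0 and params.sd["x"] == 1.0

    def test_idempotent_with_params(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 0.0, 4.0]})
        scaled, params = uv_scale(df)
        rescaled, _ = uv_scale(scaled, params=None)
        np.testing.assert_allclose(rescaled.to_numpy(), scaled.to_numpy(), atol=1e-12)
        # applying stored params to new data uses the training statistics
        applied, _ = uv_scale(df, params=params)
        np.testing.assert_allclose(applied.to_numpy(), scaled.to_numpy(), atol=1e-12)

    def test_constant_column_dropped_and_recorded(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "const": [7.0, 7.0, 7.0]})
        scaled, params = uv_scale(df)
        assert list(scaled.columns) == ["x"]
        assert params.dropped == ["const"]

    def test_all_constant_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(ValueError, match="zero variance"):
            uv_scale(df)


class TestPca:
    def test_rank_one_single_component(self):
        v = np.array([1.0, -1.0, 2.0, -2.0])
        X = np.outer(v, [1.0, 2.0, 3.0])
        res = pca(X)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_uncorrelated_columns_split_evenly(self):
        X = np.array([[1.0, 1.0], [-1.0, 1.0], [1.0, -1.0], [-1.0, -1.0]])
        res = pca(X)
        np.testing.assert_allclose(res.explained_variance_ratio, [0.5, 0.5])

    def test_full_rank_reconstruction_and_orthonormal_loadings(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((6, 4))
        X -= X.mean(axis=0)
        res = pca(X)
        np.testing.assert_allclose(
            res.scores @ res.loadings.T, X, atol=1e-8
        )
        gram = res.loadings.T @ res.loadings
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)
        assert res.explained_variance_ratio.sum() <= 1 + 1e-12

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            pca(np.zeros((3, 3)))


class TestOplsCore:
    def test_exact_fit_single_informative_column(self):
        # columns made mutually orthogonal in-sample so the single
        # predictive component can isolate the informative one exactly
        rng = np.random.default_rng(0)
        raw = rng.standard_normal((20, 5))
        raw -= raw.mean(axis=0)
        X, _ = np.linalg.qr(raw)
        X /= X.std(axis=0, ddof=1)
        y = 2.0 * X[:, 2]
        y = (y - y.mean()) / y.std(ddof=1)
        core = fit_opls(X, y, 0)
        assert core["r2"] == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_zero_orthogonal_equals_pls1(self, seed):
        """With no orthogonal components, OPLS is one-component PLS1."""
        X, y = random_regression(seed)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        core = fit_opls(Xs, ys, 0)
        sk = PLSRegression(n_components=1, scale=False).fit(Xs, ys)
        np.testing.assert_allclose(
            core["y_hat"], sk.predict(Xs).ravel(), atol=1e-8
        )

    @pytest.mark.parametrize("n_ortho", [1, 2, 3])
    def test_orthogonality_of_score_blocks(self, n_ortho):
        X, y = random_regression(seed=10 + n_ortho)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        core = fit_opls(Xs, ys, n_ortho)
        for j in range(n_ortho):
            assert abs(core["t"] @ core["T_o"][:, j]) < 1e-8
        assert np.linalg.norm(core["w"]) == pytest.approx(1.0)

    def test_orthogonal_component_removal_recovers_clean_scores(self):
        """Augmenting X with a y-orthogonal structured factor and removing
        one orthogonal component reproduces the clean predictive scores."""
        rng = np.random.default_rng(7)
        n, p = 30, 12
        y = rng.standard_normal(n)
        y = (y - y.mean()) / y.std(ddof=1)
        p1 = rng.standard_normal(p)
        X_clean = np.outer(y, p1)
        t_orth = rng.standard_normal(n)
        t_orth -= (t_orth @ y) / (y @ y) * y  # orthogonal to y
        p2 = rng.standard_normal(p)
        X_aug = X_clean + np.outer(t_orth, p2)

        clean = fit_opls(X_clean, y, 0)
        aug = fit_opls(X_aug, y, 1)
        np.testing.assert_allclose(aug["t"], clean["t"], atol=1e-6)

    def test_constant_response_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError, match="constant"):
            fit_opls(X, np.ones(10), 0)

    def test_predictions_invariant_to_variable_order_and_affine_rescaling(self):
        X, y = random_regression(seed=3, n=24, p=10)
        df = pd.DataFrame(X, columns=[f"v{i}" for i in range(10)])
        m1 = fit_model(df, y, 1)
        perm = list(reversed(df.columns))
        m2 = fit_model(df[perm], y, 1)
        np.testing.assert_allclose(m1.predict(df), m2.predict(df[perm]), atol=1e-8)
        # affine rescaling of the raw variables is absorbed by UV scaling
        df3 = df * 7.5 + 3.0
        m3 = fit_model(df3, y, 1)
        np.testing.assert_allclose(m1.predict(df), m3.predict(df3), atol=1e-8)

    def test_rmse_on_original_scale(self):
        X, y = random_regression(seed=5)
        y = 3.0 * y + 10.0
        m = fit_model(pd.DataFrame(X), y, 0)
        y_hat = m.predict(pd.DataFrame(X))
        assert m.rmse == pytest.approx(np.sqrt(np.mean((y - y_hat) ** 2)))


class TestGroupedFolds:
    def test_26_samples_7_folds_sizes(self):
        samples = np.repeat([f"S{i}" for i in range(26)], 3)
        folds = make_grouped_folds(samples, k=7, seed=0)
        sizes = sorted(
            len(set(samples[folds == f])) for f in np.unique(folds)
        )
        assert sizes == [3, 3, 4, 4, 4, 4, 4]

    def test_replicates_share_fold(self):
        samples = np.repeat([f"S{i}" for i in range(10)], 3)
        folds = make_grouped_folds(samples, k=5, seed=1)
        for s in set(samples):
            assert len(set(folds[samples == s])) == 1

    def test_deterministic_given_seed(self):
        samples = np.repeat([f"S{i}" for i in range(12)], 3)
        a = make_grouped_folds(samples, k=4, seed=9)
        b = make_grouped_folds(samples, k=4, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            make_grouped_folds(["a", "b", "c"], k=1)

    def test_more_folds_than_samples_rejected(self):
        with pytest.raises(ValueError):
            make_grouped_folds(["a", "a", "b"], k=3)


class TestGroupedQ2:
    def _replicated_problem(self, seed=0, n_samples=24, p=15, noise=0.0):
        """One dominant latent component drives both X and y, so a single
        predictive component is the right model."""
        rng = np.random.default_rng(seed)
        t = rng.standard_normal(n_samples)
        loadings = rng.standard_normal(p)
        Xs = np.outer(t, loadings) + 0.05 * rng.standard_normal((n_samples, p))
        ys = t + noise * rng.standard_normal(n_samples)
        X = np.repeat(Xs, 3, axis=0) * (1 + 0.01 * rng.standard_normal((n_samples * 3, p)))
        y = np.repeat(ys, 3)
        samples = np.repeat([f"S{i}" for i in range(n_samples)], 3)
        return X, y, samples

    def test_noiseless_signal_limit(self):
        X, y, samples = self._replicated_problem()
        folds = make_grouped_folds(samples, k=6, seed=0)
        q2, press = grouped_q2(X, y, 0, folds)
        assert q2 > 0.99
        assert press >= 0

    def test_q2_never_above_r2_under_global_scaling(self):
        """With one global scaling, cross-validated Q2 cannot beat the
        in-sample R2; per-fold rescaling may exceed it only marginally."""
        for seed in range(12):
            X, y, samples = self._replicated_problem(seed=seed, noise=0.5)
            folds = make_grouped_folds(samples, k=6, seed=seed)
            r2 = fit_model(pd.DataFrame(X), y, 0).r2
            q2_global, _ = grouped_q2(X, y, 0, folds, scale_in_fold=False)
            assert q2_global <= r2
            q2_fold, _ = grouped_q2(X, y, 0, folds, scale_in_fold=True)
            assert q2_fold <= r2 + 0.1

    def test_invariant_to_fold_relabeling(self):
        X, y, samples = self._replicated_problem(seed=2, noise=0.3)
        folds = make_grouped_folds(samples, k=5, seed=2)
        relabel = np.array([3, 4, 0, 2, 1])
        q2_a, _ = grouped_q2(X, y, 1, folds)
        q2_b, _ = grouped_q2(X, y, 1, relabel[folds])
        assert q2_a == pytest.approx(q2_b, abs=1e-12)

    def test_simca_style_global_scaling_differs_but_close(self):
        X, y, samples = self._replicated_problem(seed=6, noise=0.3)
        folds = make_grouped_folds(samples, k=6, seed=3)
        q2_fold, _ = grouped_q2(X, y, 0, folds, scale_in_fold=True)
        q2_global, _ = grouped_q2(X, y, 0, folds, scale_in_fold=False)
        assert q2_fold != q2_global
        assert abs(q2_fold - q2_global) < 0.2
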