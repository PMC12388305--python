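"""Component selection, permutation validation, CV-ANOVA and VIPpred."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sakemet.chemometrics import fit_model, make_grouped_folds
from sakemet.modeling import (
    cv_anova,
    permutation_test,
    reduce_until_valid,
    select_orthogonal_components,
    sign_and_select,
    vip_pred,
)
from sakemet import modeling

from conftest import random_regression


def _replicated(seed=0, n_samples=20, p=30, noise=0.1):
    """Factor-structured X (three latent blocks), y driven by the first
    factor — the correlation structure typical of metabolome peak tables."""
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((n_samples, 3))
    block = np.arange(p) % 3
    lam = rng.uniform(0.85, 0.98, p)
    Xs = lam * F[:, block] + np.sqrt(1 - lam**2) * rng.standard_normal((n_samples, p))
    ys = F[:, 0] + noise * rng.standard_normal(n_samples)
    X = np.repeat(Xs, 3, axis=0)
    y = np.repeat(ys, 3)
    samples = np.repeat([f"S{i:02d}" for i in range(n_samples)], 3)
    return pd.DataFrame(X, columns=[f"v{i}" for i in range(p)]), y, samples


class TestComponentSelection:
    def _fake(self, q2_seq):
        def evaluate(a_o):
            if a_o >= len(q2_seq):
                return None
            return q2_seq[a_o], 0.9
        return evaluate

    def test_accepts_while_q2_increases(self):
        trace = select_orthogonal_components(
            np.zeros((6, 2)), np.arange(6.0), folds=None,
            q2_fn=self._fake([0.40, 0.55, 0.52]),
        )
        assert trace.chosen == 1
        assert trace.stopping_reason == "Q2 stopped increasing"
        assert [v[0] for v in trace.visited] == [0, 1, 2]

    def test_monotone_decreasing_keeps_zero(self):
        trace = select_orthogonal_components(
            np.zeros((6, 2)), np.arange(6.0), folds=None,
            q2_fn=self._fake([0.40, 0.35, 0.30]),
        )
        assert trace.chosen == 0

    def test_exhausted_components_stop_search(self):
        trace = select_orthogonal_components(
            np.zeros((6, 2)), np.arange(6.0), folds=None,
            q2_fn=self._fake([0.1, 0.2]),
        )
        assert trace.chosen == 1
        assert "extractable" in trace.stopping_reason

    def test_accepted_q2_strictly_increasing_on_data(self):
        X, y, samples = _replicated(seed=1)
        folds = make_grouped_folds(samples, k=5, seed=1)
        trace = select_orthogonal_components(X, y, folds, max_n_ortho=4)
        accepted = [q2 for a_o, _, q2 in trace.visited[: trace.chosen + 1]]
        assert all(b > a for a, b in zip(accepted, accepted[1:]))


class TestPermutationTest:
    def test_anchor_equals_model_fit(self):
        X, y, samples = _replicated(seed=2)
        folds = make_grouped_folds(samples, k=5, seed=2)
        report = permutation_test(X, y, samples, 0, folds, n_perm=10, seed=0)
        m = fit_model(X, y, 0)
        assert report.r2_model == pytest.approx(m.r2, abs=1e-10)
        assert report.n_perm == 10
        assert np.all((report.correlations >= 0) & (report.correlations <= 1))

    def test_strong_signal_validates(self):
        X, y, samples = _replicated(seed=3, noise=0.05)
        folds = make_grouped_folds(samples, k=5, seed=3)
        report = permutation_test(X, y, samples, 0, folds, n_perm=50, seed=1)
        assert report.valid_flag
        # permuted Q2 mass sits far below the real model's Q2
        assert np.nanmean(report.q2_perm < report.q2_model) > 0.95

    def test_null_response_fails_validation(self):
        rng = np.random.default_rng(11)
        X, y, samples = _replicated(seed=4)
        y_null = np.repeat(rng.standard_normal(20), 3)
        folds = make_grouped_folds(samples, k=5, seed=4)
        report = permutation_test(X, y_null, samples, 0, folds, n_perm=50, seed=2)
        assert not report.valid_flag

    def test_permutation_respects_replicate_ties(self):
        """Permuted y must stay constant within each sample's injections."""
        X, y, samples = _replicated(seed=5)
        folds = make_grouped_folds(samples, k=5, seed=5)
        # run with n_perm=1 and reconstruct what the permutation did
        report = permutation_test(X, y, samples, 0, folds, n_perm=1, seed=9)
        assert report.correlations.shape == (1,)


class TestReduceUntilValid:
    def test_strong_signal_keeps_components_and_validates(self):
        X, y, samples = _replicated(seed=6, noise=0.05)
        folds = make_grouped_folds(samples, k=5, seed=6)
        trace = select_orthogonal_components(X, y, folds, max_n_ortho=2)
        model, report = reduce_until_valid(
            X, y, samples, trace, folds, n_perm=20, seed=0
        )
        assert report.valid_flag
        assert model.n_ortho == report.n_ortho <= trace.chosen
        assert model.q2 > 0.8

    def test_steps_down_until_valid(self, monkeypatch):
        calls = []

        def fake_permutation(X, y, sample_ids, n_ortho, folds, **kw):
            calls.append(n_ortho)
            return modeling.PermutationReport(
                n_perm=0,
                correlations=np.zeros(0),
                r2_perm=np.zeros(0),
                q2_perm=np.zeros(0),
                r2_model=0.9,
                q2_model=0.8,
                r2_intercept=0.5 if n_ortho >= 2 else 0.1,
                q2_intercept=-0.5,
                valid_flag=n_ortho < 2,
                n_ortho=n_ortho,
            )

        monkeypatch.setattr(modeling, "permutation_test", fake_permutation)
        X, y, samples = _replicated(seed=7)
        folds = make_grouped_folds(samples, k=5, seed=7)
        trace = modeling.ComponentSearchTrace(visited=[], chosen=2)
        model, report = reduce_until_valid(X, y, samples, trace, folds)
        assert calls == [2, 1]
        assert model.n_ortho == 1

    def test_never_valid_returns_zero_flagged(self, monkeypatch):
        def always_invalid(X, y, sample_ids, n_ortho, folds, **kw):
            return modeling.PermutationReport(
                n_perm=0, correlations=np.zeros(0), r2_perm=np.zeros(0),
                q2_perm=np.zeros(0), r2_model=0.5, q2_model=0.1,
                r2_intercept=0.9, q2_intercept=0.5, valid_flag=False,
                n_ortho=n_ortho,
            )

        monkeypatch.setattr(modeling, "permutation_test", always_invalid)
        X, y, samples = _replicated(seed=8)
        folds = make_grouped_folds(samples, k=5, seed=8)
        trace = modeling.ComponentSearchTrace(visited=[], chosen=2)
        model, report = reduce_until_valid(X, y, samples, trace, folds)
        assert model.n_ortho == 0
        assert not report.valid_flag


class TestCvAnova:
    def test_near_perfect_prediction_tiny_p(self):
        f, p = cv_anova(press=0.01, ss_tot=100.0, n=78, a=3)
        assert p < 1e-12

    def test_press_equals_sstot_large_p(self):
        f, p = cv_anova(press=50.0, ss_tot=50.0, n=30, a=2)
        assert f == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_direct_f_cdf(self):
        press, ss_tot, n, a = 12.0, 40.0, 21, 4
        f, p = cv_anova(press, ss_tot, n, a)
        f_ref = ((ss_tot - press) / a) / (press / (n - a - 1))
        assert f == pytest.approx(f_ref, abs=1e-12)
        assert p == pytest.approx(1 - stats.f.cdf(f_ref, a, n - a - 1), abs=1e-9)

    def test_bad_degrees_of_freedom(self):
        with pytest.raises(ValueError):
            cv_anova(1.0, 2.0, n=3, a=4)


class TestVip:
    def test_uniform_weights_give_unit_vip(self):
        X, y = random_regression(seed=0, n=30, p=8)
        m = fit_model(pd.DataFrame(X), y, 0)
        m.w = np.ones(8) / np.sqrt(8)
        vips = vip_pred(m)
        np.testing.assert_allclose(vips, 1.0)

    def test_single_active_variable(self):
        X, y = random_regression(seed=1, n=20, p=4)
        m = fit_model(pd.DataFrame(X), y, 0)
        m.w = np.array([0.0, 1.0, 0.0, 0.0])
        vips = vip_pred(m)
        np.testing.assert_allclose(vips, [0.0, 2.0, 0.0, 0.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_normalization_identity(self, seed):
        X, y = random_regression(seed=seed, n=30, p=50)
        m = fit_model(pd.DataFrame(X), y, seed % 3)
        vips = vip_pred(m)
        assert (vips**2).sum() == pytest.approx(50, abs=1e-8)
        assert (vips**2).mean() == pytest.approx(1.0, abs=1e-8)


class TestSignAndSelect:
    def _model_with_vips(self, vips):
        """VIPs must satisfy mean(vip^2) = 1; w is set accordingly."""
        vips = np.asarray(vips, dtype=float)
        p = len(vips)
        assert (vips**2).sum() == pytest.approx(p), "inconsistent VIP target"
        X, y = random_regression(seed=2, n=20, p=p)
        m = fit_model(pd.DataFrame(X, columns=[f"v{i}" for i in range(p)]), y, 0)
        m.w = vips / np.sqrt(p)  # unit norm; vip = sqrt(p)|w|
        return m

    def test_positively_proportional_variable_gets_plus(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(12)
        means = pd.DataFrame({"v0": x, "v1": -x})
        m = self._model_with_vips([1.0, 1.0])
        rep = sign_and_select(m, means, 2.0 * x + 1.0)
        assert rep.table.at["v0", "signed_vip"] > 0
        assert rep.table.at["v1", "signed_vip"] < 0

    def test_threshold_is_strict(self):
        # one VIP above 1.5, one exactly at 1.5 (excluded), rest below
        filler = np.sqrt((10 - 1.6**2 - 1.5**2) / 8)
        m = self._model_with_vips([1.6, 1.5] + [filler] * 8)
        rng = np.random.default_rng(1)
        means = pd.DataFrame(
            rng.standard_normal((10, 10)), columns=[f"v{i}" for i in range(10)]
        )
        rep = sign_and_select(m, means, rng.standard_normal(10), threshold=1.5)
        assert rep.selected == ["v0"]

    def test_zero_variance_variable_never_selected(self):
        filler = np.sqrt((8 - 2 * 1.6**2) / 6)
        m = self._model_with_vips([1.6, 1.6] + [filler] * 6)
        means = pd.DataFrame(
            {"v0": np.ones(10), "v1": np.arange(10.0)}
            | {f"v{i}": np.random.default_rng(i).standard_normal(10) for i in range(2, 8)}
        )
        rep = sign_and_select(m, means, np.arange(10.0))
        assert rep.table.at["v0", "signed_vip"] == 0.0
        assert not rep.table.at["v0", "selected"]
        assert rep.table.at["v1", "selected"]
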