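import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wqs2i
from wqs2i import (MixtureData, quantize_columns, weights_from_v,
                   penalized_objective, fit_single_wqs, signal_value,
                   ensemble_average_weights, validate_single, model_aic,
                   train_validation_split, wqs_ensemble, fit_wqs)
from wqs2i._glm import glm_fit


class TestWeightsFromV:
    @pytest.mark.parametrize("v, expected", [
        ((1, 1, 1, 1), (0.25, 0.25, 0.25, 0.25)),
        ((2, 0, 0), (1, 0, 0)),
        ((1, -1), (0.5, 0.5)),
    ])
    def test_examples(self, v, expected):
        assert np.allclose(weights_from_v(v), expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="v = 0"):
            weights_from_v(np.zeros(3))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=10))
    def test_simplex_property(self, v):
        v = np.asarray(v)
        if float(v @ v) == 0.0:  # all-zero (or underflowing) input
            return
        w = weights_from_v(v)
        assert abs(w.sum() - 1) < 1e-8
        assert ((w >= 0) & (w <= 1)).all()


class TestPenalizedObjective:
    def test_lambda_zero_is_rss(self, small_data):
        theta = (0.5, 0.8, np.array([1.0, 2.0, 0.5, 1.0]), None)
        w = weights_from_v(theta[2])
        resid = small_data.y - (0.5 + 0.8 * small_data.Q @ w)
        assert penalized_objective(theta, small_data, 0.0) == \
            pytest.approx(float(resid @ resid), abs=1e-10)

    def test_scale_invariance_in_v(self, small_data):
        v = np.array([1.0, -0.3, 2.0, 0.1])
        a = penalized_objective((0.1, 0.5, v, None), small_data, 7.0)
        b = penalized_objective((0.1, 0.5, 2 * v, None), small_data, 7.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_hand_value(self):
        # y=(1,0), rows of Q (1,0),(0,0), beta0=0, beta1=1, v=(1,0), lam=2:
        # perfect fit, penalty 2*(1+0) = 2
        data = MixtureData(y=np.array([1.0, 0.0]),
                           Q=np.array([[1, 0], [0, 0]]), q=2)
        obj = penalized_objective((0.0, 1.0, np.array([1.0, 0.0]), None),
                                  data, 2.0)
        assert obj == pytest.approx(2.0, abs=1e-5)

    def test_negative_lambda_rejected(self, small_data):
        with pytest.raises(ValueError):
            penalized_objective((0, 1, np.ones(4), None), small_data, -1.0)


class TestFitSingleWQS:
    def test_null_data_beta_small_and_nonnegative(self):
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            Q = quantize_columns(rng.standard_normal((1000, 3)), 4)
            data = MixtureData(y=rng.standard_normal(1000), Q=Q, q=4)
            fit = fit_single_wqs(data, "positive", lam=0.0)
            assert fit.beta1 >= 0
            assert fit.beta1 < 0.1

    def test_recovers_known_mixture(self):
        rng = np.random.default_rng(7)
        n, c = 500, 3
        Q = quantize_columns(rng.standard_normal((n, c)), 4)
        y = 1.0 * (0.7 * Q[:, 0] + 0.3 * Q[:, 1]) + rng.normal(0, 0.5, n)
        fit = fit_single_wqs(MixtureData(y=y, Q=Q, q=4), "positive", lam=0.0)
        assert fit.converged
        assert fit.beta1 == pytest.approx(1.0, abs=0.1)
        assert np.allclose(fit.w, [0.7, 0.3, 0.0], atol=0.1)

    def test_shrinkage_monotonically_sparsifies(self, small_data):
        sums = []
        for lam in (0.0, 10.0, 100.0, 1000.0):
            fit = fit_single_wqs(small_data, "positive", lam=lam)
            sums.append(np.sqrt(fit.w).sum())
        assert all(a >= b - 1e-6 for a, b in zip(sums, sums[1:]))

    def test_grid_oracle_not_better_than_optimizer(self):
        """Exhaustive simplex search (resolution 0.02, OLS-profiled
        beta0/beta1) cannot beat the optimizer by more than 1e-3."""
        rng = np.random.default_rng(3)
        n, c = 100, 3
        Q = quantize_columns(rng.standard_normal((n, c)), 4)
        y = 0.6 * (0.5 * Q[:, 0] + 0.5 * Q[:, 2]) + rng.normal(0, 0.7, n)
        data = MixtureData(y=y, Q=Q, q=4)
        fit = fit_single_wqs(data, "positive", lam=0.0)
        best = np.inf
        steps = np.arange(0, 51)
        for i in steps:
            for j in steps[: 51 - i]:
                w = np.array([i, j, 50 - i - j]) / 50.0
                x = Q @ w
                X = np.column_stack([np.ones(n), x])
                b = np.linalg.lstsq(X, y, rcond=None)[0]
                b[1] = max(b[1], 0.0)
                r = y - X @ b
                best = min(best, float(r @ r))
        assert fit.objective_value <= best + 1e-3

    def test_negative_direction_bound_holds(self, small_data):
        fit = fit_single_wqs(small_data, "negative", lam=0.0)
        assert fit.beta1 <= 0


class TestSignalValue:
    @pytest.mark.parametrize("t, kind, expected", [
        ((1, 2), "t2", (1, 4)),
        ((-3, 3), "abst", (3, 3)),
        ((5, -1), "one", (1, 1)),
        ((0, 1), "expt", (1, np.e)),
    ])
    def test_examples(self, t, kind, expected):
        assert np.allclose(signal_value(np.array(t, float), kind), expected)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown signal kind"):
            signal_value(np.ones(2), "bogus")


class TestEnsembleAverage:
    def test_equal_signals_is_plain_mean(self):
        W = np.array([[0.6, 0.4], [0.2, 0.8]])
        assert np.allclose(ensemble_average_weights(W, [1, 1]), [0.4, 0.6])

    def test_degenerate_signal_selects_one_row(self):
        W = np.array([[0.6, 0.4], [0.2, 0.8]])
        assert np.allclose(ensemble_average_weights(W, [1, 0]), W[0])

    def test_hand_weighted_mean_to_five_decimals(self):
        W = np.array([[0.6, 0.4], [0.2, 0.8]])
        w_bar = ensemble_average_weights(W, [0.512, 0.008])
        assert np.round(w_bar, 5).tolist() == [0.59385, 0.40615]

    def test_all_zero_signals_rejected(self):
        with pytest.raises(ValueError, match="no informative bootstrap"):
            ensemble_average_weights(np.array([[1.0, 0.0]]), [0.0])


class TestValidateSingle:
    def test_matches_closed_form_ols(self, small_data):
        w = np.array([0.5, 0.3, 0.1, 0.1])
        fit = validate_single(w, small_data)
        x = small_data.Q @ w
        slope = np.cov(small_data.y, x)[0, 1] / np.var(x, ddof=1)
        assert fit.coef("wqs") == pytest.approx(slope, rel=1e-10)

    def test_one_hot_weights_collapse_to_single_column(self, small_data):
        w = np.array([0.0, 0.0, 1.0, 0.0])
        fit = validate_single(w, small_data)
        X = np.column_stack([np.ones(small_data.n), small_data.Q[:, 2]])
        b = np.linalg.lstsq(X, small_data.y, rcond=None)[0]
        assert fit.coef("wqs") == pytest.approx(b[1], rel=1e-10)

    def test_logit_recovers_log_odds_slope(self):
        rng = np.random.default_rng(11)
        n = 5000
        Q = quantize_columns(rng.standard_normal((n, 2)), 4)
        w = np.array([0.5, 0.5])
        eta = -1.0 + 0.5 * (Q @ w)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = validate_single(w, MixtureData(y=y, Q=Q, q=4, link="logit"))
        assert abs(fit.coef("wqs") - 0.5) < 3 * fit.se("wqs")

    def test_singular_design_names_columns(self, rng):
        Q = quantize_columns(rng.standard_normal((50, 2)), 4)
        Z = Q[:, [0]].astype(float)  # duplicates the index when w is one-hot
        data = MixtureData(y=rng.standard_normal(50), Q=Q, Z=Z,
                           covariate_names=["dup"], q=4)
        with pytest.raises(ValueError, match="singular design"):
            validate_single(np.array([1.0, 0.0]), data)


class TestModelAic:
    def test_gaussian_closed_form(self):
        # craft y with RSS exactly 10 against X = [1, x]: residual
        # orthogonal to the design, scaled to squared norm 10
        rng = np.random.default_rng(0)
        n = 10
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        r = rng.standard_normal(n)
        r -= X @ np.linalg.lstsq(X, r, rcond=None)[0]
        r *= np.sqrt(10.0 / (r @ r))
        fit = glm_fit(r, X, ["intercept", "x"], link="identity")
        expected = 10 * (1 + np.log(2 * np.pi)) + 2 * 3
        assert model_aic(fit) == pytest.approx(expected, abs=1e-8)

    def test_extra_noise_covariate_costs_two_minus_deviance_drop(self, rng):
        n = 200
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = x + rng.standard_normal(n)
        X1 = np.column_stack([np.ones(n), x])
        X2 = np.column_stack([X1, z])
        f1 = glm_fit(y, X1, ["b0", "x"], link="identity")
        f2 = glm_fit(y, X2, ["b0", "x", "z"], link="identity")
        drop = 2 * (f2.llf - f1.llf)
        assert f2.aic - f1.aic == pytest.approx(2 - drop, abs=1e-8)


class TestSplitAndEnsemble:
    def test_split_sizes_and_disjointness(self, small_data, rng):
        train, valid = train_validation_split(small_data, 0.6, rng)
        assert train.n == 180 and valid.n == 120

    def test_logit_split_is_stratified(self, logit_data, rng):
        train, valid = train_validation_split(logit_data, 0.6, rng)
        assert abs(train.y.mean() - logit_data.y.mean()) < 0.02

    def test_ensemble_rows_on_simplex_and_deterministic(self, small_data):
        train, _ = train_validation_split(small_data, 0.6,
                                          np.random.default_rng(0))
        e1 = wqs_ensemble(train, "positive", 0.0, B=10,
                          rng=np.random.default_rng(42))
        e2 = wqs_ensemble(train, "positive", 0.0, B=10,
                          rng=np.random.default_rng(42))
        assert np.allclose(e1.per_bootstrap_w.sum(axis=1), 1, atol=1e-8)
        assert np.array_equal(e1.per_bootstrap_w, e2.per_bootstrap_w)
        assert abs(e1.w_bar.sum() - 1) < 1e-8
        lo = e1.per_bootstrap_w.min(axis=0) - 1e-12
        hi = e1.per_bootstrap_w.max(axis=0) + 1e-12
        assert ((e1.w_bar >= lo) & (e1.w_bar <= hi)).all()

    def test_full_run_finds_positive_effect(self, small_data):
        ens, final = fit_wqs(small_data, "positive", lam=0.0, B=20, seed=3)
        assert final.coef("wqs") > 0.3
        assert final.pvalue("wqs") < 0.01
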