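import logging

import numpy as np
import pytest

from wqs2i import (MixtureData, quantize_columns, penalized_objective,
                   penalized_objective_2i, initialize_two_index,
                   fit_two_index_joint, fit_two_index_bootstrap,
                   index_tolerance, tolerance_signal, finalize_two_index,
                   average_and_finalize, fit_2iwqs, simulate_dataset,
                   exchangeable_correlation, TruthSpec)
from wqs2i.twoindex import FALLBACK_WARNING


@pytest.fixture
def bidirectional_data():
    """c=6 mixture with two harmful and two protective components."""
    truth = TruthSpec(beta1p=0.6, beta1n=-0.6,
                      wp=[0.6, 0.4, 0, 0, 0, 0], wn=[0, 0, 0.5, 0.5, 0, 0])
    R = exchangeable_correlation(6, 0.3)
    return simulate_dataset(R, truth, n=800, seed=21), truth


@pytest.fixture
def positive_only_data():
    truth = TruthSpec(beta1p=0.8, beta1n=0.0,
                      wp=[0.6, 0.4, 0, 0, 0, 0], wn=np.ones(6) / 6)
    R = exchangeable_correlation(6, 0.3)
    return simulate_dataset(R, truth, n=800, seed=22), truth


class TestObjective2i:
    def test_hand_value(self):
        # y=(2,0), Q rows (1,0),(0,0): predictions (1,0), loss 1,
        # penalty 1*(1+1) = 2, total 3
        data = MixtureData(y=np.array([2.0, 0.0]),
                           Q=np.array([[1, 0], [0, 0]]), q=2)
        obj = penalized_objective_2i(
            (0.0, 1.0, -1.0, np.array([1.0, 0.0]), np.array([0.0, 1.0]), None),
            data, 1.0)
        assert obj == pytest.approx(3.0, abs=1e-5)

    def test_zero_negative_term_matches_single_index(self, small_data):
        vp = np.array([1.0, 0.5, 2.0, 0.3])
        obj2 = penalized_objective_2i(
            (0.2, 0.7, 0.0, vp, np.ones(4), None), small_data, 0.0)
        obj1 = penalized_objective((0.2, 0.7, vp, None), small_data, 0.0)
        assert obj2 == pytest.approx(obj1, rel=1e-12)

    def test_invariant_to_rescaling_each_v(self, small_data):
        vp = np.array([1.0, -0.5, 0.1, 2.0])
        vn = np.array([0.3, 1.0, -1.0, 0.2])
        a = penalized_objective_2i((0.1, 0.4, -0.2, vp, vn, None),
                                   small_data, 5.0)
        b = penalized_objective_2i((0.1, 0.4, -0.2, 3 * vp, 0.5 * vn, None),
                                   small_data, 5.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_sign_violation_rejected(self, small_data):
        with pytest.raises(ValueError, match="sign constraints"):
            penalized_objective_2i(
                (0, -0.1, 0.0, np.ones(4), np.ones(4), None), small_data, 0.0)


class TestIndexTolerance:
    def test_orthogonal_indices_have_unit_tolerance(self):
        n = 40
        ip = np.tile([1.0, -1.0], n // 2)
        in_ = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        tol_p, tol_n = index_tolerance(ip, in_)
        assert tol_p == pytest.approx(1.0, abs=1e-12)
        assert tol_n == pytest.approx(1.0, abs=1e-12)

    def test_perfect_collinearity(self, rng):
        ip = rng.standard_normal(50)
        tol_p, tol_n = index_tolerance(ip, 2.0 * ip)
        assert tol_p < 1e-10 and tol_n < 1e-10

    def test_designed_r_squared(self):
        # in = sqrt(0.75) u + 0.5 v with u, v mean-zero orthonormal:
        # R^2 of in on u is exactly 0.75, so tol = 0.25 and VIF = 4
        n = 64
        t = np.arange(n)
        u = np.cos(2 * np.pi * t / n)
        v = np.sin(2 * np.pi * t / n)
        u /= np.sqrt(u @ u)
        v /= np.sqrt(v @ v)
        in_ = np.sqrt(0.75) * u + 0.5 * v
        _, tol_n = index_tolerance(u, in_)
        assert tol_n == pytest.approx(0.25, abs=1e-10)
        assert 1.0 / tol_n == pytest.approx(4.0, abs=1e-8)

    def test_constant_index_rejected(self):
        with pytest.raises(ValueError, match="degenerate index"):
            index_tolerance(np.ones(10), np.arange(10.0))


class TestToleranceSignal:
    def test_hand_value(self):
        f = tolerance_signal(np.array([0.8, 0.2]), k=3)
        assert np.round(f, 5).tolist() == [0.512, 0.008]

    def test_equal_tolerances_give_equal_signals(self):
        for k in (1, 3, 5):
            f = tolerance_signal(np.full(4, 0.3), k=k)
            assert np.allclose(f, f[0])

    def test_larger_k_sharpens_discrimination(self):
        tols = np.array([0.9, 0.3, 0.6])
        ratios = [tolerance_signal(tols, k).max() / tolerance_signal(tols, k).min()
                  for k in (1, 2, 4)]
        assert ratios[0] < ratios[1] < ratios[2]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            tolerance_signal(np.zeros(3), k=2)


class TestInitialization:
    def test_positive_signal_concentrates_positive_init(self, positive_only_data):
        data, truth = positive_only_data
        vp, vn, diag = initialize_two_index(data)
        assert diag["positive_converged"]
        w = vp ** 2 / (vp @ vp)
        assert w[0] > 1 / 6 and w[1] > 1 / 6

    def test_failed_direction_falls_back_to_uniform(self, positive_only_data):
        data, _ = positive_only_data
        vp, vn, diag = initialize_two_index(data)
        if not diag["negative_converged"]:
            assert np.allclose(vn, 1 / 6)


class TestJointFit:
    def test_sign_bounds_hold(self, bidirectional_data):
        data, _ = bidirectional_data
        fit = fit_two_index_joint(data, 0.0, np.ones(6), np.ones(6))
        assert fit["beta1p"] >= 0 and fit["beta1n"] <= 0
        assert abs(fit["wp"].sum() - 1) < 1e-8
        assert abs(fit["wn"].sum() - 1) < 1e-8

    def test_bootstrap_deterministic_given_seed(self, bidirectional_data):
        data, _ = bidirectional_data
        kw = dict(B=5, lam=0.0, vp_init=np.ones(6), vn_init=np.ones(6))
        e1 = fit_two_index_bootstrap(data, rng=np.random.default_rng(5), **kw)
        e2 = fit_two_index_bootstrap(data, rng=np.random.default_rng(5), **kw)
        assert np.array_equal(e1.wp, e2.wp)
        assert np.array_equal(e1.beta1n, e2.beta1n)
        assert np.array_equal(e1.tol_p, e2.tol_p)


class TestFinalize:
    def test_empty_negative_falls_back_to_single_index(self, bidirectional_data,
                                                       caplog):
        data, _ = bidirectional_data
        wp_bar = np.array([0.5, 0.5, 0, 0, 0, 0.0])
        with caplog.at_level(logging.WARNING, logger="wqs2i"):
            res = finalize_two_index(wp_bar, None, data, k=3)
        assert res.fallback == "positive_only"
        assert any(FALLBACK_WARNING in m for m in caplog.messages)
        from wqs2i import validate_single
        direct = validate_single(wp_bar, data)
        assert res.beta1p == pytest.approx(direct.coef("wqs"), rel=1e-10)
        assert np.isnan(res.beta1n)

    def test_both_empty_is_error(self, bidirectional_data):
        data, _ = bidirectional_data
        with pytest.raises(ValueError, match="both directions empty"):
            finalize_two_index(None, None, data, k=3)

    def test_weakly_collinear_indices_no_escalation(self, bidirectional_data):
        data, truth = bidirectional_data
        res = finalize_two_index(truth.wp, truth.wn, data, k=3)
        assert res.vif_p >= 1.0 and res.vif_n >= 1.0
        assert res.fallback == "none"


class TestFullTwoIndexRun:
    def test_recovers_bidirectional_truth(self, bidirectional_data):
        data, truth = bidirectional_data
        res = fit_2iwqs(data, lam=0.0, B=20, k=3, seed=9)
        assert res.fallback == "none"
        assert res.beta1p == pytest.approx(truth.beta1p, abs=0.25)
        assert res.beta1n == pytest.approx(truth.beta1n, abs=0.25)
        assert res.wp_bar[0] + res.wp_bar[1] > 0.5
        assert res.wn_bar[2] + res.wn_bar[3] > 0.5

    def test_averaged_weights_within_bootstrap_envelope(self, bidirectional_data):
        data, _ = bidirectional_data
        from wqs2i.core import train_validation_split
        rng = np.random.default_rng(3)
        train, valid = train_validation_split(data, 0.6, rng)
        ens = fit_two_index_bootstrap(train, 10, 0.0, np.ones(6), np.ones(6),
                                      rng)
        res = average_and_finalize(ens, valid, k=3)
        if res.wp_bar is not None and ens.informative_p.sum() > 0:
            W = ens.wp[ens.informative_p]
            assert ((res.wp_bar >= W.min(axis=0) - 1e-12)
                    & (res.wp_bar <= W.max(axis=0) + 1e-12)).all()
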