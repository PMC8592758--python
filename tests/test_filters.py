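"""Adaptive Kalman filter variants, fading factor, Sage-Husa update, RTS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arkalman.filters import (DivergenceError, FilterConfig,
                              FilterConfigError, adapt_Q, fading_factor,
                              forgetting_weight, kf_step, rts_smooth,
                              run_filter)
from arkalman.signal import Signal
from arkalman.state_space import StateSpaceModel, build_state_space
from arkalman.synthetic import generate_ar_signal


def scalar_model(a=1.0, h=1.0, q=0.0, r=1.0):
    return StateSpaceModel(A=np.array([[a]]), H=np.array([h]),
                           Q=np.array([[q]]), R=r, mean=0.0, signal_var=1.0)


class TestKfStep:
    def test_textbook_scalar_step(self):
        # static state, unit measurement noise, diffuse-ish prior P0=1:
        # gain 0.5, estimate halves the measurement, covariance halves
        model = scalar_model()
        x, P, diag = kf_step(np.array([0.0]), np.array([[1.0]]), 1.0, model)
        assert diag["K"][0] == pytest.approx(0.5)
        assert x[0] == pytest.approx(0.5)
        assert P[0, 0] == pytest.approx(0.5)

    def test_zero_innovation_leaves_prediction_unchanged(self, toy_model):
        x = np.array([0.4, -0.2])
        P = 0.1 * np.eye(2)
        z = float(toy_model.H @ toy_model.A @ x)
        x_new, _, diag = kf_step(x, P, z, toy_model)
        assert diag["V"] == 0.0
        np.testing.assert_allclose(x_new, toy_model.A @ x)

    def test_nonfinite_innovation_raises(self, toy_model):
        with pytest.raises(DivergenceError):
            kf_step(np.array([0.0, 0.0]), np.eye(2), np.inf, toy_model, k=17)


class TestOracleEquivalence:
    def test_kf_variant_matches_textbook_filter(self, toy_model, kf_oracle,
                                                lg_simulator):
        """Central correctness anchor: the KF variant reproduces an
        independently coded covariance-form Kalman filter."""
        _, z = lg_simulator(toy_model, N=200, seed=42)
        x0 = np.zeros(2)
        P0 = np.eye(2)
        res = run_filter(Signal(samples=z), toy_model,
                         FilterConfig(variant="KF", x0=x0, P0=P0))
        ref_x, ref_P = kf_oracle(z, toy_model.A, toy_model.H, toy_model.Q,
                                 toy_model.R, x0, P0)
        assert np.max(np.abs(res.x_filtered - ref_x)) < 1e-8
        assert np.max(np.abs(res.P_filtered - ref_P)) < 1e-8
        assert np.all(res.lambdas == 1.0)
        assert np.all(res.q_trace == res.q_trace[0])

    def test_scalar_200_step_run(self, kf_oracle):
        model = scalar_model(a=0.95, q=0.1, r=0.5)
        rng = np.random.default_rng(5)
        z = rng.standard_normal(200)
        res = run_filter(Signal(samples=z), model,
                         FilterConfig(variant="KF", x0=np.zeros(1),
                                      P0=np.eye(1)))
        ref_x, _ = kf_oracle(z, model.A, model.H, model.Q, model.R,
                             np.zeros(1), np.eye(1))
        assert np.max(np.abs(res.x_filtered - ref_x)) < 1e-8


class TestForgettingWeight:
    @pytest.mark.parametrize("b,k,expected", [
        (0.95, 0, 1.0),
        (0.95, 1, 0.05 / (1 - 0.95 ** 2)),
        (0.95, 1000, 0.05),
    ])
    def test_values(self, b, k, expected):
        assert forgetting_weight(k, b) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("b", [0.95, 0.97, 0.99])
    def test_strictly_decreasing_with_limit(self, b):
        from fractions import Fraction

        # exact-arithmetic oracle: d_k = (1-b)/(1-b^(k+1)) is strictly
        # decreasing and stays above its limit 1-b
        bf = Fraction(b)
        exact = [(1 - bf) / (1 - bf ** (k + 1)) for k in range(1001)]
        assert all(a > c for a, c in zip(exact, exact[1:]))
        assert all(dk > 1 - bf for dk in exact)
        # the float implementation follows the exact values until the
        # geometric term underflows, then sits exactly on the limit
        d = np.array([forgetting_weight(k, b) for k in range(1001)])
        assert d[0] == pytest.approx(1.0)
        np.testing.assert_allclose(d, [float(e) for e in exact], rtol=1e-12)
        assert np.all(np.diff(d) <= 0)
        assert d[-1] == pytest.approx(1 - b, rel=1e-4)  # b=0.99: b**1001 ~ 4e-5

    @pytest.mark.parametrize("b", [0.0, 1.0, -0.5, 1.5])
    def test_invalid_forgetting_factor_rejected(self, b):
        with pytest.raises(FilterConfigError):
            forgetting_weight(1, b)


class TestFadingFactor:
    def test_ratio_below_one_clamps(self, toy_model):
        cfg = FilterConfig(variant="STKF")
        P = 0.1 * np.eye(2)
        lam, _ = fading_factor(0.01, 0.0, toy_model, P, toy_model.Q,
                               toy_model.R, cfg, k=3)
        assert lam == 1.0

    def test_large_innovation_passes_through(self, toy_model):
        cfg = FilterConfig(variant="STKF")
        P = 0.1 * np.eye(2)
        H, A = toy_model.H, toy_model.A
        M = float(H @ A @ P @ A.T @ H)
        # pick V so that N/M = 2.3 exactly
        v0 = 0.5
        N_target = 2.3 * M
        v2 = (N_target + H @ toy_model.Q @ H
              + cfg.beta * toy_model.R) * (1 + cfg.rho) - cfg.rho * v0
        lam, _ = fading_factor(np.sqrt(v2), v0, toy_model, P, toy_model.Q,
                               toy_model.R, cfg, k=5)
        assert lam == pytest.approx(2.3, rel=1e-10)

    def test_first_step_initialises_memory(self, toy_model):
        cfg = FilterConfig(variant="STKF")
        lam, v0 = fading_factor(2.0, 0.0, toy_model, np.eye(2), toy_model.Q,
                                toy_model.R, cfg, k=0)
        assert lam == 1.0
        assert v0 == pytest.approx(4.0)

    def test_degenerate_geometry_forces_one(self, toy_model):
        cfg = FilterConfig(variant="STKF")
        lam, _ = fading_factor(100.0, 0.0, toy_model, np.zeros((2, 2)),
                               toy_model.Q, toy_model.R, cfg, k=2)
        assert lam == 1.0

    def test_lambda_clamps_at_one_for_consistent_model(self, toy_model,
                                                       lg_simulator):
        # with the correct (Q, R) the innovation excess stays near the
        # model-based trace, so the clamp binds at most steps
        fracs = []
        for seed in range(20):
            _, z = lg_simulator(toy_model, N=500, seed=seed)
            res = run_filter(Signal(samples=z), toy_model,
                             FilterConfig(variant="STKF", x0=np.zeros(2),
                                          P0=np.eye(2)))
            assert np.all(res.lambdas >= 1.0)
            fracs.append(np.mean(res.lambdas == 1.0))
        assert np.mean(fracs) > 0.5


class TestAdaptQ:
    def test_zero_weight_keeps_previous(self):
        Q = np.diag([0.3, 0.7])
        out = adapt_Q(Q, 0.0, np.array([1.0, 2.0]), 5.0,
                      np.eye(2), np.eye(2))
        np.testing.assert_array_equal(out, Q)

    def test_full_weight_zero_innovation_zero_covariance(self):
        Q = np.diag([0.3, 0.7])
        out = adapt_Q(Q, 1.0, np.array([1.0, 2.0]), 0.0,
                      np.eye(2), np.zeros((2, 2)), q_floor=1e-9)
        np.testing.assert_allclose(np.diag(out), 1e-9)

    def test_adapted_trace_tracks_generating_covariance(self, toy_model,
                                                        lg_simulator):
        ratios = []
        for seed in range(20):
            _, z = lg_simulator(toy_model, N=1500, seed=200 + seed)
            res = run_filter(Signal(samples=z), toy_model,
                             FilterConfig(variant="SHKF", x0=np.zeros(2),
                                          P0=np.eye(2)))
            ratios.append(np.mean(res.q_trace[300:])
                          / np.trace(toy_model.Q))
        assert 0.5 < np.mean(ratios) < 2.0


class TestRunFilter:
    @pytest.mark.parametrize("variant", ["KF", "SHKF", "STKF", "STSHKF"])
    def test_covariance_health(self, variant, toy_model, lg_simulator):
        _, z = lg_simulator(toy_model, N=300, seed=8)
        res = run_filter(Signal(samples=z), toy_model,
                         FilterConfig(variant=variant))
        for P in res.P_filtered:
            np.testing.assert_allclose(P, P.T, atol=1e-12)
            assert np.all(np.diag(P) >= 0.0)
        assert np.all(res.lambdas >= 1.0)
        assert len(res.denoised) == len(z)

    def test_tracks_noiseless_ar_synthesis(self):
        sig = generate_ar_signal([0.6, -0.2, 0.1], sigma=0.05, N=2000,
                                 seed=13)
        model = build_state_space(sig, 3)
        res = run_filter(sig, model, FilterConfig(variant="STSHKF"))
        err = np.sqrt(np.mean((res.denoised.samples[50:]
                               - sig.samples[50:]) ** 2))
        # tracking beats any constant predictor
        assert err < np.std(sig.samples)

    def test_amplitude_equivariance_of_kf_variant(self, toy_model,
                                                  lg_simulator):
        # the KF is linear: scaling the measurements scales the output
        _, z = lg_simulator(toy_model, N=200, seed=3)
        cfg = FilterConfig(variant="KF", x0=np.zeros(2), P0=np.eye(2))
        base = run_filter(Signal(samples=z), toy_model, cfg)
        scaled_model = StateSpaceModel(
            A=toy_model.A, H=toy_model.H, Q=100.0 * toy_model.Q,
            R=100.0 * toy_model.R, mean=0.0, signal_var=100.0)
        cfg10 = FilterConfig(variant="KF", x0=np.zeros(2),
                             P0=100.0 * np.eye(2))
        scaled = run_filter(Signal(samples=10.0 * z), scaled_model, cfg10)
        np.testing.assert_allclose(scaled.denoised.samples,
                                   10.0 * base.denoised.samples, rtol=1e-8)

    def test_signal_shorter_than_state_rejected(self, toy_model):
        with pytest.raises(ValueError):
            run_filter(Signal(samples=np.array([1.0, 2.0])), toy_model)

    def test_bad_config_rejected(self):
        with pytest.raises(FilterConfigError):
            FilterConfig(variant="UKF")
        with pytest.raises(FilterConfigError):
            FilterConfig(b=1.5)
        with pytest.raises(FilterConfigError):
            FilterConfig(rho=0.0)
        with pytest.raises(FilterConfigError):
            FilterConfig(beta=0.5)


class TestSmoother:
    def test_last_step_anchored_at_filtered_estimate(self, toy_model,
                                                     lg_simulator):
        _, z = lg_simulator(toy_model, N=100, seed=21)
        res = run_filter(Signal(samples=z), toy_model,
                         FilterConfig(variant="KF"))
        sm = rts_smooth(res)
        np.testing.assert_array_equal(sm.x_smoothed[-1], res.x_filtered[-1])
        np.testing.assert_array_equal(sm.P_smoothed[-1], res.P_filtered[-1])

    def test_matches_hand_unrolled_scalar_recursion(self, kf_oracle):
        model = scalar_model(a=0.8, q=0.2, r=0.5)
        z = np.array([1.0, -0.5, 0.7])
        cfg = FilterConfig(variant="KF", x0=np.zeros(1), P0=np.eye(1))
        res = run_filter(Signal(samples=z), model, cfg)
        sm = rts_smooth(res)
        # hand-unrolled backward pass from the filtered/predicted pairs
        xf, Pf = res.x_filtered[:, 0], res.P_filtered[:, 0, 0]
        xp, Pp = res.x_pred[:, 0], res.P_pred[:, 0, 0]
        xs2, Ps2 = xf[2], Pf[2]
        C1 = Pf[1] * 0.8 / Pp[2]
        xs1 = xf[1] + C1 * (xs2 - xp[2])
        Ps1 = Pf[1] + C1 * (Ps2 - Pp[2]) * C1
        C0 = Pf[0] * 0.8 / Pp[1]
        xs0 = xf[0] + C0 * (xs1 - xp[1])
        Ps0 = Pf[0] + C0 * (Ps1 - Pp[1]) * C0
        np.testing.assert_allclose(sm.x_smoothed[:, 0], [xs0, xs1, xs2],
                                   rtol=1e-12)
        np.testing.assert_allclose(sm.P_smoothed[:, 0, 0], [Ps0, Ps1, Ps2],
                                   rtol=1e-12)

    def test_smoothing_reduces_state_mse_and_covariance(self, toy_model,
                                                        lg_simulator):
        wins = 0
        for seed in range(50):
            X, z = lg_simulator(toy_model, N=200, seed=300 + seed)
            res = run_filter(Signal(samples=z), toy_model,
                             FilterConfig(variant="KF", x0=np.zeros(2),
                                          P0=np.eye(2)))
            sm = rts_smooth(res)
            mse_f = np.mean((res.x_filtered - X) ** 2)
            mse_s = np.mean((sm.x_smoothed - X) ** 2)
            wins += mse_s <= mse_f
            tr_f = np.trace(res.P_filtered, axis1=1, axis2=2)
            tr_s = np.trace(sm.P_smoothed, axis1=1, axis2=2)
            assert np.all(tr_s <= tr_f + 1e-9)
        assert wins >= 48


@given(b=st.floats(0.9, 0.999), k=st.integers(0, 500))
@settings(deadline=None)
def test_forgetting_weight_bounds(b, k):
    d = forgetting_weight(k, b)
    assert 1 - b <= d <= 1.0
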