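"""Tests of the scaled unscented transform and the constrained filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from phesense import cgm, pipeline
from phesense.cgm import CGMState, FeedSchedule, derivatives
from phesense.ukf import (
    FilterError,
    UKFConfig,
    cgm_propagator,
    compute_weights,
    constrain_posterior,
    generate_sigma_points,
    predict_step,
    run_filter,
    unscented_estimate,
    update_step,
)


class TestWeights:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(n=st.integers(1, 12), alpha=st.floats(0.05, 1.0),
           kappa=st.floats(0.0, 5.0), beta=st.floats(0.0, 4.0))
    def test_mean_weights_sum_to_one(self, n, alpha, kappa, beta):
        Wm, Wc, lam = compute_weights(n, alpha, beta, kappa)
        assert np.sum(Wm) == pytest.approx(1.0, abs=1e-9)
        assert Wm.size == Wc.size == 2 * n + 1
        assert np.allclose(Wm[1:], 1.0 / (2 * (n + lam)))

    def test_scalar_reference_values(self):
        Wm, Wc, lam = compute_weights(1, 1.0, 2.0, 0.0)
        assert lam == pytest.approx(0.0)
        assert np.allclose(Wm, [0.0, 0.5, 0.5])
        assert Wc[0] == pytest.approx(2.0)

    def test_degenerate_scaling_rejected(self):
        with pytest.raises(ValueError, match="kappa|alpha"):
            compute_weights(10, 1.0, 2.0, -10.0)
        # boundary: kappa = 3 - n is fine (n + lambda = 3 > 0)
        compute_weights(10, 1.0, 2.0, -7.0)


class TestSigmaPoints:
    def test_zero_covariance_collapses_to_mean(self):
        x = np.arange(4.0)
        pts = generate_sigma_points(x, np.zeros((4, 4)), lam=0.0)
        assert np.allclose(pts, x, atol=1e-12)

    def test_scalar_spread(self):
        pts = generate_sigma_points(np.array([1.0]), np.array([[4.0]]), lam=0.0)
        assert np.allclose(np.sort(pts.ravel()), [-1.0, 1.0, 3.0])

    def test_transform_identity_recovers_moments(self):
        rng = np.random.default_rng(0)
        n = 10
        for _ in range(20):
            A = rng.normal(size=(n, n))
            P = A @ A.T + 0.1 * np.eye(n)
            x = rng.normal(size=n)
            Wm, Wc, lam = compute_weights(n, 0.5, 2.0, 0.0)
            pts = generate_sigma_points(x, P, lam)
            Wc_id = Wc.copy()
            Wc_id[0] = Wm[0]                     # beta term excluded from the identity
            mean, cov = unscented_estimate(pts, Wm, Wc_id)
            assert np.max(np.abs(mean - x)) < 1e-10
            assert np.max(np.abs(cov - P)) < 1e-10

    def test_symmetry_about_mean(self):
        rng = np.random.default_rng(1)
        P = np.diag(rng.uniform(0.1, 1.0, 5))
        x = rng.normal(size=5)
        pts = generate_sigma_points(x, P, lam=-2.0)
        assert np.allclose(pts[1:6] + pts[6:], 2 * x)


@pytest.fixture()
def linear_system():
    rng = np.random.default_rng(7)
    n, m = 10, 5
    A = rng.standard_normal((n, n))
    A *= 0.9 / np.max(np.abs(np.linalg.eigvals(A)))
    H = rng.standard_normal((m, n))
    Q = np.diag(rng.uniform(0.01, 0.1, n))
    R = np.diag(rng.uniform(0.05, 0.2, m))
    return A, H, Q, R


class TestPredictUpdate:
    def test_linear_predict_matches_closed_form(self, linear_system):
        A, H, Q, R = linear_system
        rng = np.random.default_rng(2)
        x = rng.normal(size=10)
        P = np.eye(10)
        cfg = UKFConfig(Q=Q, R=R)
        xp, Pp = predict_step(x, P, cfg, lambda pts: pts @ A.T)
        assert np.max(np.abs(xp - A @ x)) < 1e-8
        assert np.max(np.abs(Pp - (A @ P @ A.T + Q))) < 1e-8

    def test_identity_dynamics_without_noise_is_inert(self):
        x = np.arange(1.0, 11.0)
        P = np.diag(np.linspace(0.1, 1.0, 10))
        cfg = UKFConfig(Q=np.zeros((10, 10)))
        xp, Pp = predict_step(x, P, cfg, lambda pts: pts)
        assert np.allclose(xp, x, atol=1e-12)
        assert np.allclose(Pp, P, atol=1e-10)

    def test_linear_update_matches_kalman(self, linear_system):
        A, H, Q, R = linear_system
        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        P = np.eye(10) * 0.5
        y = rng.normal(size=5)
        cfg = UKFConfig(Q=Q, R=R)
        xp, Pp, innov, K = update_step(x, P, y, cfg, h=lambda pts: pts @ H.T)
        S = H @ P @ H.T + R
        Kk = P @ H.T @ np.linalg.inv(S)
        xk = x + Kk @ (y - H @ x)
        Pk = P - Kk @ S @ Kk.T
        assert np.max(np.abs(xp - xk)) < 1e-8
        assert np.max(np.abs(Pp - Pk)) < 1e-8

    def test_infinite_noise_ignores_measurement(self, linear_system):
        A, H, Q, R = linear_system
        rng = np.random.default_rng(4)
        x = rng.normal(size=10)
        P = np.eye(10)
        cfg_big = UKFConfig(Q=Q, R=R * 1e9)
        cfg = UKFConfig(Q=Q, R=R)
        y = rng.normal(size=5) * 10
        x_big, *_ = update_step(x, P, y, cfg_big, h=lambda pts: pts @ H.T)
        x_ref, _, innov, K = update_step(x, P, y, cfg, h=lambda pts: pts @ H.T)
        assert np.linalg.norm(x_big - x) < 1e-3 * np.linalg.norm(K @ innov)

    def test_zero_innovation_keeps_mean_shrinks_covariance(self, linear_system):
        A, H, Q, R = linear_system
        x = np.ones(10)
        P = np.eye(10)
        cfg = UKFConfig(Q=Q, R=R)
        y = H @ x
        xp, Pp, innov, K = update_step(x, P, y, cfg, h=lambda pts: pts @ H.T)
        assert np.allclose(xp, x, atol=1e-10)
        assert np.min(np.linalg.eigvalsh(P - Pp)) > -1e-10   # P+ <= P-

    def test_nonfinite_measurement_rejected(self, linear_system):
        A, H, Q, R = linear_system
        cfg = UKFConfig(Q=Q, R=R)
        with pytest.raises(FilterError):
            update_step(np.zeros(10), np.eye(10), np.array([1, 2, np.nan, 4, 5]),
                        cfg, h=lambda pts: pts @ H.T)


class TestConstraint:
    def test_feasible_posterior_untouched(self):
        cfg = UKFConfig()
        x = np.full(10, 2.0)
        P = np.eye(10) * 0.01
        xc, Pc = constrain_posterior(x, P, np.zeros(10), cfg)
        assert xc is x and Pc is P

    def test_scalar_hand_enumeration(self):
        # alpha=1, kappa=0, n=1 -> lambda=0, Wm=(0,.5,.5), Wc=(2,.5,.5)
        # x=-0.5, P=1: points (-0.5, 0.5, -1.5) -> clipped (0, 0.5, 0)
        # mean = 0*0 + .5*.5 + .5*0 = 0.25
        # cov  = 2*(0-.25)^2 + .5*(.5-.25)^2 + .5*(0-.25)^2 = 0.1875
        cfg = UKFConfig(alpha=1.0, kappa=0.0, beta=2.0,
                        Q=np.zeros(10), R=np.eye(5))     # Q/R unused here
        xc, Pc = constrain_posterior(np.array([-0.5]), np.array([[1.0]]),
                                     np.array([0.0]), cfg)
        assert xc[0] == pytest.approx(0.25)
        assert Pc[0, 0] == pytest.approx(0.1875)

    def test_projected_covariance_stays_psd(self):
        rng = np.random.default_rng(5)
        cfg = UKFConfig()
        for _ in range(20):
            A = rng.normal(size=(10, 10))
            P = A @ A.T + 0.05 * np.eye(10)
            x = rng.normal(size=10) - 1.0        # mostly violating
            xc, Pc = constrain_posterior(x, P, np.zeros(10), cfg)
            assert np.all(xc >= 0)
            assert np.min(np.linalg.eigvalsh(Pc)) >= -1e-9


class TestPropagator:
    def test_matches_adaptive_integrator(self, params):
        sched = FeedSchedule(t_batch_end=15.0, t_induction=45.0, t_end=70.0)
        x0 = CGMState().to_array()
        prop = cgm_propagator(params, sched, t0_h=2.0, dt_h=0.25, substep_s=15.0)
        got = prop(x0[None, :])[0]
        sol = solve_ivp(lambda t, x: derivatives(t, x, params, sched),
                        (2.0, 2.25), x0, rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(got - sol.y[:, -1])) < 1e-6

    def test_vectorised_over_points(self, params):
        sched = FeedSchedule(t_batch_end=15.0, t_induction=45.0, t_end=70.0)
        rng = np.random.default_rng(6)
        pts = CGMState().to_array() + rng.uniform(0, 0.01, (5, 10))
        prop = cgm_propagator(params, sched, 1.0, 0.1)
        batch = prop(pts)
        for i in range(5):
            assert np.allclose(batch[i], prop(pts[i][None, :])[0])


class TestRunFilter:
    def test_degenerate_filter_reproduces_open_loop(self, short_ref, params, x0_arr):
        # infinite measurement noise + degenerate prior: the filter is the
        # simulator (same x0 convention: one update interval of lead time)
        cfg = UKFConfig(R=np.eye(5) * 1e12, P0=np.eye(10) * 1e-12,
                        Q=np.zeros((10, 10)))
        T = short_ref.online.times.size
        res = run_filter(short_ref, None, cfg, short_ref.schedule, x0_arr,
                         measurements=np.zeros((T, 5)))
        grid = np.concatenate([[short_ref.online.times[0] - cfg.dt_update / 3600.0],
                               short_ref.online.times])
        ol = cgm.simulate(CGMState(), params, short_ref.schedule, grid,
                          rtol=1e-9, atol=1e-9)
        dev = np.abs(res.x_post[:, [2, 1, 3, 4, 5]] - cgm.measure(ol.states[1:]))
        assert dev.max() < 0.05

    def test_tracks_perturbed_truth_better_than_open_loop(self, short_ref, params,
                                                          x0_arr, default_P0):
        # truth starts with 30% more inoculum than the filter believes;
        # direct noisy concentration measurements correct the estimate
        rng = np.random.default_rng(3)
        x0p = x0_arr.copy()
        x0p[2] *= 1.3
        truth = cgm.simulate(x0p, params, short_ref.schedule, short_ref.online.times,
                             rtol=1e-9, atol=1e-9)
        sd = np.array([0.1, 0.05, 0.1, 0.02, 0.005])
        y = cgm.measure(truth.states) + rng.normal(0, sd, (truth.times.size, 5))
        cfg = UKFConfig(R=np.diag(sd**2), P0=default_P0)
        res = run_filter(short_ref, None, cfg, short_ref.schedule, x0_arr,
                         measurements=y)
        ol = pipeline.open_loop(short_ref, params)
        rm_filter = np.sqrt(np.mean((res.x_post[:, 2] - truth.states[:, 2]) ** 2))
        rm_open = np.sqrt(np.mean((ol.states[:, 2] - truth.states[:, 2]) ** 2))
        assert rm_filter < rm_open

    def test_one_update_per_online_row(self, short_ref, short_models, x0_arr,
                                       default_P0):
        sub = type(short_ref.online)(times=short_ref.online.times[:40],
                                     values=short_ref.online.values[:40],
                                     phase_index=short_ref.online.phase_index[:40])
        cfg = UKFConfig(R=np.eye(5), P0=default_P0)
        res = run_filter(sub, short_models, cfg, short_ref.schedule, x0_arr)
        assert res.times.size == 40
        assert res.x_post.shape == (40, 10)
        assert res.innovations.shape == (40, 5)
        assert np.array_equal(res.times, sub.times)

    def test_missing_phase_model_rejected(self, short_ref, short_models, x0_arr,
                                          default_P0):
        models = {1: short_models[1], 2: short_models[2]}
        cfg = UKFConfig(R=np.eye(5), P0=default_P0)
        with pytest.raises(FilterError, match="phase 3"):
            run_filter(short_ref, models, cfg, short_ref.schedule, x0_arr)

    def test_cadence_mismatch_rejected(self, short_ref, short_models, x0_arr,
                                       default_P0):
        cfg = UKFConfig(R=np.eye(5), P0=default_P0, dt_update=60.0, dt_predict=60.0)
        with pytest.raises(ValueError, match="cadence"):
            run_filter(short_ref, short_models, cfg, short_ref.schedule, x0_arr)


def test_innovation_consistency_on_self_generated_data(linear_system):
    """Normalized innovation squared stays near its chi-square expectation
    when the filter's noise model matches the generating process."""
    A, H, Q, R = linear_system
    rng = np.random.default_rng(8)
    cfg = UKFConfig(Q=Q, R=R)
    x_true = rng.normal(size=10)
    x, P = x_true.copy(), np.eye(10)
    nis = []
    for _ in range(300):
        x_true = A @ x_true + rng.multivariate_normal(np.zeros(10), Q)
        y = H @ x_true + rng.multivariate_normal(np.zeros(5), R)
        x, P = predict_step(x, P, cfg, lambda pts: pts @ A.T)
        Py = H @ P @ H.T + R
        x, P, innov, _ = update_step(x, P, y, cfg, h=lambda pts: pts @ H.T)
        nis.append(innov @ np.linalg.solve(Py, innov))
    ratio = np.mean(nis) / 5.0
    assert 0.3 < ratio < 3.0


def test_config_validation():
    with pytest.raises(ValueError, match="alpha"):
        UKFConfig(alpha=1.5)
    with pytest.raises(ValueError, match="multiple"):
        UKFConfig(dt_predict=70.0, dt_update=120.0)
    with pytest.raises(ValueError, match="semidefinite"):
        UKFConfig(Q=-np.eye(10))
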