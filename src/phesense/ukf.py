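"""Constrained unscented Kalman filter for the hybrid soft sensor.

The filter propagates the 10-dimensional process-model state with the
coarse-grained kinetics as transition function and takes the phase-wise
PLSR concentration estimates as its measurement vector.  Sigma points
use the scaled unscented transform (Cholesky square root, parameters
alpha/beta/kappa), noise enters additively (process covariance Q after
the time update, measurement covariance R in the innovation covariance),
and nonnegativity of the posterior is enforced by projecting violating
sigma points onto the constraint boundary and recombining.

Prediction runs on a 60 s cadence with two predictions per 120 s
measurement tick, matching the logging interval of the online signals.
Internally all dynamics are in hours; the second-based cadences are
converted at the configuration boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .cgm import (
    N_STATES,
    STATE_NAMES,
    CGMParameters,
    FeedSchedule,
    derivatives,
    measure,
)

__all__ = [
    "UKFConfig",
    "SigmaPointSet",
    "FilterResult",
    "compute_weights",
    "generate_sigma_points",
    "predict_step",
    "update_step",
    "constrain_posterior",
    "cgm_propagator",
    "run_filter",
]


class FilterError(RuntimeError):
    """Numerical failure inside the filter (covariance degeneracy, ODE blow-up)."""


def _default_lower_bounds() -> np.ndarray:
    lb = np.zeros(N_STATES)
    lb[0] = 1e-6                      # volume must stay strictly positive
    return lb


@dataclass
class UKFConfig:
    """Tuning parameters and noise covariances.

    ``Q`` (10x10) and ``R`` (5x5) may be passed as full matrices or as
    diagonal vectors.  ``dt_predict`` and ``dt_update`` are in seconds;
    the update interval must be an integer multiple of the prediction
    interval.  ``ode_substep_s`` controls the fixed-step RK4 integrator
    used to push sigma points through the process model.
    """

    alpha: float = 0.5
    beta: float = 2.0
    kappa: float = 0.0
    Q: np.ndarray = field(default_factory=lambda: np.diag(_default_q()))
    R: np.ndarray = field(default_factory=lambda: np.eye(5))
    P0: np.ndarray | None = None
    lower_bounds: np.ndarray = field(default_factory=_default_lower_bounds)
    dt_predict: float = 60.0
    dt_update: float = 120.0
    ode_substep_s: float = 15.0
    repropagate_constraint: bool = False

    def __post_init__(self) -> None:
        self.Q = _as_cov(self.Q, N_STATES, "Q")
        self.R = _as_cov(self.R, 5, "R")
        if self.P0 is not None:
            self.P0 = _as_cov(self.P0, N_STATES, "P0")
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        ratio = self.dt_update / self.dt_predict
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("dt_update must be an integer multiple of dt_predict")


def _default_q() -> np.ndarray:
    # per-60 s-step process noise variances; engineering defaults, replaced by
    # calibration in the full pipeline
    return np.array([1e-6, 2.5e-3, 1e-2, 1e-2, 2.5e-3, 1e-4,
                     1e-6, 1e-6, 1e-6, 1e-6])


def _as_cov(M, n: int, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        if M.size != n:
            raise ValueError(f"{name} diagonal must have length {n}")
        M = np.diag(M)
    if M.shape != (n, n):
        raise ValueError(f"{name} must be {n}x{n}, got {M.shape}")
    if not np.allclose(M, M.T, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    if np.min(np.linalg.eigvalsh(M)) < -1e-10:
        raise ValueError(f"{name} must be positive semidefinite")
    return M


@dataclass
class SigmaPointSet:
    """2n+1 sigma points (rows) with their mean and covariance weights."""

    points: np.ndarray            # (2n+1, n)
    Wm: np.ndarray
    Wc: np.ndarray


@dataclass
class FilterResult:
    """Per-tick filter log: prior/posterior means and covariances,
    innovations and Kalman gains, one row per measurement update."""

    times: np.ndarray             # (T,) [h]
    x_prior: np.ndarray           # (T, n)
    x_post: np.ndarray            # (T, n)
    P_prior: np.ndarray           # (T, n, n)
    P_post: np.ndarray            # (T, n, n)
    innovations: np.ndarray       # (T, m)
    kalman_gains: np.ndarray      # (T, n, m)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"time_h": self.times})
        for j, n in enumerate(STATE_NAMES):
            df[f"prior_{n}"] = self.x_prior[:, j]
        for j, n in enumerate(STATE_NAMES):
            df[f"post_{n}"] = self.x_post[:, j]
        for j, n in enumerate(STATE_NAMES):
            df[f"var_{n}"] = self.P_post[:, j, j]
        for j in range(self.innovations.shape[1]):
            df[f"innovation_{j}"] = self.innovations[:, j]
        return df

    def interpolate_post(self, t: np.ndarray, cols=None) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        cols = range(self.x_post.shape[1]) if cols is None else cols
        out = np.empty((t.size, len(list(cols))))
        for k, j in enumerate(cols):
            out[:, k] = np.interp(t, self.times, self.x_post[:, j])
        return out


# ---------------------------------------------------------------------------
# Unscented transform primitives


def compute_weights(n: int, alpha: float, beta: float, kappa: float
                    ) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled-UT weights; ``lambda = alpha^2 (n + kappa) - n``.

    The off-center weights are ``1 / (2 (n + lambda))``, which makes the
    mean weights sum to one and the transform exact for linear maps.
    ``Wc(0)`` carries the usual ``(1 - alpha^2 + beta)`` correction.
    """
    if n < 1:
        raise ValueError("state dimension must be >= 1")
    lam = alpha**2 * (n + kappa) - n
    if n + lam <= 0:
        raise ValueError(
            f"n + lambda = {n + lam:.4g} must be positive; increase kappa or alpha")
    Wm = np.full(2 * n + 1, 1.0 / (2 * (n + lam)))
    Wc = Wm.copy()
    Wm[0] = lam / (n + lam)
    Wc[0] = lam / (n + lam) + (1 - alpha**2 + beta)
    return Wm, Wc, lam


def _cholesky_jittered(P: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor with escalating diagonal jitter.

    Starts at 1e-10 * trace(P)/n and escalates tenfold up to 1e-6
    (relative) before giving up.
    """
    try:
        return np.linalg.cholesky(P)
    except np.linalg.LinAlgError:
        pass
    n = P.shape[0]
    base = max(np.trace(P) / n, 1e-300)
    jitter = 1e-10
    while jitter <= 1e-6 + 1e-18:
        try:
            return np.linalg.cholesky(P + jitter * base * np.eye(n))
        except np.linalg.LinAlgError:
            jitter *= 10
    raise FilterError("covariance is numerically degenerate: Cholesky failed after max jitter")


def generate_sigma_points(x_hat: np.ndarray, P: np.ndarray, lam: float) -> np.ndarray:
    """Sigma points (2n+1, n): the mean plus/minus the scaled Cholesky columns."""
    x_hat = np.asarray(x_hat, dtype=float)
    P = np.asarray(P, dtype=float)
    n = x_hat.size
    L = _cholesky_jittered((n + lam) * P)
    pts = np.empty((2 * n + 1, n))
    pts[0] = x_hat
    pts[1:n + 1] = x_hat + L.T
    pts[n + 1:] = x_hat - L.T
    return pts


def unscented_estimate(points: np.ndarray, Wm: np.ndarray, Wc: np.ndarray,
                       noise: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Weighted mean and covariance of transformed sigma points."""
    mean = Wm @ points
    d = points - mean
    cov = (Wc[:, None] * d).T @ d
    if noise is not None:
        cov = cov + noise
    return mean, 0.5 * (cov + cov.T)


def _psd_floor(P: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Clip negative eigenvalues introduced by roundoff (or by negative
    center weights in the constrained recombination) back to the floor."""
    P = 0.5 * (P + P.T)
    w = np.linalg.eigvalsh(P)
    if w[0] < floor - 1e-15:
        P = P + (floor - w[0]) * np.eye(P.shape[0])
    return P


# ---------------------------------------------------------------------------
# Filter steps


def predict_step(x_post: np.ndarray, P_post: np.ndarray, config: UKFConfig,
                 propagate: Callable[[np.ndarray], np.ndarray]
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Time update: push sigma points through the transition, recombine,
    add Q, symmetrize."""
    n = x_post.size
    Wm, Wc, lam = compute_weights(n, config.alpha, config.beta, config.kappa)
    pts = generate_sigma_points(x_post, P_post, lam)
    prop = propagate(pts)
    if not np.all(np.isfinite(prop)):
        bad = int(np.flatnonzero(~np.isfinite(prop).all(axis=1))[0])
        raise FilterError(f"transition produced non-finite sigma point (index {bad})")
    x_prior, P_prior = unscented_estimate(prop, Wm, Wc, noise=config.Q)
    return x_prior, P_prior


def update_step(x_prior: np.ndarray, P_prior: np.ndarray, y: np.ndarray,
                config: UKFConfig,
                h: Callable[[np.ndarray], np.ndarray] = measure
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Measurement update; returns (x_post, P_post, innovation, K).

    The innovation covariance is solved, never inverted; the posterior
    covariance is symmetrized.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise FilterError("measurement vector contains non-finite entries")
    n = x_prior.size
    Wm, Wc, lam = compute_weights(n, config.alpha, config.beta, config.kappa)
    pts = generate_sigma_points(x_prior, P_prior, lam)
    gam = np.atleast_2d(h(pts))
    y_hat = Wm @ gam
    dg = gam - y_hat
    dx = pts - x_prior
    Py = (Wc[:, None] * dg).T @ dg + config.R
    Py = 0.5 * (Py + Py.T)
    Pxy = (Wc[:, None] * dx).T @ dg
    try:
        # K = Pxy Py^-1  via  Py^T K^T = Pxy^T
        K = np.linalg.solve(Py, Pxy.T).T
    except np.linalg.LinAlgError as e:
        raise FilterError(f"innovation covariance singular ({e}); consider larger R") from e
    innovation = y - y_hat
    x_post = x_prior + K @ innovation
    P_post = 0.5 * ((P_prior - K @ Py @ K.T) + (P_prior - K @ Py @ K.T).T)
    return x_post, P_post, innovation, K


def constrain_posterior(x_post: np.ndarray, P_post: np.ndarray,
                        lower_bounds: np.ndarray, config: UKFConfig,
                        propagate: Callable[[np.ndarray], np.ndarray] | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Project the posterior onto the lower-bound constraints.

    Regenerates sigma points from the (violating) posterior, clips every
    coordinate to its bound, and recombines with the standard weights —
    applied once, no iteration.  When ``repropagate_constraint`` is set
    and a propagator is supplied, the clipped points are additionally
    pushed through the transition before recombination.  The recombined
    covariance is floored at PSD (the negative center weight of the
    scaled transform can otherwise leave a small negative eigenvalue).
    """
    lb = np.asarray(lower_bounds, dtype=float)
    if np.all(x_post >= lb):
        return x_post, P_post
    n = x_post.size
    Wm, Wc, lam = compute_weights(n, config.alpha, config.beta, config.kappa)
    pts = generate_sigma_points(x_post, P_post, lam)
    pts = np.maximum(pts, lb)
    if config.repropagate_constraint and propagate is not None:
        pts = propagate(pts)
        pts = np.maximum(pts, lb)
    x_c, P_c = unscented_estimate(pts, Wm, Wc)
    x_c = np.maximum(x_c, lb)
    return x_c, _psd_floor(P_c)


# ---------------------------------------------------------------------------
# Transition propagator (vectorised fixed-step RK4)


def cgm_propagator(params: CGMParameters, schedule: FeedSchedule,
                   t0_h: float, dt_h: float, substep_s: float = 15.0
                   ) -> Callable[[np.ndarray], np.ndarray]:
    """Propagator pushing a batch of sigma points through the process model.

    Integrates the coarse-grained kinetics from ``t0_h`` over ``dt_h``
    with classical RK4 at a fixed substep, vectorised over all points.
    The fastest mode (quasi-steady glycerol at high cell density) has a
    time constant well above the default 15 s substep.  Volumes are kept
    strictly positive before each derivative evaluation.
    """
    n_sub = max(1, int(round(dt_h * 3600.0 / substep_s)))
    h = dt_h / n_sub

    def f(t, x):
        x = x.copy()
        x[..., 0] = np.clip(x[..., 0], 1e-6, None)
        return derivatives(t, x, params, schedule)

    def propagate(points: np.ndarray) -> np.ndarray:
        x = np.array(points, dtype=float)
        t = t0_h
        for _ in range(n_sub):
            k1 = f(t, x)
            k2 = f(t + h / 2, x + h / 2 * k1)
            k3 = f(t + h / 2, x + h / 2 * k2)
            k4 = f(t + h, x + h * k3)
            x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        return x

    return propagate


# ---------------------------------------------------------------------------
# Filter loop


def plsr_measurements(online, models: dict[int, "object"], *, n_ref: int = 1) -> np.ndarray:
    """PLSR measurement matrix (T, 5) for a full online log.

    Each phase's rows are offset-centered against that phase's own start
    (the consistent-starting-conditions convention) and pushed through
    the phase's model.  Raw (possibly negative) predictions are returned;
    the filter's state constraint handles physicality.
    """
    from .plsr import phase_offset_center, predict

    Y = np.empty((online.times.size, 5))
    for phase in (1, 2, 3):
        rows = online.phase_rows(phase)
        if rows.size == 0:
            continue
        if phase not in models:
            raise FilterError(f"no trained PLS model for phase {phase}")
        Xc, _ = phase_offset_center(online.values[rows], n_ref=n_ref)
        Y[rows] = predict(models[phase], Xc)
    return Y


def run_filter(dataset, plsr_models: dict[int, "object"] | None, config: UKFConfig,
               schedule: FeedSchedule, x0: np.ndarray, P0: np.ndarray | None = None,
               *, params: CGMParameters | None = None, n_ref: int = 1,
               measurements: np.ndarray | None = None) -> FilterResult:
    """Run the hybrid filter over a full process dataset.

    Per 120 s online row: two 60 s prediction steps followed by one
    measurement update with the PLSR estimate, then the nonnegativity
    projection.  The initial estimate ``x0`` refers to one update
    interval before the first online row, so every row receives exactly
    one update preceded by two predictions.

    ``measurements`` (T, 5) replaces the PLSR estimates with externally
    supplied concentration measurements (e.g. from a probe), in which
    case ``plsr_models`` may be None.
    """
    params = params or CGMParameters()
    online = dataset.online if hasattr(dataset, "online") else dataset
    times = online.times
    if measurements is None:
        if plsr_models is None:
            raise FilterError("either plsr_models or measurements must be supplied")
        for phase in np.unique(online.phase_index):
            if int(phase) not in plsr_models:
                raise FilterError(f"no trained PLS model for phase {int(phase)}")
    cad = np.diff(times) * 3600.0
    if not np.allclose(cad, config.dt_update, atol=1.0):
        raise ValueError("online cadence does not match config.dt_update")

    if measurements is None:
        Ymeas = plsr_measurements(online, plsr_models, n_ref=n_ref)
    else:
        Ymeas = np.asarray(measurements, dtype=float)
        if Ymeas.shape != (times.size, 5):
            raise ValueError(f"measurements must be ({times.size}, 5), got {Ymeas.shape}")
    x = np.asarray(x0, dtype=float).copy()
    P = _as_cov(config.P0 if P0 is None else P0, N_STATES, "P0")
    lb = config.lower_bounds
    dt_pred_h = config.dt_predict / 3600.0
    n_pred = int(round(config.dt_update / config.dt_predict))

    T = times.size
    res = FilterResult(
        times=times.copy(),
        x_prior=np.empty((T, N_STATES)), x_post=np.empty((T, N_STATES)),
        P_prior=np.empty((T, N_STATES, N_STATES)), P_post=np.empty((T, N_STATES, N_STATES)),
        innovations=np.empty((T, 5)), kalman_gains=np.empty((T, N_STATES, 5)),
    )
    for k in range(T):
        t_tick_start = times[k] - config.dt_update / 3600.0
        for j in range(n_pred):
            prop = cgm_propagator(params, schedule, t_tick_start + j * dt_pred_h,
                                  dt_pred_h, config.ode_substep_s)
            x, P = predict_step(x, P, config, prop)
        res.x_prior[k], res.P_prior[k] = x, P
        x, P, innov, K = update_step(x, P, Ymeas[k], config)
        x, P = constrain_posterior(
            x, P, lb, config,
            propagate=cgm_propagator(params, schedule, times[k], dt_pred_h,
                                     config.ode_substep_s))
        P = _psd_floor(P)
        res.x_post[k], res.P_post[k] = x, P
        res.innovations[k], res.kalman_gains[k] = innov, K
    return res
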