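"""Noise-covariance calibration for the hybrid filter.

The measurement-noise covariance R comes straight from the PLSR error:
its diagonal holds the squared per-output RMSE of the PLSR predictions
against offline samples of a calibration process.  The process-noise
covariance Q has no such direct estimate; its diagonal is tuned by a
derivative-free generalized pattern search in log10 space, minimizing
the mean squared error between the filter's posterior (interpolated to
the offline sampling times) and the offline measurements, with each
output standardized by its offline spread so biomass does not dominate
L-tyrosine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cgm import MEASURED_INDICES, N_STATES, CGMParameters, FeedSchedule
from .ukf import UKFConfig, run_filter

__all__ = ["NoiseSpec", "build_R", "pattern_search", "estimate_Q", "offline_objective"]


@dataclass
class NoiseSpec:
    """Calibrated noise diagonals plus provenance of the runs that made them."""

    r_diag: np.ndarray            # (5,) [g^2/L^2]
    q_diag: np.ndarray            # (10,)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r_diag = np.asarray(self.r_diag, dtype=float)
        self.q_diag = np.asarray(self.q_diag, dtype=float)
        if np.any(self.r_diag <= 0) or np.any(self.q_diag <= 0):
            raise ValueError("noise diagonals must be strictly positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"r_diag": self.r_diag.tolist(), "q_diag": self.q_diag.tolist(),
                       "provenance": self.provenance}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NoiseSpec":
        with open(path) as fh:
            d = json.load(fh)
        return cls(r_diag=np.array(d["r_diag"]), q_diag=np.array(d["q_diag"]),
                   provenance=d.get("provenance", {}))


def build_R(rmse_per_output: np.ndarray, *, floor: float = 1e-3) -> np.ndarray:
    """Measurement-noise covariance: diag of squared PLSR RMSEs.

    RMSEs below ``floor`` g/L are raised to it first — an output whose
    calibration samples happen to sit in a flat, near-zero stretch (the
    glycerol pathology: no batch-phase samples, so its error is computed
    over a range where the concentration is always ~0) would otherwise
    make the filter trust that channel absurdly much.
    """
    r = np.asarray(rmse_per_output, dtype=float)
    if r.shape != (5,):
        raise ValueError(f"expected 5 RMSEs, got shape {r.shape}")
    if np.any(~np.isfinite(r)) or np.any(r <= 0):
        raise ValueError("RMSEs must be finite and > 0")
    return np.diag(np.maximum(r, floor) ** 2)


@dataclass
class PatternSearchTrace:
    """Objective history of accepted iterates plus bookkeeping."""

    best_x: np.ndarray
    best_f: float
    history: list = field(default_factory=list)   # (n_eval, f_best) tuples
    n_eval: int = 0
    converged: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history, columns=["n_eval", "best_objective"])


def pattern_search(objective, x0: np.ndarray, bounds: tuple[float, float], *,
                   mesh0: float = 1.0, mesh_tol: float = 1e-3,
                   expand: float = 2.0, contract: float = 0.5,
                   max_evals: int = 500) -> PatternSearchTrace:
    """Generalized pattern search with opportunistic coordinate polling.

    Polls ``x +/- mesh * e_i`` in fixed coordinate order, moving to the
    first improving candidate (mesh expands on success, contracts when a
    full poll fails); stops when the mesh drops below ``mesh_tol`` or the
    evaluation budget is spent.  Fully deterministic.  Coordinates are
    clipped to ``bounds``.
    """
    x = np.asarray(x0, dtype=float).copy()
    lo, hi = bounds
    x = np.clip(x, lo, hi)
    f = objective(x)
    n_eval = 1
    trace = PatternSearchTrace(best_x=x.copy(), best_f=f, history=[(1, f)])
    mesh = mesh0
    d = x.size
    while mesh >= mesh_tol and n_eval < max_evals:
        improved = False
        for i in range(d):
            for sgn in (+1.0, -1.0):
                if n_eval >= max_evals:
                    break
                cand = x.copy()
                cand[i] = np.clip(cand[i] + sgn * mesh, lo, hi)
                if cand[i] == x[i]:
                    continue
                fc = objective(cand)
                n_eval += 1
                if fc < f:
                    x, f = cand, fc
                    trace.history.append((n_eval, f))
                    improved = True
                    break
            if improved or n_eval >= max_evals:
                break
        mesh = mesh * expand if improved else mesh * contract
    trace.best_x, trace.best_f, trace.n_eval = x, f, n_eval
    trace.converged = mesh < mesh_tol
    return trace


def offline_objective(result, offline: pd.DataFrame, y_sd: np.ndarray) -> float:
    """Standardized MSE of the posterior at the offline sampling times."""
    t = offline["time_h"].to_numpy(float)
    mask = (t >= result.times[0]) & (t <= result.times[-1])
    t = t[mask]
    if t.size == 0:
        raise ValueError("no offline samples inside the filtered time span")
    pred = result.interpolate_post(t, cols=MEASURED_INDICES)
    obs = offline.loc[mask, ["X", "S", "P", "A", "Y"]].to_numpy(float)
    return float(np.mean(((pred - obs) / y_sd) ** 2))


def offline_sd(offline: pd.DataFrame, *, floor: float = 1e-3) -> np.ndarray:
    sd = offline[["X", "S", "P", "A", "Y"]].to_numpy(float).std(axis=0, ddof=0)
    return np.maximum(sd, floor)


def estimate_Q(dataset, plsr_models, config_template: UKFConfig,
               schedule: FeedSchedule, x0: np.ndarray, *,
               params: CGMParameters | None = None,
               q_init: np.ndarray | None = None,
               bounds: tuple[float, float] = (1e-8, 1e2),
               free_indices: list[int] | None = None,
               mesh0: float = 1.0, mesh_tol: float = 1e-3, max_evals: int = 500,
               seed: int = 0) -> tuple[np.ndarray, PatternSearchTrace]:
    """Tune the diagonal of Q against offline samples of one process.

    Runs the full hybrid filter at every candidate, so the cost is
    ``max_evals`` filter passes; ``free_indices`` restricts the search
    to a subset of state coordinates (the rest stay at ``q_init``),
    which is how the expensive 10-dimensional poll is kept affordable.
    The search moves in log10(q).  Deterministic given the inputs (the
    seed only labels the provenance; the search itself draws no random
    numbers).
    """
    if len(dataset.offline) < 5:
        raise ValueError("need at least 5 offline samples to calibrate Q")
    params = params or CGMParameters()
    q0 = np.array(q_init, dtype=float) if q_init is not None else np.diag(config_template.Q).copy()
    lo, hi = bounds
    if np.any(q0 < lo) or np.any(q0 > hi):
        raise ValueError("q_init outside bounds")
    free = list(range(N_STATES)) if free_indices is None else list(free_indices)
    y_sd = offline_sd(dataset.offline)

    def run_with(q_diag: np.ndarray):
        cfg = UKFConfig(alpha=config_template.alpha, beta=config_template.beta,
                        kappa=config_template.kappa, Q=np.diag(q_diag),
                        R=config_template.R, P0=config_template.P0,
                        lower_bounds=config_template.lower_bounds,
                        dt_predict=config_template.dt_predict,
                        dt_update=config_template.dt_update,
                        ode_substep_s=config_template.ode_substep_s)
        return run_filter(dataset, plsr_models, cfg, schedule, x0, params=params)

    def objective(logq_free: np.ndarray) -> float:
        q = q0.copy()
        q[free] = 10.0 ** logq_free
        try:
            res = run_with(q)
        except Exception:
            return np.inf
        return offline_objective(res, dataset.offline, y_sd)

    trace = pattern_search(objective, np.log10(q0[free]),
                           (np.log10(lo), np.log10(hi)),
                           mesh0=mesh0, mesh_tol=mesh_tol, max_evals=max_evals)
    if not np.isfinite(trace.best_f):
        raise RuntimeError("calibration failed: filter diverged at every candidate")
    q_best = q0.copy()
    q_best[free] = 10.0 ** trace.best_x
    return q_best, trace
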