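"""Coarse-grained proteome-allocation model of a fed-batch L-phenylalanine process.

The model tracks six reactor states — volume ``V`` [L], glycerol ``S``,
biomass ``X``, L-phenylalanine ``P``, acetate ``A`` and L-tyrosine ``Y``
[all g/L] — plus four intracellular pools expressed as biomass mass
fractions: the transport/catabolism proteome sector ``phi_T``, the
ribosomal sector ``phi_R``, the heterologous production sector ``phi_Fp``
and a central metabolite pool ``m``.  A fixed housekeeping sector
``phi_Q`` completes the proteome.  Reaction rates are gated by the sector
sizes, so the cell's resource-allocation state shapes the macroscopic
kinetics: glycerol uptake is catalysed by ``phi_T``, growth by ``phi_R``
(and by L-tyrosine, which the production strain cannot synthesise),
product formation by ``phi_Fp``, and acetate overflow switches on when
catabolic flux exceeds a respiratory capacity threshold.

The same right-hand side serves two roles: ground-truth simulator for the
synthetic process generator, and state-transition function inside the
unscented Kalman filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "STATE_NAMES",
    "MEASURED_NAMES",
    "MEASURED_INDICES",
    "N_STATES",
    "CGMParameters",
    "CGMState",
    "FeedSchedule",
    "ReactionRates",
    "Trajectory",
    "InvalidStateError",
    "SimulationError",
    "ConfigurationError",
    "reaction_rates",
    "allocation",
    "derivatives",
    "simulate",
    "measure",
]

# ---------------------------------------------------------------------------
# State layout

#: Order of the state vector used everywhere in the package.
STATE_NAMES: tuple[str, ...] = (
    "V", "S", "X", "P", "A", "Y", "phi_T", "phi_R", "phi_Fp", "m",
)
N_STATES = len(STATE_NAMES)

_V, _S, _X, _P, _A, _Y, _PHI_T, _PHI_R, _PHI_FP, _M = range(N_STATES)

#: Fixed measurement ordering (biomass, glycerol, L-phe, acetate, L-tyr).
MEASURED_NAMES: tuple[str, ...] = ("X", "S", "P", "A", "Y")
MEASURED_INDICES: tuple[int, ...] = (_X, _S, _P, _A, _Y)


class InvalidStateError(ValueError):
    """A state vector violates the model invariants (non-finite, V <= 0, ...)."""


class SimulationError(RuntimeError):
    """ODE integration failed; carries the last time reached."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class ConfigurationError(ValueError):
    """Parameters or schedule are inconsistent."""


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class CGMParameters:
    """Kinetic parameters of the coarse-grained model.

    The numeric defaults are engineering choices calibrated only to
    reproduce the qualitative phenotype of the process (batch phase ends
    after roughly 13-17 h, specific growth tracks the 0.1 1/h feed
    setpoint, tens of g/L product after induction, low acetate); they are
    not fitted to any experimental dataset.

    Attributes
    ----------
    k_T, k_R, k_F : float
        Catalytic rate constants of the transport, ribosomal and
        production sectors [1/h].
    K_S : float
        Glycerol half-saturation of uptake [g/L].
    K_mR, K_mF : float
        Metabolite-pool half-saturation of growth / production [-].
    K_Y : float
        L-tyrosine half-saturation of growth [g/L].
    c_Y : float
        L-tyrosine demand per unit biomass formed [g/g].
    Y_MS, Y_XM, Y_PM, Y_AM : float
        Yields: metabolite per glycerol, biomass per metabolite, product
        per metabolite, acetate per metabolite [g/g].
    v_crit : float
        Specific catabolic capacity above which overflow sets in
        [g/(g h)].
    k_A : float
        Overflow gain [-].
    phi_Q : float
        Fixed housekeeping proteome fraction [-].
    alpha_R_max : float
        Ceiling of the ribosomal allocation response [-].
    alpha_Fp_max, K_I : float
        Induction allocation response: maximum production allocation [-]
        and IPTG half-saturation [mM].
    mu_set : float
        Growth-rate setpoint of the exponential-feed phase [1/h].
    q_feed3 : float
        Specific glycerol feed rate of the production phase
        [g_gly/(g_X h)].
    """

    k_T: float = 2.5
    k_R: float = 1.8
    k_F: float = 0.9
    K_S: float = 0.1
    K_mR: float = 0.05
    K_mF: float = 0.05
    K_Y: float = 0.005
    c_Y: float = 0.02
    Y_MS: float = 0.7
    Y_XM: float = 0.8
    Y_PM: float = 0.6
    Y_AM: float = 0.5
    v_crit: float = 0.6
    k_A: float = 0.3
    phi_Q: float = 0.45
    alpha_R_max: float = 0.8
    alpha_Fp_max: float = 0.25
    K_I: float = 0.02
    mu_set: float = 0.1
    q_feed3: float = 0.18

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigurationError(f"parameter {f.name} must be finite and > 0, got {v}")
        if not 0 < self.phi_Q < 1:
            raise ConfigurationError("phi_Q must lie in (0, 1)")
        if self.alpha_Fp_max >= 1 - self.phi_Q:
            raise ConfigurationError("alpha_Fp_max must be < 1 - phi_Q")
        if self.alpha_R_max > 1:
            raise ConfigurationError("alpha_R_max must be <= 1 (keeps alpha_T >= 0)")

    # -- serialization (unit-suffixed keys, one swap-in config file) --------

    _UNIT_KEYS = {
        "k_T": "kT_per_h", "k_R": "kR_per_h", "k_F": "kF_per_h",
        "K_S": "KS_g_per_L", "K_mR": "KmR_frac", "K_mF": "KmF_frac",
        "K_Y": "KY_g_per_L", "c_Y": "cY_g_per_g",
        "Y_MS": "YMS_g_per_g", "Y_XM": "YXM_g_per_g",
        "Y_PM": "YPM_g_per_g", "Y_AM": "YAM_g_per_g",
        "v_crit": "vcrit_g_per_g_h", "k_A": "kA_frac",
        "phi_Q": "phiQ_frac", "alpha_R_max": "alphaRmax_frac",
        "alpha_Fp_max": "alphaFpmax_frac", "K_I": "KI_mM",
        "mu_set": "muset_per_h", "q_feed3": "qfeed3_g_per_g_h",
    }

    def to_dict(self) -> dict[str, float]:
        return {self._UNIT_KEYS[f.name]: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "CGMParameters":
        inv = {v: k for k, v in cls._UNIT_KEYS.items()}
        unknown = set(d) - set(inv)
        if unknown:
            raise ConfigurationError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{inv[k]: float(v) for k, v in d.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CGMParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_overrides(self, **kw: float) -> "CGMParameters":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# State


@dataclass
class CGMState:
    """One point of the 10-dimensional model state.

    Concentrations in g/L, volume in L, intracellular pools as mass
    fractions of biomass.  The three dynamic proteome sectors together
    with the fixed housekeeping sector close the proteome:
    ``phi_T + phi_R + phi_Fp <= 1 - phi_Q``; the metabolite pool ``m`` is
    accounted separately.
    """

    V: float = 1.0
    S: float = 4.0
    X: float = 0.02
    P: float = 0.0
    A: float = 0.0
    Y: float = 0.1
    phi_T: float = 0.30
    phi_R: float = 0.20
    phi_Fp: float = 0.0
    m: float = 0.05

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "CGMState":
        x = np.asarray(x, dtype=float)
        if x.shape != (N_STATES,):
            raise InvalidStateError(f"state vector must have length {N_STATES}, got shape {x.shape}")
        return cls(**dict(zip(STATE_NAMES, x)))

    def validate(self, params: CGMParameters | None = None, tol: float = 1e-9) -> None:
        x = self.to_array()
        if not np.all(np.isfinite(x)):
            raise InvalidStateError("state contains non-finite components")
        if self.V <= 0:
            raise InvalidStateError(f"volume must be > 0, got {self.V}")
        if np.any(x < -tol):
            bad = [STATE_NAMES[i] for i in np.flatnonzero(x < -tol)]
            raise InvalidStateError(f"negative state components: {bad}")
        if params is not None:
            if self.phi_T + self.phi_R + self.phi_Fp > 1 - params.phi_Q + tol:
                raise InvalidStateError("proteome closure violated: sum(phi) > 1 - phi_Q")


class ReactionRates(NamedTuple):
    """Specific rates [g/(g h)] plus the growth rate mu [1/h]."""

    v_T: float
    v_R: float
    v_F: float
    v_A: float
    mu: float
    v_Y: float


RATE_NAMES = ReactionRates._fields


# ---------------------------------------------------------------------------
# Feed schedule


@dataclass
class FeedSchedule:
    """Three-phase fed-batch schedule.

    Phase 1 (batch) runs until ``t_batch_end`` with no feed; phase 2
    (biomass production) applies a closed-loop exponential feed that
    supplies glycerol for growth at ``mu_set``; phase 3 (induced
    production, from ``t_induction``) feeds at a constant specific rate
    ``q_feed3``.  The phase-2 medium also carries L-phe and L-tyr (the
    strain is a double auxotroph); the phase-3 medium carries glycerol
    only.  IPTG is applied at induction and is a schedule input, not a
    dynamic state.
    """

    t_batch_end: float
    t_induction: float
    t_end: float
    iptg: float = 0.3
    S_feed2: float = 312.5
    S_feed3: float = 800.0
    P_feed2: float = 1.65
    Y_feed2: float = 3.75
    #: optional replacement feed law F(t, state_array) -> L/h
    feed_law: Callable[[float, np.ndarray], float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0 < self.t_batch_end < self.t_induction < self.t_end:
            raise ConfigurationError(
                "schedule must satisfy 0 < t_batch_end < t_induction < t_end, got "
                f"({self.t_batch_end}, {self.t_induction}, {self.t_end})"
            )
        if self.iptg < 0:
            raise ConfigurationError("iptg must be >= 0")

    def phase_of(self, t) -> np.ndarray | int:
        """Phase index in {1, 2, 3} for scalar or array times."""
        t = np.asarray(t)
        ph = np.where(t < self.t_batch_end, 1, np.where(t < self.t_induction, 2, 3))
        return ph if ph.ndim else int(ph)

    def iptg_at(self, t: float) -> float:
        return self.iptg if t >= self.t_induction else 0.0

    def feed_concentrations(self, phase: int) -> np.ndarray:
        """Feed concentrations [S, X, P, A, Y] of the active medium [g/L]."""
        c = np.zeros(5)
        if phase == 2:
            c[0], c[2], c[4] = self.S_feed2, self.P_feed2, self.Y_feed2
        elif phase == 3:
            c[0] = self.S_feed3
        return c

    def feed_rate(self, t: float, x: np.ndarray, params: CGMParameters) -> float | np.ndarray:
        """Volumetric feed rate F [L/h]; closed-loop in biomass inventory.

        Phase 2 supplies glycerol to sustain growth at ``mu_set`` given
        the effective biomass-on-glycerol yield ``Y_MS * Y_XM``; phase 3
        supplies ``q_feed3`` g glycerol per g biomass per hour.
        """
        if self.feed_law is not None:
            return max(0.0, self.feed_law(t, x))
        phase = self.phase_of(t)
        x = np.asarray(x, dtype=float)
        XV = np.clip(x[..., _X], 0.0, None) * np.clip(x[..., _V], 0.0, None)
        if phase == 1:
            return np.zeros_like(XV) if XV.ndim else 0.0
        if phase == 2:
            return params.mu_set / (params.Y_MS * params.Y_XM) * XV / self.S_feed2
        return params.q_feed3 * XV / self.S_feed3

    def to_dict(self) -> dict:
        return {
            "t_batch_end_h": self.t_batch_end,
            "t_induction_h": self.t_induction,
            "t_end_h": self.t_end,
            "iptg_mM": self.iptg,
            "Sfeed2_g_per_L": self.S_feed2,
            "Sfeed3_g_per_L": self.S_feed3,
            "Pfeed2_g_per_L": self.P_feed2,
            "Yfeed2_g_per_L": self.Y_feed2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeedSchedule":
        return cls(
            t_batch_end=d["t_batch_end_h"], t_induction=d["t_induction_h"],
            t_end=d["t_end_h"], iptg=d["iptg_mM"],
            S_feed2=d["Sfeed2_g_per_L"], S_feed3=d["Sfeed3_g_per_L"],
            P_feed2=d["Pfeed2_g_per_L"], Y_feed2=d["Yfeed2_g_per_L"],
        )


# ---------------------------------------------------------------------------
# Kinetics


def _rates_array(x: np.ndarray, params: CGMParameters, iptg: float) -> tuple[np.ndarray, ...]:
    """Vectorised specific rates for states of shape (..., 10).

    Concentrations and fractions are clipped at zero for the rate
    evaluation only, so slightly negative sigma-point excursions remain
    well defined; the raw state is never modified.
    """
    p = params
    S = np.clip(x[..., _S], 0.0, None)
    Y = np.clip(x[..., _Y], 0.0, None)
    phi_T = np.clip(x[..., _PHI_T], 0.0, None)
    phi_R = np.clip(x[..., _PHI_R], 0.0, None)
    phi_Fp = np.clip(x[..., _PHI_FP], 0.0, None)
    m = np.clip(x[..., _M], 0.0, None)

    v_T = p.k_T * phi_T * S / (p.K_S + S)
    v_R = p.k_R * phi_R * (m / (p.K_mR + m)) * (Y / (p.K_Y + Y))
    v_F = p.k_F * phi_Fp * m / (p.K_mF + m)
    v_A = p.k_A * np.clip(v_T - p.v_crit, 0.0, None)
    mu = v_R
    v_Y = p.c_Y * mu
    return v_T, v_R, v_F, v_A, mu, v_Y


def reaction_rates(state: CGMState | np.ndarray, params: CGMParameters,
                   iptg: float = 0.0) -> ReactionRates:
    """Specific reaction rates at one state.

    ``v_T`` glycerol uptake, ``v_R`` growth (ribosome-catalysed, L-tyr
    limited), ``v_F`` product formation, ``v_A`` acetate overflow
    (active only above the catabolic capacity ``v_crit``), ``mu`` the
    specific growth rate and ``v_Y`` the L-tyr consumption rate.
    """
    x = state.to_array() if isinstance(state, CGMState) else np.asarray(state, dtype=float)
    if x.shape != (N_STATES,):
        raise InvalidStateError(f"expected a single state of length {N_STATES}")
    if not np.all(np.isfinite(x)):
        raise InvalidStateError("state contains non-finite components")
    return ReactionRates(*(float(v) for v in _rates_array(x, params, iptg)))


def allocation(state: CGMState | np.ndarray, params: CGMParameters,
               iptg: float = 0.0) -> dict[str, float | np.ndarray]:
    """Proteome allocation targets ``alpha_i``; they always sum to one.

    Induction diverts a Monod-type share of the proteome to the
    production sector; ribosomal allocation responds to the metabolite
    pool; the transporter sector takes the remainder.
    """
    if iptg < 0:
        raise ConfigurationError("iptg must be >= 0")
    p = params
    x = state.to_array() if isinstance(state, CGMState) else np.asarray(state, dtype=float)
    m = np.clip(x[..., _M], 0.0, None)
    alpha_Q = p.phi_Q
    alpha_Fp = p.alpha_Fp_max * iptg / (p.K_I + iptg) if iptg > 0 else 0.0
    alpha_R = p.alpha_R_max * (m / (p.K_mR + m)) * (1.0 - alpha_Fp - alpha_Q)
    alpha_T = 1.0 - alpha_R - alpha_Fp - alpha_Q
    return {"alpha_T": alpha_T, "alpha_R": alpha_R, "alpha_Fp": alpha_Fp, "alpha_Q": alpha_Q}


def derivatives(t: float, x: np.ndarray, params: CGMParameters,
                schedule: FeedSchedule) -> np.ndarray:
    """Right-hand side dx/dt for states of shape (10,) or (k, 10).

    Liquid-phase balances use the standard fed-batch form (dilution by
    F/V); proteome sectors relax toward their allocation targets at the
    growth rate; the metabolite pool balances uptake against the growth,
    product and overflow drains plus growth dilution.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if x.shape[-1] != N_STATES:
        raise InvalidStateError(f"state vectors must have length {N_STATES}")
    V = x[..., _V]
    if np.any(V <= 0):
        raise InvalidStateError(f"volume must be > 0 at t={t:.4f}")

    p = params
    phase = schedule.phase_of(t)
    iptg = schedule.iptg_at(t)
    v_T, v_R, v_F, v_A, mu, v_Y = _rates_array(x, p, iptg)
    al = allocation(x, p, iptg)

    F = schedule.feed_rate(t, x, p)
    cf = schedule.feed_concentrations(phase)  # [S, X, P, A, Y] in feed
    D = F / V  # dilution rate [1/h]

    X = np.clip(x[..., _X], 0.0, None)
    dx = np.empty_like(x)
    dx[..., _V] = F
    dx[..., _S] = -v_T * X + D * (cf[0] - x[..., _S])
    dx[..., _X] = mu * X - D * x[..., _X]
    dx[..., _P] = v_F * X + D * (cf[2] - x[..., _P])
    dx[..., _A] = v_A * X - D * x[..., _A]
    dx[..., _Y] = -v_Y * X + D * (cf[4] - x[..., _Y])
    dx[..., _PHI_T] = mu * (al["alpha_T"] - x[..., _PHI_T])
    dx[..., _PHI_R] = mu * (al["alpha_R"] - x[..., _PHI_R])
    dx[..., _PHI_FP] = mu * (al["alpha_Fp"] - x[..., _PHI_FP])
    dx[..., _M] = (p.Y_MS * v_T - mu / p.Y_XM - v_F / p.Y_PM - v_A / p.Y_AM
                   - mu * x[..., _M])
    return dx if not single else dx.reshape(N_STATES)


# ---------------------------------------------------------------------------
# Measurement map


def measure(state: CGMState | np.ndarray) -> np.ndarray:
    """Noise-free observation [biomass, glycerol, L-phe, acetate, L-tyr].

    Accepts a single state or an array of states (..., 10); intracellular
    components never enter the output.
    """
    x = state.to_array() if isinstance(state, CGMState) else np.asarray(state, dtype=float)
    return x[..., list(MEASURED_INDICES)]


# ---------------------------------------------------------------------------
# Trajectory container & simulation


@dataclass
class Trajectory:
    """Simulated path: times [h], states (T, 10), specific rates (T, 6),
    volumetric feed rate (T,) [L/h], phase index per point, and the two
    cumulative glycerol bookkeeping integrals (fed-in and taken-up mass
    [g]) carried along by the integrator for mass-balance checks."""

    times: np.ndarray
    states: np.ndarray
    rates: np.ndarray
    feed: np.ndarray
    phase_index: np.ndarray
    cum_S_in: np.ndarray
    cum_S_up: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if np.any(np.diff(self.phase_index) < 0):
            raise ValueError("phase index must be non-decreasing")

    def interpolate_states(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of all state columns onto times ``t``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            raise ValueError("interpolation times outside trajectory span")
        out = np.empty((t.size, N_STATES))
        for j in range(N_STATES):
            out[:, j] = np.interp(t, self.times, self.states[:, j])
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.times})
        for j, n in enumerate(STATE_NAMES):
            df[n] = self.states[:, j]
        for j, n in enumerate(RATE_NAMES):
            df[n] = self.rates[:, j]
        df["F_L_per_h"] = self.feed
        df["phase"] = self.phase_index
        df["cum_S_in_g"] = self.cum_S_in
        df["cum_S_up_g"] = self.cum_S_up
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        return cls(
            times=df["time_h"].to_numpy(float),
            states=df[list(STATE_NAMES)].to_numpy(float),
            rates=df[list(RATE_NAMES)].to_numpy(float),
            feed=df["F_L_per_h"].to_numpy(float),
            phase_index=df["phase"].to_numpy(int),
            cum_S_in=df["cum_S_in_g"].to_numpy(float),
            cum_S_up=df["cum_S_up_g"].to_numpy(float),
        )


def simulate(x0: CGMState | np.ndarray, params: CGMParameters, schedule: FeedSchedule,
             t_grid: np.ndarray, *, rtol: float = 1e-9, atol: float = 1e-9,
             method: str = "LSODA") -> Trajectory:
    """Integrate the model over ``t_grid``, phase by phase.

    Each process phase is integrated separately so the feed-law switch
    never lands inside an adaptive step.  Two bookkeeping states (the
    cumulative glycerol mass fed in and taken up, in grams) ride along in
    the same integration, making the liquid-phase glycerol balance
    checkable to integrator accuracy.  Components more negative than the
    absolute tolerance raise; smaller excursions are clipped to zero in
    the returned states.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D array with >= 2 points")
    x0 = x0.to_array() if isinstance(x0, CGMState) else np.asarray(x0, dtype=float)
    CGMState.from_array(x0).validate(params)

    def rhs(t, z):
        dx = derivatives(t, z[:N_STATES], params, schedule)
        F = schedule.feed_rate(t, z[:N_STATES], params)
        phase = schedule.phase_of(t)
        cf = schedule.feed_concentrations(phase)
        v_T = _rates_array(z[:N_STATES], params, schedule.iptg_at(t))[0]
        X = max(z[_X], 0.0)
        return np.concatenate([dx, [F * cf[0], v_T * X * z[_V]]])

    # phase boundaries clipped to the requested span
    cuts = [t_grid[0]]
    for b in (schedule.t_batch_end, schedule.t_induction):
        if t_grid[0] < b < t_grid[-1]:
            cuts.append(b)
    cuts.append(t_grid[-1])

    # each t_grid point falls in exactly one half-open segment (a, b], so the
    # concatenated t_eval arrays reproduce t_grid[1:] exactly
    z = np.concatenate([x0, [0.0, 0.0]])
    times_out, states_out, cumin_out, cumup_out = [t_grid[0]], [x0.copy()], [0.0], [0.0]
    for a, b in zip(cuts[:-1], cuts[1:]):
        t_eval = t_grid[(t_grid > a) & (t_grid <= b)]
        # always integrate to the segment end so the next phase starts exactly at b
        sol = solve_ivp(rhs, (a, b), z, method=method,
                        t_eval=np.unique(np.append(t_eval, b)),
                        rtol=rtol, atol=atol)
        if not sol.success:
            last = sol.t[-1] if sol.t.size else a
            raise SimulationError(f"integrator failed in ({a:.3f}, {b:.3f}) h: {sol.message}",
                                  last_time=float(last))
        for k in range(sol.t.size):
            if sol.t[k] in t_eval:
                times_out.append(float(sol.t[k]))
                states_out.append(sol.y[:N_STATES, k].copy())
                cumin_out.append(float(sol.y[N_STATES, k]))
                cumup_out.append(float(sol.y[N_STATES + 1, k]))
        z = sol.y[:, -1]

    times = np.array(times_out)
    states = np.vstack(states_out)
    cum_in = np.array(cumin_out)
    cum_up = np.array(cumup_out)

    if np.any(states < -max(atol * 100, 1e-7)):
        worst = states.min()
        raise SimulationError(f"state went negative beyond tolerance (min={worst:.3e})")
    states = np.clip(states, 0.0, None)

    phases = schedule.phase_of(times)
    rates = np.empty((times.size, len(RATE_NAMES)))
    feed = np.empty(times.size)
    for i, (t, x) in enumerate(zip(times, states)):
        rates[i] = _rates_array(x, params, schedule.iptg_at(t))
        feed[i] = schedule.feed_rate(t, x, params)
    return Trajectory(times=times, states=states, rates=rates, feed=feed,
                      phase_index=np.asarray(phases), cum_S_in=cum_in, cum_S_up=cum_up)


def detect_batch_end(params: CGMParameters, x0: CGMState | None = None, *,
                     threshold: float = 0.01, t_max: float = 40.0) -> float:
    """Time at which batch-phase glycerol first falls below ``threshold`` g/L.

    Stands in for the dissolved-oxygen spike that marks glycerol
    depletion in the real process: the batch dynamics are simulated with
    no feed and the crossing time located by a root solve on the
    interpolated glycerol trace.
    """
    x0 = x0 or CGMState()
    # batch-only schedule: boundaries far beyond t_max so no feed ever starts
    sched = FeedSchedule(t_batch_end=t_max + 1, t_induction=t_max + 2, t_end=t_max + 3,
                         iptg=0.0)
    grid = np.linspace(0.0, t_max, int(t_max * 60) + 1)
    traj = simulate(x0, params, sched, grid, rtol=1e-9, atol=1e-9)
    S = traj.states[:, _S]
    below = np.flatnonzero(S < threshold)
    if below.size == 0:
        raise SimulationError(f"glycerol never fell below {threshold} g/L within {t_max} h")
    i = below[0]
    if i == 0:
        return float(traj.times[0])
    # linear bracketing between the neighbouring grid points
    t0, t1 = traj.times[i - 1], traj.times[i]
    s0, s1 = S[i - 1], S[i]
    return float(t0 + (s0 - threshold) / (s0 - s1) * (t1 - t0))
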