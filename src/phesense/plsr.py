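"""Phase-wise partial least-squares regression (SIMPLS) soft sensor.

Maps the eight routinely logged online channels (stirrer speed, aeration
rate, pO2, temperature, pH, off-gas CO2, substrate feed mass flow,
cumulative base addition) to the five measurable broth concentrations
(biomass, glycerol, L-phe, acetate, L-tyr).  Because offline samples are
sparse, the regression is trained against model-simulated concentrations
interpolated onto the online timestamps.  The three process phases have
different dynamics, so one model is fitted per phase, with inputs
offset-centered against the phase-start row so that every phase starts
from a common origin.  The latent-variable count is chosen by five-fold
cross-validation (RMSECV).

SIMPLS is implemented directly (successive SVDs of the deflated
cross-product matrix X'Y with loading-orthogonal deflation); at full rank
it coincides with ordinary least squares, which the test suite exploits
as an oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .cgm import MEASURED_NAMES, Trajectory, measure

__all__ = [
    "CHANNELS",
    "OnlineMatrix",
    "PhasePLSModel",
    "CVReport",
    "phase_offset_center",
    "build_training_outputs",
    "simpls_fit",
    "predict",
    "crossvalidate",
    "rmse",
]

#: Fixed column order of the online matrix.
CHANNELS: tuple[str, ...] = (
    "stirrer_rpm",
    "aeration_L_per_min",
    "pO2_pct",
    "temperature_C",
    "pH",
    "co2_offgas_pct",
    "feed_massflow_g_per_h",
    "base_cumulative_mL",
)
N_CHANNELS = len(CHANNELS)


@dataclass
class OnlineMatrix:
    """Dense online process log at fixed cadence.

    ``values`` has one column per entry of :data:`CHANNELS`, in that
    order.  Ingest from delimited text forward-fills isolated gaps (up to
    three consecutive rows); longer gaps are an error.
    """

    times: np.ndarray              # [h]
    values: np.ndarray             # (T, 8)
    phase_index: np.ndarray        # (T,) in {1,2,3}

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.phase_index = np.asarray(self.phase_index, dtype=int)
        if self.values.shape != (self.times.size, N_CHANNELS):
            raise ValueError(f"values must be (T, {N_CHANNELS}), got {self.values.shape}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("online times must be strictly increasing")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("online matrix contains missing values after ingest")

    def phase_rows(self, phase: int) -> np.ndarray:
        return np.flatnonzero(self.phase_index == phase)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.times})
        for j, c in enumerate(CHANNELS):
            df[c] = self.values[:, j]
        df["phase"] = self.phase_index
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, max_ffill: int = 3,
                   column_map: dict[str, str] | None = None) -> "OnlineMatrix":
        """Build from a table with named channel columns.

        ``column_map`` translates file column names to the canonical
        channel names.  Missing values are forward-filled up to
        ``max_ffill`` consecutive rows.
        """
        if column_map:
            df = df.rename(columns=column_map)
        missing = [c for c in ("time_h", *CHANNELS, "phase") if c not in df.columns]
        if missing:
            raise ValueError(f"online table lacks columns: {missing}")
        vals = df[list(CHANNELS)].copy()
        if vals.isna().any().any():
            filled = vals.ffill(limit=max_ffill)
            if filled.isna().any().any():
                bad = filled.columns[filled.isna().any()].tolist()
                raise ValueError(f"gap longer than {max_ffill} rows in channels {bad}")
            vals = filled
        return cls(times=df["time_h"].to_numpy(float), values=vals.to_numpy(float),
                   phase_index=df["phase"].to_numpy(int))


# ---------------------------------------------------------------------------
# Centering and training outputs


def phase_offset_center(X: np.ndarray, *, n_ref: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Offset-center the rows of one phase against its start.

    Subtracts the phase-start reference ``x0_ref`` (the first row, or the
    mean of the first ``n_ref`` rows to damp sensor noise) from every
    row, so each phase begins at the origin regardless of where the
    previous phase left the signals.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("phase must have at least 2 rows")
    x0_ref = X[: max(1, n_ref)].mean(axis=0)
    return X - x0_ref, x0_ref


def build_training_outputs(traj: Trajectory, online_times: np.ndarray) -> np.ndarray:
    """Interpolate the simulated measurable concentrations to online times.

    Returns a (T, 5) matrix in the fixed measurement order.  Query times
    must lie within the trajectory span — no extrapolation.
    """
    online_times = np.asarray(online_times, dtype=float)
    if online_times.size and (online_times.min() < traj.times[0] - 1e-12
                              or online_times.max() > traj.times[-1] + 1e-12):
        raise ValueError("online times extend beyond the trajectory span (no extrapolation)")
    conc = measure(traj.states)          # (T_traj, 5)
    out = np.empty((online_times.size, conc.shape[1]))
    for j in range(conc.shape[1]):
        out[:, j] = np.interp(online_times, traj.times, conc[:, j])
    return out


# ---------------------------------------------------------------------------
# SIMPLS


@dataclass
class PhasePLSModel:
    """Fitted per-phase PLS model.

    Prediction is the affine map ``yhat = (x - x_mean) @ B + y_mean``
    applied to offset-centered inputs; ``x0_ref`` records the phase-start
    offset used for centering (a new phase supplies its own first row in
    its place).  Weights, loadings and scores follow SIMPLS conventions;
    training scores are mutually orthogonal.
    """

    phase: int
    x0_ref: np.ndarray            # (8,)  phase-start reference of the inputs
    x_mean: np.ndarray            # (8,)  SIMPLS centering of the inputs
    y_mean: np.ndarray            # (5,)
    weights: np.ndarray           # (8, a)  R: X-weights, yhat scores t = Xc R
    x_loadings: np.ndarray        # (8, a)
    y_loadings: np.ndarray        # (5, a)
    coefficients: np.ndarray      # (8, 5)
    intercept: np.ndarray         # (5,)
    n_lv: int
    rmse_train: np.ndarray = field(default_factory=lambda: np.full(5, np.nan))

    def to_json(self, path) -> None:
        def mat(a):
            a = np.asarray(a)
            return {"shape": list(a.shape), "data": a.ravel().tolist()}
        obj = {
            "phase": self.phase, "n_lv": self.n_lv,
            "input_columns": list(CHANNELS), "output_columns": list(MEASURED_NAMES),
            "x0_ref": mat(self.x0_ref), "x_mean": mat(self.x_mean),
            "y_mean": mat(self.y_mean), "weights": mat(self.weights),
            "x_loadings": mat(self.x_loadings), "y_loadings": mat(self.y_loadings),
            "coefficients": mat(self.coefficients), "intercept": mat(self.intercept),
            "rmse_train": mat(self.rmse_train),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PhasePLSModel":
        with open(path) as fh:
            obj = json.load(fh)

        def unmat(d):
            return np.array(d["data"], dtype=float).reshape(d["shape"])

        return cls(phase=obj["phase"], n_lv=obj["n_lv"],
                   x0_ref=unmat(obj["x0_ref"]), x_mean=unmat(obj["x_mean"]),
                   y_mean=unmat(obj["y_mean"]), weights=unmat(obj["weights"]),
                   x_loadings=unmat(obj["x_loadings"]), y_loadings=unmat(obj["y_loadings"]),
                   coefficients=unmat(obj["coefficients"]), intercept=unmat(obj["intercept"]),
                   rmse_train=unmat(obj["rmse_train"]))


def simpls_fit(Xc: np.ndarray, Y: np.ndarray, n_lv: int, *, phase: int = 0,
               x0_ref: np.ndarray | None = None) -> PhasePLSModel:
    """Fit a PLS model with ``n_lv`` latent variables by SIMPLS.

    ``Xc`` are the (offset-centered) inputs and ``Y`` the outputs; both
    are additionally mean-centered internally, and the fitted affine map
    absorbs those means.  The de Jong construction takes, at each step,
    the dominant singular vector of the deflated cross-product ``S = X'Y``
    as the X-weight, then deflates ``S`` against an orthonormal basis of
    the X-loadings so that successive score vectors are orthogonal.
    """
    Xc = np.asarray(Xc, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Xc.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n, p = Xc.shape
    q = Y.shape[1]

    x_mean = Xc.mean(axis=0)
    y_mean = Y.mean(axis=0)
    X0 = Xc - x_mean
    Y0 = Y - y_mean

    max_lv = int(np.linalg.matrix_rank(X0))
    if not 1 <= n_lv <= max_lv:
        raise ValueError(f"n_lv={n_lv} not attainable; rank of centered X is {max_lv}")

    S = X0.T @ Y0
    R = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((q, n_lv))
    V = np.zeros((p, n_lv))
    for a in range(n_lv):
        u, sv, _ = np.linalg.svd(S, full_matrices=False)
        r = u[:, 0]
        t = X0 @ r
        normt = np.linalg.norm(t)
        if normt < 1e-12:
            raise ValueError(f"degenerate score at component {a + 1}; reduce n_lv")
        t /= normt
        r /= normt
        p_a = X0.T @ t
        q_a = Y0.T @ t
        v = p_a.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_a)
        v /= np.linalg.norm(v)
        S = S - np.outer(v, v @ S)
        R[:, a], T[:, a], P[:, a], Q[:, a], V[:, a] = r, t, p_a, q_a, v

    B = R @ Q.T                                  # (p, q), for mean-centered x
    intercept = y_mean - x_mean @ B
    model = PhasePLSModel(
        phase=phase,
        x0_ref=np.zeros(p) if x0_ref is None else np.asarray(x0_ref, dtype=float),
        x_mean=x_mean, y_mean=y_mean, weights=R, x_loadings=P, y_loadings=Q,
        coefficients=B, intercept=intercept, n_lv=n_lv,
    )
    resid = Y - predict(model, Xc)
    model.rmse_train = np.sqrt(np.mean(resid**2, axis=0))
    return model


def predict(model: PhasePLSModel, Xnew: np.ndarray) -> np.ndarray:
    """Apply the fitted affine map to offset-centered input rows.

    ``Xnew`` must already be centered with the phase-start convention
    (for a new process phase, subtract that phase's own first row).
    Negative predicted concentrations are returned as-is; clipping, if
    any, is the caller's responsibility (the state constraint in the
    filter acts on states, not measurements).
    """
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != model.coefficients.shape[0]:
        raise ValueError(
            f"expected {model.coefficients.shape[0]} input columns, got {Xnew.shape[1]}")
    return Xnew @ model.coefficients + model.intercept


def rmse(yhat: np.ndarray, y_ref: np.ndarray) -> np.ndarray:
    """Per-output root-mean-square error [g/L]."""
    yhat = np.atleast_2d(np.asarray(yhat, dtype=float))
    y_ref = np.atleast_2d(np.asarray(y_ref, dtype=float))
    if yhat.shape != y_ref.shape:
        raise ValueError(f"shape mismatch: {yhat.shape} vs {y_ref.shape}")
    if yhat.shape[0] == 0:
        raise ValueError("empty alignment: no rows to compare")
    return np.sqrt(np.mean((yhat - y_ref) ** 2, axis=0))


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVReport:
    """RMSECV table and the chosen latent-variable count for one phase.

    ``rmsecv`` holds the per-output RMSECV in g/L (rows: 1..max_lv
    components); ``aggregate`` is the selection criterion — the root of
    the mean per-output MSE computed on standardized outputs, so that
    large-scale outputs (biomass, tens of g/L) do not drown small ones
    (L-tyr, tenths).  Ties break toward fewer components.
    """

    rmsecv: np.ndarray            # (max_lv, 5)
    aggregate: np.ndarray         # (max_lv,)
    fold_mse: np.ndarray          # (k, max_lv) standardized per-fold MSE
    chosen_lv: int
    folds: list[np.ndarray]
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rmsecv, columns=list(MEASURED_NAMES))
        df.insert(0, "n_lv", np.arange(1, self.rmsecv.shape[0] + 1))
        df["aggregate_std"] = self.aggregate
        return df


def _make_folds(n: int, k: int, *, contiguous: bool, seed: int | None) -> list[np.ndarray]:
    idx = np.arange(n)
    if not contiguous:
        idx = np.random.default_rng(seed).permutation(n)
    return [np.sort(f) for f in np.array_split(idx, k)]


def crossvalidate(Xc: np.ndarray, Y: np.ndarray, max_lv: int = 8, k: int = 5,
                  seed: int | None = 0, *, contiguous: bool = True,
                  rule: str = "1se") -> CVReport:
    """Select the latent-variable count by k-fold RMSECV.

    Default folds are contiguous time blocks, limiting leakage between
    neighbouring (highly autocorrelated) samples; random-row folds are
    available via ``contiguous=False``.  Fold sizes differ by at most
    one.

    Selection uses the one-standard-error rule by default: the smallest
    component count whose mean cross-validated error lies within one
    standard error (over folds) of the global minimum.  Past the true
    latent dimension the RMSECV curve is typically flat to within noise,
    where a strict argmin would pick an arbitrary over-parameterized
    model; the 1-SE rule treats such near-ties as ties and breaks them
    toward parsimony, and coincides with the argmin whenever the
    differences are real.  ``rule="min"`` gives the strict argmin
    (first minimum on exact ties).
    """
    Xc = np.asarray(Xc, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = Xc.shape[0]
    if k > n:
        raise ValueError(f"k={k} folds require at least {k} rows, got {n}")
    folds = _make_folds(n, k, contiguous=contiguous, seed=seed)

    # attainable components are limited by the worst training-fold rank
    attainable = max_lv
    for f in folds:
        train = np.setdiff1d(np.arange(n), f)
        Xt = Xc[train] - Xc[train].mean(axis=0)
        attainable = min(attainable, int(np.linalg.matrix_rank(Xt)))
    if attainable < 1:
        raise ValueError("training folds are rank deficient; cannot fit any component")

    y_sd = Y.std(axis=0, ddof=0)
    y_sd = np.where(y_sd < 1e-12, 1.0, y_sd)

    sq = np.zeros((attainable, Y.shape[1]))       # summed squared errors
    fold_mse = np.zeros((k, attainable))          # standardized MSE per fold
    for fi, f in enumerate(folds):
        train = np.setdiff1d(np.arange(n), f)
        for a in range(1, attainable + 1):
            m = simpls_fit(Xc[train], Y[train], a)
            e = Y[f] - predict(m, Xc[f])
            sq[a - 1] += np.sum(e**2, axis=0)
            fold_mse[fi, a - 1] = np.mean((e / y_sd) ** 2)
    rmsecv = np.sqrt(sq / n)
    mean_mse = fold_mse.mean(axis=0)
    aggregate = np.sqrt(mean_mse)
    best = int(np.argmin(mean_mse))               # first index on exact ties
    if rule == "min":
        chosen = best + 1
    elif rule == "1se":
        se = fold_mse[:, best].std(ddof=1) / np.sqrt(k)
        chosen = int(np.argmax(mean_mse <= mean_mse[best] + se)) + 1
    else:
        raise ValueError(f"unknown selection rule {rule!r}; use '1se' or 'min'")
    return CVReport(rmsecv=rmsecv, aggregate=aggregate, fold_mse=fold_mse,
                    chosen_lv=chosen, folds=folds, seed=seed)
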