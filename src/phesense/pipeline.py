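"""Workflow orchestration for the three-process soft-sensor study.

The study design uses three fed-batch runs with explicit roles: a
reference process trains the phase-wise PLSR models, a calibration
process fixes the noise covariances (R from the PLSR prediction error,
Q by pattern search against its offline samples), and a test process —
never touched during training or calibration — receives the full hybrid
filter and is scored per state against its offline measurements,
side by side with the open-loop process model.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import build_R, estimate_Q
from .cgm import (
    MEASURED_INDICES,
    MEASURED_NAMES,
    CGMParameters,
    CGMState,
    Trajectory,
    simulate,
)
from .plsr import (
    CVReport,
    PhasePLSModel,
    build_training_outputs,
    crossvalidate,
    phase_offset_center,
    rmse,
    simpls_fit,
)
from .synthetic import ProcessDataset, make_scenario
from .ukf import FilterResult, UKFConfig, plsr_measurements, run_filter

__all__ = ["RunConfig", "cmd_train", "cmd_evaluate", "default_P0", "run_demo"]

log = logging.getLogger("phesense")

STATE_LABELS = dict(zip(MEASURED_NAMES,
                        ("biomass", "glycerol", "l_phe", "acetate", "l_tyr")))


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    # plsr
    max_lv: int = 8
    cv_folds: int = 5
    n_ref: int = 1
    contiguous_folds: bool = True
    # ukf
    alpha: float = 0.5
    beta: float = 2.0
    kappa: float = 0.0
    p0_rel: float = 0.1
    p0_floor: float = 1e-6
    p0_glycerol_inflation: float = 10.0
    ode_substep_s: float = 15.0
    # calibration
    q_bounds: tuple[float, float] = (1e-8, 1e2)
    calib_max_evals: int = 40
    calib_mesh0: float = 1.0
    calib_mesh_tol: float = 1e-3
    calib_free_states: tuple[int, ...] = tuple(MEASURED_INDICES)
    # scenario sizes
    phase2_hours: float = 30.0
    phase3_hours: float = 25.0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 1 <= self.max_lv <= 8:
            raise ValueError("max_lv must be in [1, 8]")
        if self.calib_max_evals < 1:
            raise ValueError("calib_max_evals must be >= 1")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["q_bounds"] = list(self.q_bounds)
        d["calib_free_states"] = list(self.calib_free_states)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "q_bounds" in d:
            d["q_bounds"] = tuple(d["q_bounds"])
        if "calib_free_states" in d:
            d["calib_free_states"] = tuple(d["calib_free_states"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def default_P0(x0: np.ndarray, *, rel: float = 0.1, floor: float = 1e-6,
               glycerol_inflation: float = 10.0) -> np.ndarray:
    """Initial covariance: (rel * x0)^2 per state with a floor.

    The glycerol entry is inflated because starting substrate levels
    vary between runs more than the other initial conditions, so the
    filter should lean on the measurements for that state early on.
    """
    d = np.maximum((rel * np.asarray(x0, dtype=float)) ** 2, floor)
    d[1] *= glycerol_inflation
    return np.diag(d)


# ---------------------------------------------------------------------------
# Stages


def cmd_train(dataset: ProcessDataset, config: RunConfig | None = None,
              truth: Trajectory | None = None
              ) -> tuple[dict[int, PhasePLSModel], dict[int, CVReport], pd.DataFrame]:
    """Train one PLS model per phase on a reference dataset.

    Inputs are offset-centered per phase; outputs are the process-model
    concentrations interpolated onto the online timestamps (the sparse
    offline samples alone cannot support per-row training).  The
    latent-variable count per phase comes from k-fold RMSECV.
    """
    config = config or RunConfig()
    truth = truth if truth is not None else dataset.truth
    if truth is None:
        raise ValueError("training requires the simulated trajectory (dataset.truth)")
    online = dataset.online
    present = set(np.unique(online.phase_index).tolist())
    missing = {1, 2, 3} - present
    if missing:
        raise ValueError(f"dataset lacks rows for phase(s) {sorted(missing)}")

    models: dict[int, PhasePLSModel] = {}
    reports: dict[int, CVReport] = {}
    rows_rmse = []
    for phase in (1, 2, 3):
        idx = online.phase_rows(phase)
        if idx.size <= config.cv_folds:
            raise ValueError(f"phase {phase} too short for {config.cv_folds}-fold CV")
        Xc, x0_ref = phase_offset_center(online.values[idx], n_ref=config.n_ref)
        Y = build_training_outputs(truth, online.times[idx])
        rep = crossvalidate(Xc, Y, max_lv=config.max_lv, k=config.cv_folds,
                            seed=config.seed, contiguous=config.contiguous_folds)
        model = simpls_fit(Xc, Y, rep.chosen_lv, phase=phase, x0_ref=x0_ref)
        models[phase], reports[phase] = model, rep
        rows_rmse.append([phase, rep.chosen_lv, *model.rmse_train])
        log.info("phase %d: %d rows, %d LVs, train RMSE %s",
                 phase, idx.size, rep.chosen_lv, np.round(model.rmse_train, 3))
    train_rmse = pd.DataFrame(rows_rmse, columns=["phase", "n_lv", *MEASURED_NAMES])
    return models, reports, train_rmse


def _interp_to_offline(times: np.ndarray, values: np.ndarray,
                       offline: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    t = offline["time_h"].to_numpy(float)
    mask = (t >= times[0]) & (t <= times[-1])
    if not mask.any():
        raise ValueError("no overlap between predictions and offline samples")
    t = t[mask]
    pred = np.column_stack([np.interp(t, times, values[:, j])
                            for j in range(values.shape[1])])
    obs = offline.loc[mask, list(MEASURED_NAMES)].to_numpy(float)
    return pred, obs


def plsr_offline_rmse(dataset: ProcessDataset, models: dict[int, PhasePLSModel],
                      *, n_ref: int = 1) -> np.ndarray:
    """Per-output RMSE of the PLSR predictions against offline samples."""
    Y = plsr_measurements(dataset.online, models, n_ref=n_ref)
    pred, obs = _interp_to_offline(dataset.online.times, Y, dataset.offline)
    return rmse(pred, obs)


def cmd_evaluate(ukf_result: FilterResult, openloop: Trajectory,
                 offline: pd.DataFrame) -> pd.DataFrame:
    """Per-state RMSE of the open-loop process model and of the filter.

    Both prediction tracks are linearly interpolated onto the offline
    sampling times.  Returns a 5-state x 2-method table.
    """
    if offline.empty:
        raise ValueError("offline table is empty")
    from .cgm import measure

    pred_cgm, obs = _interp_to_offline(openloop.times, measure(openloop.states), offline)
    pred_ukf, _ = _interp_to_offline(ukf_result.times,
                                     ukf_result.x_post[:, list(MEASURED_INDICES)], offline)
    table = pd.DataFrame(
        {"CGM": rmse(pred_cgm, obs), "UKF": rmse(pred_ukf, obs)},
        index=[STATE_LABELS[n] for n in MEASURED_NAMES])
    table.index.name = "state"
    return table


def open_loop(dataset: ProcessDataset, params: CGMParameters,
              x0: np.ndarray | CGMState | None = None) -> Trajectory:
    """Open-loop process-model run over the dataset's schedule and span."""
    x0 = x0 if x0 is not None else CGMState()
    return simulate(x0, params, dataset.schedule, dataset.online.times,
                    rtol=1e-7, atol=1e-9)


# ---------------------------------------------------------------------------
# Full study


def run_demo(outdir, seed: int = 0, config: RunConfig | None = None,
             *, params: CGMParameters | None = None) -> dict:
    """Run the full three-process study on synthetic data.

    Simulates the reference, calibration and test processes; trains the
    phase-wise PLSR on the reference; builds R from the PLSR prediction
    error and tunes Q on the calibration process; filters the test
    process; and writes models, noise spec, filter log, evaluation table
    and a manifest to ``outdir``.  Fully deterministic for a fixed seed
    and configuration.
    """
    config = config or RunConfig(seed=seed)
    params = params or CGMParameters()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("simulating scenarios (seed=%d)", seed)
    ref = make_scenario("reference_high_iptg", seed=seed, params=params,
                        phase2_hours=config.phase2_hours, phase3_hours=config.phase3_hours)
    cal = make_scenario("low_iptg_A", seed=seed, params=params,
                        phase2_hours=config.phase2_hours, phase3_hours=config.phase3_hours)
    test = make_scenario("low_iptg_B", seed=seed, params=params,
                         phase2_hours=config.phase2_hours, phase3_hours=config.phase3_hours)
    for name, ds in (("process1_reference", ref), ("process2_calibration", cal),
                     ("process3_test", test)):
        ds.save(out / name)

    models, reports, train_rmse = cmd_train(ref, config)
    for phase, m in models.items():
        m.to_json(out / f"pls_phase{phase}.json")
        reports[phase].to_frame().to_csv(out / f"cv_phase{phase}.csv", index=False)
    train_rmse.to_csv(out / "train_rmse.csv", index=False)

    log.info("building R from PLSR error on the calibration process")
    r_cal = plsr_offline_rmse(cal, models, n_ref=config.n_ref)
    R = build_R(r_cal)

    x0 = CGMState().to_array()
    P0 = default_P0(x0, rel=config.p0_rel, floor=config.p0_floor,
                    glycerol_inflation=config.p0_glycerol_inflation)
    cfg = UKFConfig(alpha=config.alpha, beta=config.beta, kappa=config.kappa,
                    R=R, P0=P0, ode_substep_s=config.ode_substep_s)

    log.info("calibrating Q (budget %d evaluations)", config.calib_max_evals)
    q_best, trace = estimate_Q(
        cal, models, cfg, cal.schedule, x0, params=params,
        bounds=config.q_bounds, free_indices=list(config.calib_free_states),
        mesh0=config.calib_mesh0, mesh_tol=config.calib_mesh_tol,
        max_evals=config.calib_max_evals, seed=seed)
    trace.to_frame().to_csv(out / "calibration_trace.csv", index=False)
    from .calibration import NoiseSpec

    NoiseSpec(r_diag=np.diag(R), q_diag=q_best,
              provenance={"R": "PLSR offline RMSE on process2",
                          "Q": f"pattern search, {trace.n_eval} evaluations"}
              ).to_json(out / "noise.json")

    log.info("filtering the test process")
    cfg_t = UKFConfig(alpha=config.alpha, beta=config.beta, kappa=config.kappa,
                      Q=np.diag(q_best), R=R, P0=P0,
                      ode_substep_s=config.ode_substep_s)
    result = run_filter(test, models, cfg_t, test.schedule, x0, params=params,
                        n_ref=config.n_ref)
    result.to_frame().to_csv(out / "filter_result.csv", index=False)

    ol = open_loop(test, params)
    table = cmd_evaluate(result, ol, test.offline)
    table.to_csv(out / "evaluation.csv")
    log.info("evaluation (test process):\n%s", table.round(3))

    manifest = {
        "seed": seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "scenarios": {"train": ref.scenario, "calibrate": cal.scenario,
                      "test": test.scenario},
        "chosen_lv": {p: int(m.n_lv) for p, m in models.items()},
        "r_diag": np.diag(R).tolist(),
        "q_diag": q_best.tolist(),
        "calibration_evals": trace.n_eval,
        "evaluation": {s: {"CGM": float(table.loc[s, "CGM"]),
                           "UKF": float(table.loc[s, "UKF"])}
                       for s in table.index},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
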