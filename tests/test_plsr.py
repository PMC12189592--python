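"""Tests of offset-centering, SIMPLS, cross-validation and RMSE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phesense.cgm import Trajectory
from phesense.plsr import (
    CHANNELS,
    OnlineMatrix,
    PhasePLSModel,
    build_training_outputs,
    crossvalidate,
    phase_offset_center,
    predict,
    rmse,
    simpls_fit,
)


class TestOffsetCentering:
    def test_direct_subtraction_example(self):
        Xc, x0 = phase_offset_center(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert np.array_equal(Xc, [[0, 0], [2, 2]])
        assert np.array_equal(x0, [1, 2])

    def test_first_row_maps_to_zero(self):
        X = np.random.default_rng(0).normal(size=(20, 8))
        Xc, _ = phase_offset_center(X)
        assert np.array_equal(Xc[0], np.zeros(8))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(2, 30), st.integers(1, 8), st.integers(0, 10_000))
    def test_adding_reference_back_reconstructs(self, rows, cols, seed):
        X = np.random.default_rng(seed).normal(size=(rows, cols))
        Xc, x0 = phase_offset_center(X)
        assert np.allclose(Xc + x0, X)
        assert np.array_equal(Xc[0], np.zeros(cols))

    def test_reference_averaging(self):
        X = np.array([[0.0], [2.0], [4.0], [6.0]])
        Xc, x0 = phase_offset_center(X, n_ref=3)
        assert x0 == pytest.approx(2.0)

    def test_single_row_phase_rejected(self):
        with pytest.raises(ValueError):
            phase_offset_center(np.ones((1, 8)))


def _toy_trajectory():
    times = np.array([0.0, 1.0, 2.0, 3.0])
    states = np.zeros((4, 10))
    states[:, 0] = 1.0
    states[:, 2] = [0.0, 2.0, 4.0, 4.0]       # biomass
    states[:, 1] = [4.0, 2.0, 0.0, 0.0]       # glycerol
    return Trajectory(times=times, states=states, rates=np.zeros((4, 6)),
                      feed=np.zeros(4), phase_index=np.ones(4, dtype=int),
                      cum_S_in=np.zeros(4), cum_S_up=np.zeros(4))


class TestTrainingOutputs:
    def test_exact_at_knots(self):
        traj = _toy_trajectory()
        Y = build_training_outputs(traj, traj.times)
        assert np.array_equal(Y[:, 0], [0, 2, 4, 4])

    def test_linear_midpoint(self):
        Y = build_training_outputs(_toy_trajectory(), np.array([0.5]))
        assert Y[0, 0] == pytest.approx(1.0)
        assert Y[0, 1] == pytest.approx(3.0)

    def test_bracketing_bound_property(self):
        traj = _toy_trajectory()
        rng = np.random.default_rng(2)
        t = rng.uniform(0, 3, 100)
        Y = build_training_outputs(traj, t)
        for j in range(5):
            lo = traj.states[:, [2, 1, 3, 4, 5][j]].min()
            hi = traj.states[:, [2, 1, 3, 4, 5][j]].max()
            assert np.all(Y[:, j] >= lo - 1e-12) and np.all(Y[:, j] <= hi + 1e-12)

    def test_no_extrapolation(self):
        with pytest.raises(ValueError):
            build_training_outputs(_toy_trajectory(), np.array([3.5]))


class TestSimpls:
    def test_exact_linear_relation_single_input(self):
        x = np.linspace(-3, 3, 20)[:, None]
        m = simpls_fit(x, 2.0 * x, 1)
        assert m.coefficients[0, 0] == pytest.approx(2.0, abs=1e-12)
        assert m.rmse_train[0] == pytest.approx(0.0, abs=1e-10)
        assert predict(m, [[5.0]])[0, 0] == pytest.approx(10.0)

    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 8))
        Y = rng.normal(size=(30, 5))
        m = simpls_fit(X, Y, 8)
        B = np.linalg.lstsq(X - X.mean(0), Y - Y.mean(0), rcond=None)[0]
        assert np.max(np.abs(m.coefficients - B)) < 1e-8

    def test_training_error_nonincreasing_in_components(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 8))
        Y = rng.normal(size=(30, 5))
        norms = [np.linalg.norm(Y - predict(simpls_fit(X, Y, a), X))
                 for a in range(1, 9)]
        assert np.all(np.diff(norms) <= 1e-9)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 8))
        Y = rng.normal(size=(40, 5))
        m = simpls_fit(X, Y, 5)
        T = (X - m.x_mean) @ m.weights
        G = T.T @ T
        assert np.max(np.abs(G - np.diag(np.diag(G)))) < 1e-8

    def test_rank_limit_reported(self):
        rng = np.random.default_rng(6)
        T = rng.normal(size=(30, 2))
        X = T @ rng.normal(size=(8, 2)).T           # rank 2
        with pytest.raises(ValueError, match="rank.*2"):
            simpls_fit(X, rng.normal(size=(30, 5)), 5)

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        m = simpls_fit(rng.normal(size=(20, 8)), rng.normal(size=(20, 5)), 2)
        with pytest.raises(ValueError, match="columns"):
            predict(m, np.ones((3, 6)))

    def test_shift_absorbed_by_phase_centering(self):
        # a constant offset present at the phase start vanishes after Eq.-1
        # centering, so predictions are invariant to it
        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 8))
        Y = rng.normal(size=(25, 5))
        Xc, _ = phase_offset_center(X)
        m = simpls_fit(Xc, Y, 3)
        X_shift = X + np.full(8, 7.5)
        Xc2, _ = phase_offset_center(X_shift)
        assert np.allclose(predict(m, Xc), predict(m, Xc2))

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 8))
        m = simpls_fit(X, rng.normal(size=(20, 5)), 3, phase=2, x0_ref=X[0])
        f = tmp_path / "model.json"
        m.to_json(f)
        back = PhasePLSModel.from_json(f)
        assert back.phase == 2 and back.n_lv == 3
        assert np.allclose(back.coefficients, m.coefficients)
        assert np.allclose(predict(back, X), predict(m, X))


class TestCrossValidation:
    def test_recovers_latent_rank_noiseless(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            T = rng.standard_normal((60, 2))
            X = T @ rng.standard_normal((8, 2)).T
            Y = T @ rng.standard_normal((5, 2)).T
            hits += crossvalidate(X, Y, max_lv=6, k=5, seed=seed).chosen_lv == 2
        assert hits >= 9

    def test_argmin_rule_minimizes_aggregate(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(50, 8))
        Y = rng.normal(size=(50, 5))
        rep = crossvalidate(X, Y, max_lv=6, k=5, rule="min")
        assert np.all(rep.aggregate[rep.chosen_lv - 1] <= rep.aggregate + 1e-15)

    def test_one_se_rule_never_exceeds_argmin(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(50, 8))
        Y = rng.normal(size=(50, 5))
        a = crossvalidate(X, Y, max_lv=6, k=5, rule="1se").chosen_lv
        b = crossvalidate(X, Y, max_lv=6, k=5, rule="min").chosen_lv
        assert a <= b

    def test_fold_sizes_differ_by_at_most_one(self):
        rep = crossvalidate(np.random.default_rng(12).normal(size=(23, 8)),
                            np.random.default_rng(13).normal(size=(23, 5)),
                            max_lv=3, k=5)
        sizes = [len(f) for f in rep.folds]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 23

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            crossvalidate(np.ones((3, 8)), np.ones((3, 5)), k=5)

    def test_unknown_rule_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError, match="rule"):
            crossvalidate(rng.normal(size=(20, 8)), rng.normal(size=(20, 5)),
                          max_lv=2, rule="best")


class TestRmse:
    def test_identical_vectors_zero(self):
        assert np.array_equal(rmse(np.ones((5, 2)), np.ones((5, 2))), [0, 0])

    def test_arithmetic_example(self):
        out = rmse(np.array([[0.0], [0.0]]), np.array([[3.0], [4.0]]))
        assert out[0] == pytest.approx(np.sqrt(12.5))

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(15)
        yhat = rng.normal(size=(40, 5))
        y = rng.normal(size=(40, 5))
        expected = [np.sqrt(sum((yhat[i, j] - y[i, j]) ** 2 for i in range(40)) / 40)
                    for j in range(5)]
        assert np.allclose(rmse(yhat, y), expected)

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            rmse(np.empty((0, 5)), np.empty((0, 5)))


class TestOnlineMatrix:
    def _frame(self, values):
        df = pd.DataFrame(values, columns=list(CHANNELS))
        df.insert(0, "time_h", np.arange(len(df)) / 30.0)
        df["phase"] = 1
        return df

    def test_short_gap_forward_filled(self):
        vals = np.ones((10, 8))
        df = self._frame(vals)
        df.loc[3:5, "pH"] = np.nan                # 3-row gap: allowed
        om = OnlineMatrix.from_frame(df)
        assert np.all(np.isfinite(om.values))

    def test_long_gap_rejected(self):
        df = self._frame(np.ones((10, 8)))
        df.loc[3:7, "pH"] = np.nan                # 5-row gap
        with pytest.raises(ValueError, match="gap"):
            OnlineMatrix.from_frame(df)

    def test_frame_round_trip(self):
        rng = np.random.default_rng(16)
        om = OnlineMatrix(times=np.arange(5) / 30.0, values=rng.normal(size=(5, 8)),
                          phase_index=np.array([1, 1, 2, 2, 3]))
        back = OnlineMatrix.from_frame(om.to_frame())
        assert np.allclose(back.values, om.values)
        assert np.array_equal(back.phase_index, om.phase_index)

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError):
            OnlineMatrix(times=np.array([0.0, 0.0]), values=np.ones((2, 8)),
                         phase_index=np.array([1, 1]))
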