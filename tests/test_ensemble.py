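"""Combiner, metrics, linked-list weight history, count curve, loss tracking."""

import numpy as np
import pytest

from dynawa.ensemble import (
    EvalMetrics,
    WeightHistory,
    combine,
    count_curve,
    evaluate,
    track_loss,
    update_weights,
)
from dynawa.learners import PredictionMatrix
from dynawa.weights import WeightVector

from .conftest import oracle_matrix, trace_from_matrix


def pmat(values, names=None):
    values = np.atleast_2d(np.asarray(values, float))
    names = names or [f"L{i}" for i in range(values.shape[1])]
    return PredictionMatrix(values, names, np.arange(values.shape[0]))


def wvec(w, names=None, strategy="test"):
    w = np.asarray(w, float)
    return WeightVector(w, names or [f"L{i}" for i in range(len(w))], strategy)


class TestCombine:
    def test_one_hot_selects_a_column(self):
        P = pmat(np.random.default_rng(0).random((6, 3)))
        out = combine(P, wvec([0.0, 1.0, 0.0]))
        assert np.array_equal(out, P.values[:, 1])

    def test_equal_weights_are_row_means(self):
        P = pmat(np.random.default_rng(1).random((5, 4)))
        assert np.allclose(combine(P, wvec(np.full(4, 0.25))),
                           P.values.mean(axis=1))

    def test_hand_dot_product(self):
        P = pmat([[1.0, 3.0], [2.0, 4.0]])
        assert np.allclose(combine(P, wvec([0.25, 0.75])), [2.5, 3.5])

    def test_misaligned_names_error(self):
        P = pmat(np.random.default_rng(2).random((4, 2)), ["A", "B"])
        with pytest.raises(ValueError, match="learner names"):
            combine(P, wvec([0.5, 0.5], ["B", "A"]))


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        m = evaluate(y, y)
        assert m.r2 == pytest.approx(1.0) and m.rmse == pytest.approx(0.0)

    def test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = evaluate(np.full(4, y.mean()), y)
        assert m.r2 == pytest.approx(0.0)

    def test_hand_computation(self):
        m = evaluate(np.array([1.0, 2.0, 4.0]), np.array([1.0, 2.0, 3.0]))
        assert m.rmse == pytest.approx(np.sqrt(1 / 3))
        assert m.r2 == pytest.approx(0.5)

    def test_constant_target_errors(self):
        with pytest.raises(ValueError, match="constant"):
            evaluate(np.array([1.0, 2.0]), np.array([3.0, 3.0]))

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        y = rng.random(20)
        pred = y + rng.normal(0, 0.1, 20)
        perm = rng.permutation(20)
        a, b = evaluate(pred, y), evaluate(pred[perm], y[perm])
        assert a.r2 == pytest.approx(b.r2) and a.rmse == pytest.approx(b.rmse)

    def test_invalid_metrics_rejected(self):
        with pytest.raises(ValueError):
            EvalMetrics(r2=0.5, rmse=-1.0, n=10)


class TestWeightHistory:
    def test_init_then_update_current(self):
        h = WeightHistory.init(wvec([1.0], ["A"]))
        update_weights(h, wvec([1.0], ["A"], "u1"))
        assert h.current_weights().strategy == "u1"
        assert len(h) == 2

    def test_rollback_best_picks_min_rmse(self):
        h = WeightHistory.init(wvec([1.0], ["A"]), EvalMetrics(0.5, 3.0, 10))
        update_weights(h, wvec([1.0], ["A"]), EvalMetrics(0.9, 1.0, 10))
        update_weights(h, wvec([1.0], ["A"]), EvalMetrics(0.7, 2.0, 10))
        assert h.rollback_best().step_id == 1

    def test_round_trip_serialisation(self, tmp_path):
        h = WeightHistory.init(wvec([0.6, 0.4], ["A", "B"], "sam"),
                               EvalMetrics(0.8, 2.0, 5))
        update_weights(h, wvec([0.3, 0.7], ["A", "B"], "sam"),
                       EvalMetrics(0.85, 1.8, 5))
        path = tmp_path / "hist.json"
        h.to_json(path)
        back = WeightHistory.from_json(path)
        assert len(back) == len(h)
        for a, b in zip(back, h):
            assert a.step_id == b.step_id
            assert np.allclose(a.weights.w, b.weights.w)
            assert a.timestamp == b.timestamp

    def test_append_to_uninitialized_errors(self):
        with pytest.raises(ValueError, match="uninitialized"):
            WeightHistory().append(wvec([1.0], ["A"]))

    def test_step_ids_strictly_increasing(self):
        h = WeightHistory.init(wvec([1.0], ["A"]))
        for _ in range(4):
            update_weights(h, wvec([1.0], ["A"]))
        ids = [n.step_id for n in h]
        assert ids == sorted(set(ids))


class TestCountCurve:
    def test_three_learners_give_two_points(self):
        rng = np.random.default_rng(4)
        y = rng.normal(15, 6, 40)
        P = pmat(np.column_stack([y + rng.normal(0, s, 40) for s in (0.5, 1, 2)]))
        cc = count_curve(P, y, P, y, strategy="r2")
        assert [k for k, _ in cc.points] == [2, 3]

    def test_ranking_is_identity_when_already_sorted(self):
        rng = np.random.default_rng(5)
        y = rng.normal(15, 6, 60)
        cols = [y + rng.normal(0, s, 60) for s in (0.2, 1.0, 3.0, 6.0)]
        P = pmat(np.column_stack(cols))
        cc = count_curve(P, y, P, y, strategy="r2")
        assert cc.ranking == P.learner_names

    def test_informative_learners_plateau_early(self):
        """4 informative + 4 noise learners: attention curve rises then flattens."""
        rng = np.random.default_rng(6)
        n = 150
        y_cal = rng.normal(15, 6, n)
        y_val = rng.normal(15, 6, n)
        cal_cols, val_cols = [], []
        for k in range(8):
            if k < 4:
                cal_cols.append(y_cal + rng.normal(0, 1.0, n))
                val_cols.append(y_val + rng.normal(0, 1.0, n))
            else:
                cal_cols.append(rng.normal(15, 6, n))
                val_cols.append(rng.normal(15, 6, n))
        P_cal = pmat(np.column_stack(cal_cols))
        P_val = pmat(np.column_stack(val_cols))
        cc = count_curve(P_cal, y_cal, P_val, y_val, strategy="sam", seed=0)
        r2_by_k = dict(cc.points)
        assert cc.plateau_k <= 6
        assert r2_by_k[4] > r2_by_k[2]

    def test_single_learner_errors(self):
        P = pmat(np.random.default_rng(7).random((10, 1)))
        with pytest.raises(ValueError, match="at least 2"):
            count_curve(P, P.values[:, 0], P, P.values[:, 0])


class TestTrackLoss:
    def test_patience_equal_to_max_iter_runs_everything(self):
        P, y = oracle_matrix(K=3, n=60, seed=8, uninformative="shuffled")
        out = track_loss("af", P, y, P, y, max_iter=40, patience=41)
        assert out["stop_iteration"] == 40
        assert len(out["calibration_mae"]) == 41

    def test_constant_loss_stops_after_patience(self):
        col = np.random.default_rng(9).random(20)
        P = pmat(np.column_stack([col] * 3))
        y = col + 0.05
        out = track_loss("af", P, y, P, y, max_iter=60, patience=10)
        assert out["stop_iteration"] == 10

    def test_best_seen_envelope_non_increasing(self):
        P, y = oracle_matrix(K=3, n=80, seed=10, uninformative="shuffled")
        out = track_loss("af", P, y, P, y, max_iter=80, patience=80)
        env = np.minimum.accumulate(out["calibration_mae"])
        assert (np.diff(env) <= 1e-12).all()
        assert env[-1] < out["calibration_mae"][0]

    def test_fold_averaged_calibration_mae(self):
        P, y = oracle_matrix(K=2, n=30, seed=11, uninformative="shuffled")
        trace = trace_from_matrix(P, y)
        out = track_loss("adam", P, y, P, y, trace=trace, max_iter=10, patience=10)
        assert len(out["calibration_mae"]) == len(out["validation_mae"])

    def test_non_iterative_strategy_rejected(self):
        P, y = oracle_matrix(K=2, n=20, seed=12)
        with pytest.raises(ValueError, match="not iterative"):
            track_loss("r2", P, y, P, y)
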