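"""Weighted-averaging combiner, dynamic weight history, metrics and curves.

The ensemble prediction is the convex combination ``y_hat = P @ w`` of
base-learner predictions.  A singly linked :class:`WeightHistory` stores the
initial and every updated weight vector together with metric snapshots, so
weights can be adjusted on the fly and rolled back to the best-performing
node.  :func:`count_curve` reproduces the learner-count analysis (ensemble
R^2 as the top-k ranked learners are added, k = 2..K, with plateau
detection) and :func:`track_loss` records calibration/validation MAE per
iteration of an iterative strategy with early stopping.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .learners import PredictionMatrix, TrainingTrace
from .weights import WeightVector, compute_weights

__all__ = [
    "EvalMetrics", "WeightHistory", "CountCurve", "combine", "evaluate",
    "update_weights", "count_curve", "track_loss", "ITERATIVE_STRATEGIES",
]

ITERATIVE_STRATEGIES = ("af", "adam", "ql", "ga")


@dataclass(frozen=True)
class EvalMetrics:
    """R^2 (unitless) and RMSE (g kg^-1) over n samples."""

    r2: float
    rmse: float
    n: int

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.n < 1 or self.r2 > 1 + 1e-12:
            raise ValueError("invalid metrics")


def combine(P: PredictionMatrix, w: WeightVector) -> np.ndarray:
    """Weighted-average prediction ``P @ w`` with learner-name alignment checks."""
    if P.learner_names != w.learner_names:
        raise ValueError(
            "learner names of the prediction matrix and weight vector differ; "
            "positional matching is never silent"
        )
    return P.values @ w.w


def evaluate(pred: np.ndarray, y: np.ndarray) -> EvalMetrics:
    """R^2 = 1 - SSres/SStot and RMSE; errors on a constant target."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if pred.shape != y.shape or len(y) < 2:
        raise ValueError("pred and y must share length >= 2")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("target is constant (SStot = 0): R^2 undefined")
    ss_res = np.sum((pred - y) ** 2)
    return EvalMetrics(
        r2=float(1.0 - ss_res / ss_tot),
        rmse=float(np.sqrt(np.mean((pred - y) ** 2))),
        n=len(y),
    )


# ---------------------------------------------------------------------------
# dynamic linked-list weight store


@dataclass
class _Node:
    step_id: int
    weights: WeightVector
    metrics: EvalMetrics | None
    timestamp: float
    next: "_Node | None" = None


@dataclass
class WeightHistory:
    """Singly linked list of timestamped weight vectors with metric snapshots.

    ``head`` holds the initial weights; updates append at the tail, keeping
    step ids strictly increasing.  ``rollback_best`` returns the node with
    the lowest snapshot RMSE.
    """

    head: _Node | None = None
    tail: _Node | None = field(default=None, repr=False)

    @classmethod
    def init(cls, weights: WeightVector, metrics: EvalMetrics | None = None
             ) -> "WeightHistory":
        node = _Node(step_id=0, weights=weights, metrics=metrics, timestamp=time.time())
        return cls(head=node, tail=node)

    def __iter__(self):
        node = self.head
        while node is not None:
            yield node
            node = node.next

    def __len__(self) -> int:
        return sum(1 for _ in self)

    def append(self, weights: WeightVector, metrics: EvalMetrics | None = None) -> None:
        if self.head is None or self.tail is None:
            raise ValueError("cannot append to an uninitialized history; call init()")
        node = _Node(step_id=self.tail.step_id + 1, weights=weights,
                     metrics=metrics, timestamp=time.time())
        self.tail.next = node
        self.tail = node

    def current_weights(self) -> WeightVector:
        if self.tail is None:
            raise ValueError("empty history")
        return self.tail.weights

    def rollback_best(self) -> _Node:
        scored = [n for n in self if n.metrics is not None]
        if not scored:
            raise ValueError("no metric snapshots recorded")
        return min(scored, key=lambda n: n.metrics.rmse)

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "step_id": n.step_id,
                "strategy": n.weights.strategy,
                "learner_names": n.weights.learner_names,
                "w": n.weights.w.tolist(),
                "metrics": None if n.metrics is None else {
                    "r2": n.metrics.r2, "rmse": n.metrics.rmse, "n": n.metrics.n,
                },
                "timestamp": n.timestamp,
            }
            for n in self
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "WeightHistory":
        payload = json.loads(Path(path).read_text())
        hist: WeightHistory | None = None
        for rec in payload:
            wv = WeightVector(np.array(rec["w"]), rec["learner_names"], rec["strategy"])
            em = rec["metrics"] and EvalMetrics(**rec["metrics"])
            if hist is None:
                hist = cls.init(wv, em)
                hist.head.timestamp = rec["timestamp"]
                hist.head.step_id = rec["step_id"]
            else:
                hist.append(wv, em)
                hist.tail.timestamp = rec["timestamp"]
                hist.tail.step_id = rec["step_id"]
        if hist is None:
            raise ValueError(f"{path}: empty history file")
        return hist


def update_weights(hist: WeightHistory, new_w: WeightVector,
                   metrics: EvalMetrics | None = None) -> WeightHistory:
    """Append a weight vector (with optional metrics snapshot) at the tail."""
    hist.append(new_w, metrics)
    return hist


# ---------------------------------------------------------------------------
# learner-count curve


@dataclass
class CountCurve:
    ranking: list[str]
    points: list[tuple[int, float]]
    plateau_k: int


def count_curve(
    P_cal_oof: PredictionMatrix,
    y_cal: np.ndarray,
    P_val: PredictionMatrix,
    y_val: np.ndarray,
    strategy: str = "sam",
    trace: TrainingTrace | None = None,
    seed: int = 0,
    tol: float = 0.002,
    consecutive: int = 3,
) -> CountCurve:
    """Ensemble validation R^2 as the top-k ranked learners are added.

    Learners are ranked by individual validation R^2 (descending; ties by
    lower RMSE, then name).  For each k in 2..K the strategy's weights are
    recomputed on the top-k calibration out-of-fold columns and the ensemble
    is scored on validation.  ``plateau_k`` is the smallest k after which
    the R^2 change stays below ``tol`` for ``consecutive`` increments (K if
    that never happens).
    """
    K = P_val.n_learners
    if K < 2:
        raise ValueError("need at least 2 learners for a count curve")
    per = []
    for j, name in enumerate(P_val.learner_names):
        m = evaluate(P_val.values[:, j], y_val)
        per.append((name, m.r2, m.rmse))
    ranking = [name for name, _, _ in
               sorted(per, key=lambda t: (-t[1], t[2], t[0]))]
    points: list[tuple[int, float]] = []
    for k in range(2, K + 1):
        top = ranking[:k]
        sub_oof = P_cal_oof.select(top)
        sub_val = P_val.select(top)
        wv = compute_weights(strategy, sub_oof, y_cal, trace=trace, seed=seed)
        metrics = evaluate(combine(sub_val, wv), y_val)
        points.append((k, metrics.r2))
    plateau_k = K
    r2s = [r for _, r in points]
    for i in range(len(r2s)):
        tail = [abs(r2s[j] - r2s[j - 1]) for j in range(i + 1, min(i + 1 + consecutive, len(r2s)))]
        if len(tail) == consecutive and all(d < tol for d in tail):
            plateau_k = points[i][0]
            break
    return CountCurve(ranking=ranking, points=points, plateau_k=plateau_k)


# ---------------------------------------------------------------------------
# loss tracking with early stopping


def track_loss(
    strategy: str,
    P_oof: PredictionMatrix,
    y_cal: np.ndarray,
    P_val: PredictionMatrix,
    y_val: np.ndarray,
    trace: TrainingTrace | None = None,
    max_iter: int = 160,
    patience: int = 15,
    seed: int = 0,
) -> dict:
    """Per-iteration calibration/validation MAE for an iterative strategy.

    Calibration MAE is the mean over CV folds of the out-of-fold ensemble
    MAE (falling back to the pooled MAE when no fold assignment is known).
    Early stopping halts when validation MAE has not improved for
    ``patience`` iterations; returns both (truncated) curves and the
    stopping iteration.
    """
    if strategy not in ITERATIVE_STRATEGIES:
        raise ValueError(
            f"strategy '{strategy}' is not iterative; choose from {ITERATIVE_STRATEGIES}"
        )
    y_cal = np.asarray(y_cal, float)
    y_val = np.asarray(y_val, float)
    if strategy == "af":
        wv = compute_weights("af", P_oof, y_cal, record_path=True)
        path = wv.diagnostics["weight_path"]
    elif strategy == "adam":
        from .weights import AdamConfig, weights_adam
        wv = weights_adam(P_oof, y_cal, AdamConfig(iterations=max_iter), record_path=True)
        path = wv.diagnostics["weight_path"]
    elif strategy == "ql":
        from .weights import QLearningConfig, weights_q_learning
        wv = weights_q_learning(P_oof, y_cal, QLearningConfig(episodes=max_iter, seed=seed),
                                record_path=True)
        path = wv.diagnostics["weight_path"]
    else:  # ga
        from .weights import GAWeightConfig, weights_ga
        wv = weights_ga(P_oof, y_cal, GAWeightConfig(generations=max_iter, seed=seed),
                        record_path=True)
        path = wv.diagnostics["weight_path"]
    path = path[: max_iter + 1]

    fold_of = trace.fold_of if trace is not None else None

    def cal_mae(w: np.ndarray) -> float:
        err = np.abs(P_oof.values @ w - y_cal)
        if fold_of is None:
            return float(err.mean())
        return float(np.mean([err[fold_of == f].mean() for f in np.unique(fold_of)]))

    cal_curve, val_curve = [], []
    best_val, since_best, stop_iter = np.inf, 0, len(path) - 1
    for t, w in enumerate(path):
        cal_curve.append(cal_mae(w))
        vmae = float(np.mean(np.abs(P_val.values @ w - y_val)))
        val_curve.append(vmae)
        if vmae < best_val - 1e-12:
            best_val, since_best = vmae, 0
        else:
            since_best += 1
            if since_best >= patience:
                stop_iter = t
                break
    return {
        "strategy": strategy,
        "calibration_mae": np.array(cal_curve),
        "validation_mae": np.array(val_curve),
        "stop_iteration": stop_iter,
        "weights": wv,
    }
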