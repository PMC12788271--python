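"""Eight weight-allocation strategies for the weighted-averaging ensemble.

Every strategy maps base-learner behaviour — a prediction matrix ``P``
(n samples x K learners), per-learner training errors, and/or the true
targets ``y`` — to a :class:`WeightVector` on the probability simplex
(w >= 0, sum w = 1).  The ensemble prediction is then ``P @ w``.

Strategies
----------
``r2`` (R^2 normalisation)
    The conventional evaluation-index baseline: per-learner R^2 scores,
    floored at zero, normalised to sum one.
``al`` (adaptive learning)
    Relative performance scores ``S_i = 1 - MAE_i / mean(MAE)`` from
    training-process errors, min-max normalised then sum-normalised.
``sam`` (self-attention)
    Each learner's prediction column is a feature vector; pairwise
    dot-product similarity scores are reduced per learner (row mean) and
    softmax-normalised into weights.
``ql`` (Q-learning)
    Tabular reinforcement learning over discretised weight states; action i
    adds an increment to w_i; the reward is the drop in ensemble MSE.
``af`` (adaptive filter)
    Projected gradient descent on the ensemble MSE with non-negativity and
    sum-to-one restored after every step.
``adam``
    The same objective optimised with bias-corrected Adam moments and the
    same simplex projection.
``ga``
    A genetic algorithm over simplex-valued individuals with roulette
    selection, arithmetic crossover, random-coordinate-replacement mutation
    and elitism; fitness is -RMSE.
``meta`` (meta-learning)
    A depth-limited regression tree stacked on the prediction columns;
    weights are its normalised impurity-reduction feature importances.

The optimising strategies (af, adam, ga, ql) return the best iterate seen,
so their training MSE never exceeds that of the equal-weight start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .learners import PredictionMatrix, TrainingTrace

__all__ = [
    "WeightVector", "QLearningConfig", "AttentionConfig", "AdamConfig",
    "GAWeightConfig", "weights_r2_normalization", "weights_adaptive_learning",
    "weights_self_attention", "weights_q_learning", "weights_adaptive_filter",
    "weights_adam", "weights_ga", "weights_meta_learning", "STRATEGIES",
    "compute_weights", "simplex_project",
]


@dataclass
class WeightVector:
    """K nonnegative weights summing to one, with strategy diagnostics."""

    w: np.ndarray
    learner_names: list[str]
    strategy: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if len(self.w) != len(self.learner_names):
            raise ValueError("weights and learner_names must align")
        if len(self.w) < 1:
            raise ValueError("need at least one learner")
        if (self.w < -1e-12).any():
            raise ValueError("weights must be nonnegative")
        if abs(self.w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {self.w.sum()})")

    def as_dict(self) -> dict:
        return dict(zip(self.learner_names, self.w.tolist()))


@dataclass(frozen=True)
class QLearningConfig:
    alpha: float = 0.1        # learning rate of the printed update
    gamma: float = 0.9        # discount factor
    epsilon: float = 0.1      # exploration rate
    delta: float = 0.05       # per-action weight increment & state resolution
    episodes: int = 400
    seed: int = 0
    standard_update: bool = False  # textbook Q += a*(r + g*maxQ' - Q) variant

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma", "epsilon"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")


@dataclass(frozen=True)
class AttentionConfig:
    projection_dim: int = 0   # 0 -> identity projection
    standardize: bool = True
    temperature: float = 1.0
    seed: int = 0
    trained: bool = False     # gradient-train the projection on ensemble MSE
    train_iterations: int = 200
    train_lr: float = 0.05

    def __post_init__(self) -> None:
        if self.projection_dim < 0:
            raise ValueError("projection_dim must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.trained and self.projection_dim == 0:
            object.__setattr__(self, "projection_dim", 16)


@dataclass(frozen=True)
class AdamConfig:
    lr: float = 0.2
    beta1: float = 0.7
    beta2: float = 0.97
    iterations: int = 120
    eps_hat: float = 1e-8

    def __post_init__(self) -> None:
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("betas must lie in [0, 1)")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")


@dataclass(frozen=True)
class GAWeightConfig:
    population_size: int = 40
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")


# ---------------------------------------------------------------------------
# helpers


def simplex_project(w: np.ndarray) -> np.ndarray:
    """Clip negatives to zero and renormalise to sum one (equal weights if all zero)."""
    w = np.clip(np.asarray(w, dtype=float), 0.0, None)
    s = w.sum()
    if s <= 0:
        return np.full(len(w), 1.0 / len(w))
    return w / s


def _check_aligned(P: PredictionMatrix, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if len(y) != P.values.shape[0]:
        raise ValueError(
            f"target length {len(y)} does not match prediction rows {P.values.shape[0]}"
        )
    return y


def _ensemble_mse(P: np.ndarray, w: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((P @ w - y) ** 2))


def _mse_grad(P: np.ndarray, w: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Analytic gradient of J(w) = mean((P w - y)^2): (2/N) P^T (P w - y)."""
    n = len(y)
    return (2.0 / n) * P.T @ (P @ w - y)


# ---------------------------------------------------------------------------
# the eight strategies


def weights_r2_normalization(P: PredictionMatrix, y: np.ndarray) -> WeightVector:
    """Normalise per-learner R^2 scores (floored at 0) to sum one.

    If no learner beats the mean predictor (all R^2 <= 0), weights are equal.
    """
    y = _check_aligned(P, y)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        r2 = np.zeros(P.n_learners)
    else:
        ss_res = np.sum((P.values - y[:, None]) ** 2, axis=0)
        r2 = 1.0 - ss_res / ss_tot
    pos = np.clip(r2, 0.0, None)
    w = pos / pos.sum() if pos.sum() > 0 else np.full(P.n_learners, 1.0 / P.n_learners)
    return WeightVector(w, P.learner_names, "r2", {"r2_scores": r2})


def weights_adaptive_learning(
    trace: TrainingTrace | np.ndarray,
    learner_names: list[str] | None = None,
    seed: int = 0,
) -> WeightVector:
    """Training-process scores S_i = 1 - MAE_i / mean(MAE), min-max then
    sum normalised.

    Accepts either a :class:`TrainingTrace` or a raw per-learner MAE vector.
    Gaussian initial weights are drawn (and recorded in diagnostics) but are
    overwritten by the iterated scores; all-equal MAE degenerates to equal
    weights.
    """
    if isinstance(trace, TrainingTrace):
        names = learner_names or list(trace.records)
        mae = trace.mae_vector(names)
    else:
        mae = np.asarray(trace, dtype=float)
        names = learner_names or [f"L{i}" for i in range(len(mae))]
    if (mae < 0).any():
        raise ValueError("MAE values must be nonnegative")
    rng = np.random.default_rng(seed)
    init = rng.normal(0, 1, len(mae))  # drawn per the procedure, then overwritten
    mean_mae = mae.mean()
    if mean_mae == 0:
        w = np.full(len(mae), 1.0 / len(mae))
        return WeightVector(w, names, "al", {"scores": np.ones(len(mae)), "init": init})
    scores = 1.0 - mae / mean_mae
    span = scores.max() - scores.min()
    if span == 0:
        w = np.full(len(mae), 1.0 / len(mae))
        normed = np.full(len(mae), 0.5)
    else:
        normed = (scores - scores.min()) / span
        w = normed / normed.sum()
    return WeightVector(w, names, "al",
                        {"scores": scores, "minmax": normed, "init": init})


def weights_self_attention(
    P: PredictionMatrix, config: AttentionConfig | None = None,
    y: np.ndarray | None = None,
) -> WeightVector:
    """Dot-product self-attention over learner prediction columns.

    Each column h_i is z-scored (optional), optionally projected to
    ``projection_dim`` by a fixed seeded random linear map, scored against
    every other column by the scaled dot product h_i . h_j / sqrt(d) (d the
    feature-vector length, the usual scaled-dot-product stabilisation),
    reduced by the row mean and softmax-normalised into weights.  The full
    K x K attention matrix is kept in diagnostics.
    """
    config = config or AttentionConfig()
    H = P.values.T.astype(float).copy()  # (K, n)
    if config.standardize:
        if P.values.shape[0] < 2:
            raise ValueError("standardize requires at least 2 samples")
        sd = H.std(axis=1)
        zero = sd == 0
        if zero.any():
            warnings.warn(
                "zero-variance prediction column(s) treated as all-zero features"
            )
        mu = H.mean(axis=1)
        H = np.where(zero[:, None], 0.0, (H - mu[:, None]) / np.where(zero, 1, sd)[:, None])
    if config.trained:
        if y is None:
            raise ValueError("trained attention projection requires targets y")
        return _attention_trained(P, H, np.asarray(y, float), config)
    if config.projection_dim > 0:
        rng = np.random.default_rng(config.seed)
        proj = rng.normal(0, 1.0 / np.sqrt(H.shape[1]), (H.shape[1], config.projection_dim))
        H = H @ proj
    scores = H @ H.T / np.sqrt(H.shape[1])  # (K, K) scaled dot-product similarities
    s = scores.mean(axis=1)
    s = s / config.temperature
    s = s - s.max()  # softmax stabilisation
    e = np.exp(s)
    w = e / e.sum()
    return WeightVector(w, P.learner_names, "sam",
                        {"attention": scores, "aggregate": s})


def _attention_trained(P: PredictionMatrix, H: np.ndarray, y: np.ndarray,
                       config: AttentionConfig) -> WeightVector:
    """Attention with the linear projection trained by Adam on ensemble MSE."""
    Pm = P.values
    K, n = H.shape
    d = config.projection_dim
    rng = np.random.default_rng(config.seed)
    W = rng.normal(0, 1.0 / np.sqrt(n), (n, d))
    m = np.zeros_like(W)
    v = np.zeros_like(W)

    def forward(W):
        Q = H @ W
        scores = Q @ Q.T / np.sqrt(d)
        s = scores.mean(axis=1) / config.temperature
        e = np.exp(s - s.max())
        return Q, scores, e / e.sum()

    Q, scores, w = forward(W)
    best_w, best_scores = w.copy(), scores
    best_mse = _ensemble_mse(Pm, w, y)
    losses = [best_mse]
    for t in range(1, config.train_iterations + 1):
        Q, scores, w = forward(W)
        g_w = _mse_grad(Pm, w, y)
        g_s = (np.diag(w) - np.outer(w, w)) @ g_w / config.temperature
        g_scores = np.tile((g_s / K)[:, None], (1, K))
        dQ = (g_scores + g_scores.T) @ Q / np.sqrt(d)
        dW = H.T @ dQ
        m = 0.9 * m + 0.1 * dW
        v = 0.999 * v + 0.001 * dW ** 2
        W = W - config.train_lr * (m / (1 - 0.9 ** t)) / (
            np.sqrt(v / (1 - 0.999 ** t)) + 1e-8
        )
        mse = _ensemble_mse(Pm, w, y)
        losses.append(mse)
        if mse < best_mse:
            best_mse, best_w, best_scores = mse, w.copy(), scores
    return WeightVector(best_w, P.learner_names, "sam",
                        {"attention": best_scores, "loss_curve": np.array(losses)})


def _discretise(w: np.ndarray, delta: float) -> tuple:
    return tuple(np.round(w / delta).astype(int).tolist())


def weights_q_learning(
    P: PredictionMatrix, y: np.ndarray, config: QLearningConfig | None = None,
    record_path: bool = False,
) -> WeightVector:
    """Tabular Q-learning over the weight simplex.

    State: the weight vector discretised to the ``delta`` grid.  Action i:
    add ``delta`` to w_i, renormalise.  Reward: the decrease in ensemble MSE
    scaled by 1/var(y).  The update is applied as printed in the source
    method, Q <- (1-a) Q + (r + g max Q'), with the textbook variant
    available via ``standard_update``.  Returns the visited weight vector
    with the best ensemble MSE.
    """
    config = config or QLearningConfig()
    y = _check_aligned(P, y)
    K = P.n_learners
    if K == 1:
        return WeightVector(np.array([1.0]), P.learner_names, "ql", {})
    rng = np.random.default_rng(config.seed)
    Pm = P.values
    var_y = np.var(y) or 1.0
    w = np.full(K, 1.0 / K)
    Q: dict[tuple, np.ndarray] = {}
    best_w, best_mse = w.copy(), _ensemble_mse(Pm, w, y)
    mse = best_mse
    path = [w.copy()] if record_path else None
    for _ in range(config.episodes):
        state = _discretise(w, config.delta)
        qvals = Q.setdefault(state, np.zeros(K))
        if rng.random() < config.epsilon:
            action = int(rng.integers(K))
        else:
            action = int(np.argmax(qvals))
        w_new = w.copy()
        w_new[action] += config.delta
        w_new = w_new / w_new.sum()
        mse_new = _ensemble_mse(Pm, w_new, y)
        reward = (mse - mse_new) / var_y
        next_q = Q.setdefault(_discretise(w_new, config.delta), np.zeros(K))
        target = reward + config.gamma * next_q.max()
        if config.standard_update:
            qvals[action] += config.alpha * (target - qvals[action])
        else:  # as printed: the target term is not scaled by the learning rate
            qvals[action] = (1 - config.alpha) * qvals[action] + target
        delta_w = np.abs(w_new - w).max()
        w, mse = w_new, mse_new
        if record_path:
            path.append(w.copy())
        if mse < best_mse:
            best_mse, best_w = mse, w.copy()
        if delta_w < 1e-4:
            break
    diag = {"best_mse": best_mse, "n_states": len(Q), "q_table": Q}
    if record_path:
        diag["weight_path"] = path
    return WeightVector(best_w, P.learner_names, "ql", diag)


def weights_adaptive_filter(
    P: PredictionMatrix, y: np.ndarray, iterations: int = 100,
    lr: float | None = None, record_path: bool = False,
) -> WeightVector:
    """Projected gradient descent on the ensemble MSE.

    Starts at equal weights; after every step negatives are clipped and the
    vector renormalised to sum one.  ``lr=None`` uses the inverse Lipschitz
    constant of the gradient (2 sigma_max(P)^2 / N).  The best iterate seen
    is returned, so the result never underperforms the equal-weight start.
    """
    y = _check_aligned(P, y)
    Pm = P.values
    K = P.n_learners
    w = np.full(K, 1.0 / K)
    if lr is None:
        smax = np.linalg.norm(Pm, 2)
        lip = 2.0 * smax ** 2 / len(y)
        lr = 1.0 / lip if lip > 0 else 1.0
    losses = [_ensemble_mse(Pm, w, y)]
    best_w, best_mse = w.copy(), losses[0]
    path = [w.copy()] if record_path else None
    for _ in range(iterations):
        w = simplex_project(w - lr * _mse_grad(Pm, w, y))
        mse = _ensemble_mse(Pm, w, y)
        losses.append(mse)
        if record_path:
            path.append(w.copy())
        if mse < best_mse:
            best_mse, best_w = mse, w.copy()
    diag = {"loss_curve": np.array(losses), "lr": lr}
    if record_path:
        diag["weight_path"] = path
    return WeightVector(best_w, P.learner_names, "af", diag)


def weights_adam(
    P: PredictionMatrix, y: np.ndarray, config: AdamConfig | None = None,
    record_path: bool = False,
) -> WeightVector:
    """Adam on the ensemble MSE with a simplex projection after every step."""
    config = config or AdamConfig()
    y = _check_aligned(P, y)
    Pm = P.values
    K = P.n_learners
    w = np.full(K, 1.0 / K)
    m = np.zeros(K)
    v = np.zeros(K)
    losses = [_ensemble_mse(Pm, w, y)]
    best_w, best_mse = w.copy(), losses[0]
    path = [w.copy()] if record_path else None
    for t in range(1, config.iterations + 1):
        g = _mse_grad(Pm, w, y)
        m = config.beta1 * m + (1 - config.beta1) * g
        v = config.beta2 * v + (1 - config.beta2) * g ** 2
        mhat = m / (1 - config.beta1 ** t)
        vhat = v / (1 - config.beta2 ** t)
        w = simplex_project(w - config.lr * mhat / (np.sqrt(vhat) + config.eps_hat))
        mse = _ensemble_mse(Pm, w, y)
        losses.append(mse)
        if record_path:
            path.append(w.copy())
        if mse < best_mse:
            best_mse, best_w = mse, w.copy()
    diag = {"loss_curve": np.array(losses)}
    if record_path:
        diag["weight_path"] = path
    return WeightVector(best_w, P.learner_names, "adam", diag)


def weights_ga(
    P: PredictionMatrix, y: np.ndarray, config: GAWeightConfig | None = None,
    record_path: bool = False,
) -> WeightVector:
    """Genetic algorithm over simplex weight vectors; fitness = -RMSE.

    Roulette selection on shifted-positive fitness, arithmetic crossover,
    mutation by replacing one coordinate with a uniform draw (then
    renormalising), generational replacement with elitism.  Returns the best
    individual ever seen; the best-fitness curve is non-decreasing.
    """
    config = config or GAWeightConfig()
    y = _check_aligned(P, y)
    Pm = P.values
    K = P.n_learners
    if K == 1:
        return WeightVector(np.array([1.0]), P.learner_names, "ga", {})
    rng = np.random.default_rng(config.seed)

    def fitness(w: np.ndarray) -> float:
        return -float(np.sqrt(_ensemble_mse(Pm, w, y)))

    pop = rng.dirichlet(np.ones(K), size=config.population_size)
    pop[0] = np.full(K, 1.0 / K)  # include the equal-weight start
    fit = np.array([fitness(w) for w in pop])
    bi = int(np.argmax(fit))
    best_w, best_fit = pop[bi].copy(), float(fit[bi])
    curve = [best_fit]
    path = [best_w.copy()] if record_path else None
    for _ in range(config.generations):
        shifted = fit - fit.min() + 1e-12
        probs = shifted / shifted.sum()
        children = np.empty_like(pop)
        for i in range(len(pop)):
            pa, pb = rng.choice(len(pop), size=2, p=probs)
            if rng.random() < config.crossover_rate:
                lam = rng.random()
                child = lam * pop[pa] + (1 - lam) * pop[pb]
            else:
                child = pop[pa].copy()
            if rng.random() < config.mutation_rate:
                child[rng.integers(K)] = rng.random()
            children[i] = simplex_project(child)
        children[0] = best_w  # elitism
        pop = children
        fit = np.array([fitness(w) for w in pop])
        gi = int(np.argmax(fit))
        if fit[gi] > best_fit:
            best_fit, best_w = float(fit[gi]), pop[gi].copy()
        curve.append(best_fit)
        if record_path:
            path.append(best_w.copy())
    diag = {"fitness_curve": np.array(curve)}
    if record_path:
        diag["weight_path"] = path
    return WeightVector(best_w, P.learner_names, "ga", diag)


def weights_meta_learning(
    P_oof: PredictionMatrix, y: np.ndarray, max_depth: int = 6, seed: int = 0,
) -> WeightVector:
    """Regression-tree stacking: weights are normalised impurity importances.

    A depth-limited tree maps the K out-of-fold prediction columns to the
    target; a column never used by any split receives weight 0.  Constant
    targets (no possible split) degenerate to equal weights with a warning.
    """
    y = _check_aligned(P_oof, y)
    K = P_oof.n_learners
    if K == 1:
        return WeightVector(np.array([1.0]), P_oof.learner_names, "meta", {})
    if np.ptp(y) == 0:
        warnings.warn("constant target: meta-learning weights degenerate to equal")
        return WeightVector(np.full(K, 1.0 / K), P_oof.learner_names, "meta", {})
    tree = DecisionTreeRegressor(max_depth=max_depth, random_state=seed)
    tree.fit(P_oof.values, y)
    imp = tree.feature_importances_
    if imp.sum() <= 0:
        w = np.full(K, 1.0 / K)
    else:
        w = imp / imp.sum()
    return WeightVector(w, P_oof.learner_names, "meta", {"tree_depth": tree.get_depth()})


STRATEGIES = ("sam", "ql", "af", "al", "ga", "meta", "adam", "r2")


def compute_weights(
    strategy: str,
    P_oof: PredictionMatrix,
    y: np.ndarray,
    trace: TrainingTrace | None = None,
    seed: int = 0,
    record_path: bool = False,
) -> WeightVector:
    """Dispatch one of the eight strategies by short name."""
    if strategy == "sam":
        return weights_self_attention(P_oof, AttentionConfig(seed=seed))
    if strategy == "ql":
        return weights_q_learning(P_oof, y, QLearningConfig(seed=seed),
                                  record_path=record_path)
    if strategy == "af":
        return weights_adaptive_filter(P_oof, y, record_path=record_path)
    if strategy == "al":
        if trace is None:
            raise ValueError("adaptive learning requires a TrainingTrace")
        return weights_adaptive_learning(trace, P_oof.learner_names, seed=seed)
    if strategy == "ga":
        return weights_ga(P_oof, y, GAWeightConfig(seed=seed), record_path=record_path)
    if strategy == "meta":
        return weights_meta_learning(P_oof, y, seed=seed)
    if strategy == "adam":
        return weights_adam(P_oof, y, record_path=record_path)
    if strategy == "r2":
        return weights_r2_normalization(P_oof, y)
    raise ValueError(f"unknown strategy '{strategy}'; choose from {STRATEGIES}")
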