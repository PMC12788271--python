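"""The eight weight-allocation strategies: frozen examples, oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynawa.learners import PredictionMatrix
from dynawa.weights import (
    AdamConfig,
    AttentionConfig,
    GAWeightConfig,
    QLearningConfig,
    compute_weights,
    simplex_project,
    weights_adam,
    weights_adaptive_filter,
    weights_adaptive_learning,
    weights_ga,
    weights_meta_learning,
    weights_q_learning,
    weights_r2_normalization,
    weights_self_attention,
)
from dynawa.weights import _mse_grad

from .conftest import oracle_matrix, trace_from_matrix


def pmat(values, names=None):
    values = np.atleast_2d(np.asarray(values, float))
    names = names or [f"L{i}" for i in range(values.shape[1])]
    return PredictionMatrix(values, names, np.arange(values.shape[0]))


def matrix_with_r2(r2_targets, n=64, seed=0):
    """Columns whose R^2 against y are exactly the requested values."""
    rng = np.random.default_rng(seed)
    y = rng.normal(0, 1, n)
    y = (y - y.mean()) / np.sqrt(np.sum((y - y.mean()) ** 2))  # SStot = 1
    u = rng.normal(0, 1, n)
    u /= np.linalg.norm(u)
    cols = [y + np.sqrt(1.0 - r2) * u for r2 in r2_targets]
    return pmat(np.column_stack(cols)), y


class TestR2Normalization:
    def test_equal_scores_split_evenly(self):
        P, y = matrix_with_r2([0.8, 0.8])
        assert np.allclose(weights_r2_normalization(P, y).w, [0.5, 0.5])

    def test_zero_score_learner_gets_nothing(self):
        P, y = matrix_with_r2([1.0, 0.0])
        assert np.allclose(weights_r2_normalization(P, y).w, [1.0, 0.0], atol=1e-9)

    def test_printed_arithmetic(self):
        P, y = matrix_with_r2([0.9, 0.6, 0.3])
        assert np.allclose(weights_r2_normalization(P, y).w,
                           [0.5, 1 / 3, 1 / 6], atol=1e-9)

    def test_all_nonpositive_degenerates_to_equal(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 30)
        P = pmat(rng.normal(10, 1, (30, 3)))
        assert np.allclose(weights_r2_normalization(P, y).w, 1 / 3)

    def test_length_mismatch_errors(self):
        P, y = matrix_with_r2([0.5])
        with pytest.raises(ValueError, match="does not match"):
            weights_r2_normalization(P, y[:-1])


class TestAdaptiveLearning:
    def test_hand_computed_chain(self):
        """MAE [1,2,3] -> S [0.5,0,-0.5] -> min-max [1,0.5,0] -> w [2/3,1/3,0]."""
        wv = weights_adaptive_learning(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(wv.w, [2 / 3, 1 / 3, 0.0])
        assert np.allclose(wv.diagnostics["scores"], [0.5, 0.0, -0.5])

    def test_zero_error_learner_scores_one(self):
        wv = weights_adaptive_learning(np.array([0.0, 2.0]))
        assert wv.diagnostics["scores"][0] == pytest.approx(1.0)

    def test_learner_at_mean_scores_zero(self):
        wv = weights_adaptive_learning(np.array([2.0, 2.0, 2.0, 2.0]))
        assert np.allclose(wv.diagnostics["scores"], 0.0)
        assert np.allclose(wv.w, 0.25)  # declared degenerate case

    def test_all_zero_mae_degenerates_to_equal(self):
        assert np.allclose(weights_adaptive_learning(np.zeros(3)).w, 1 / 3)


def brute_force_attention(P_values, temperature=1.0):
    """Independent oracle: z-score, all K^2 scaled dot products, row means, softmax."""
    cols = []
    for j in range(P_values.shape[1]):
        c = P_values[:, j]
        sd = c.std()
        cols.append(np.zeros_like(c) if sd == 0 else (c - c.mean()) / sd)
    K = len(cols)
    n = P_values.shape[0]
    scores = np.array([[np.dot(cols[i], cols[j]) / np.sqrt(n) for j in range(K)]
                       for i in range(K)])
    s = np.array([scores[i].mean() for i in range(K)]) / temperature
    e = np.exp(s - s.max())
    return e / e.sum()


class TestSelfAttention:
    def test_identical_columns_share_weight(self):
        col = np.random.default_rng(2).random(10)
        P = pmat(np.column_stack([col, col, col]))
        assert np.allclose(weights_self_attention(P).w, 1 / 3)

    def test_singleton_is_one(self):
        P = pmat(np.random.default_rng(3).random((6, 1)))
        assert np.allclose(weights_self_attention(P).w, [1.0])

    @pytest.mark.parametrize("K,n,seed", [(2, 4, 0), (3, 4, 1), (3, 6, 2), (4, 6, 3)])
    def test_matches_brute_force_oracle(self, K, n, seed):
        P = pmat(np.random.default_rng(seed).random((n, K)))
        assert np.allclose(weights_self_attention(P).w,
                           brute_force_attention(P.values), atol=1e-12)

    def test_zero_variance_column_warns_and_scores_zero(self):
        rng = np.random.default_rng(4)
        P = pmat(np.column_stack([rng.random(8), np.full(8, 0.3)]))
        with pytest.warns(UserWarning, match="zero-variance"):
            wv = weights_self_attention(P)
        assert wv.w[0] > wv.w[1]

    def test_trained_projection_reduces_training_loss(self):
        P, y = oracle_matrix(K=4, n=100, seed=5, uninformative="shuffled")
        cfg = AttentionConfig(trained=True, seed=0)
        wv = weights_self_attention(P, cfg, y=y)
        curve = wv.diagnostics["loss_curve"]
        assert curve.min() <= curve[0]
        assert np.argmax(wv.w) == 0


class TestQLearning:
    def test_printed_update_with_unit_rate_stores_reward(self):
        """alpha=1, gamma=0: the printed rule collapses to Q(s,a) <- r."""
        P, y = oracle_matrix(K=3, n=50, seed=6, uninformative="shuffled")
        cfg = QLearningConfig(alpha=1.0, gamma=0.0, epsilon=0.0, episodes=1, seed=0)
        wv = weights_q_learning(P, y, cfg)
        q_table = wv.diagnostics["q_table"]
        w0 = np.full(3, 1 / 3)
        state0 = tuple(np.round(w0 / cfg.delta).astype(int).tolist())
        action = int(np.argmax(q_table[state0]))  # greedy pick of the lone update
        w1 = w0.copy()
        w1[action] += cfg.delta
        w1 /= w1.sum()
        mse0 = np.mean((P.values @ w0 - y) ** 2)
        mse1 = np.mean((P.values @ w1 - y) ** 2)
        expected_r = (mse0 - mse1) / np.var(y)
        assert q_table[state0][action] == pytest.approx(expected_r, rel=1e-9)

    def test_singleton_for_any_config(self):
        P = pmat(np.random.default_rng(7).random((10, 1)))
        wv = weights_q_learning(P, P.values[:, 0], QLearningConfig(seed=1))
        assert np.allclose(wv.w, [1.0])

    def test_oracle_learner_gets_argmax_weight(self):
        P, y = oracle_matrix(K=3, n=150, seed=8, uninformative="shuffled")
        wv = weights_q_learning(P, y, QLearningConfig(episodes=300, seed=0))
        assert np.argmax(wv.w) == 0
        # brute check: the one-hot oracle vector minimises the ensemble MSE
        mses = [np.mean((P.values @ np.eye(3)[k] - y) ** 2) for k in range(3)]
        assert np.argmin(mses) == 0


class TestAdaptiveFilter:
    def test_identical_columns_stay_equal(self):
        col = np.random.default_rng(9).random(12)
        P = pmat(np.column_stack([col] * 4))
        wv = weights_adaptive_filter(P, col + 0.1, record_path=True)
        for w in wv.diagnostics["weight_path"]:
            assert np.allclose(w, 0.25)

    def test_analytic_gradient_matches_central_differences(self):
        rng = np.random.default_rng(10)
        P = rng.random((5, 3))
        y = rng.random(5)
        w = np.array([0.2, 0.5, 0.3])
        g = _mse_grad(P, w, y)
        eps = 1e-6
        for k in range(3):
            d = np.zeros(3)
            d[k] = eps
            num = (np.mean((P @ (w + d) - y) ** 2)
                   - np.mean((P @ (w - d) - y) ** 2)) / (2 * eps)
            assert abs(num - g[k]) / max(abs(num), 1e-12) < 1e-5

    def test_oracle_column_dominates(self):
        rng = np.random.default_rng(11)
        y = rng.normal(15, 6, 100)
        P = pmat(np.column_stack([y, rng.normal(15, 6, 100), rng.normal(15, 6, 100)]))
        wv = weights_adaptive_filter(P, y, iterations=300)
        assert wv.w[0] > 0.9


class TestAdam:
    def test_identical_columns_stay_equal(self):
        col = np.random.default_rng(12).random(10)
        P = pmat(np.column_stack([col] * 3))
        assert np.allclose(weights_adam(P, col).w, 1 / 3)

    def test_best_seen_never_worse_than_start(self):
        rng = np.random.default_rng(13)
        P = pmat(rng.random((20, 4)))
        y = rng.random(20)
        wv = weights_adam(P, y)
        curve = wv.diagnostics["loss_curve"]
        assert np.mean((P.values @ wv.w - y) ** 2) <= curve[0] + 1e-12

    def test_oracle_column_dominates(self):
        P, y = oracle_matrix(K=4, n=120, seed=14, uninformative="shuffled")
        assert np.argmax(weights_adam(P, y).w) == 0


class TestGA:
    def test_singleton(self):
        P = pmat(np.random.default_rng(15).random((8, 1)))
        assert np.allclose(weights_ga(P, P.values[:, 0]).w, [1.0])

    def test_oracle_recovery_and_monotone_fitness(self):
        P, y = oracle_matrix(K=3, n=120, seed=16, uninformative="shuffled")
        wv = weights_ga(P, y, GAWeightConfig(population_size=40, generations=100, seed=0))
        assert wv.w[0] > 0.8
        assert (np.diff(wv.diagnostics["fitness_curve"]) >= -1e-12).all()


class TestMetaLearning:
    def test_singleton(self):
        P = pmat(np.random.default_rng(17).random((8, 1)))
        assert np.allclose(weights_meta_learning(P, P.values[:, 0]).w, [1.0])

    def test_exact_column_takes_all_importance(self):
        rng = np.random.default_rng(18)
        y = rng.normal(15, 6, 60)
        P = pmat(np.column_stack([y, np.full(60, 1.0), np.full(60, 2.0)]))
        wv = weights_meta_learning(P, y)
        assert wv.w[0] == pytest.approx(1.0)

    def test_constant_target_warns_equal(self):
        P = pmat(np.random.default_rng(19).random((10, 3)))
        with pytest.warns(UserWarning, match="constant target"):
            wv = weights_meta_learning(P, np.full(10, 5.0))
        assert np.allclose(wv.w, 1 / 3)


class TestSimplexInvariant:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(1, 10), st.integers(5, 20), st.integers(0, 10_000))
    def test_every_strategy_returns_a_simplex_vector(self, K, n, seed):
        rng = np.random.default_rng(seed)
        P = pmat(rng.normal(15, 6, (n, K)))
        y = rng.normal(15, 6, n)
        trace = trace_from_matrix(P, y)
        for strat in ("sam", "ql", "af", "al", "ga", "meta", "adam", "r2"):
            wv = compute_weights(strat, P, y, trace=trace, seed=seed % 100)
            assert (wv.w >= -1e-12).all()
            assert wv.w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_simplex_project_handles_degenerate_input(self):
        assert np.allclose(simplex_project(np.array([-1.0, -2.0])), 0.5)
        assert np.allclose(simplex_project(np.array([2.0, 2.0])), 0.5)


class TestConfigValidation:
    @pytest.mark.parametrize("cfg,kw", [
        (QLearningConfig, {"alpha": 1.5}),
        (QLearningConfig, {"delta": 0.0}),
        (AttentionConfig, {"temperature": 0.0}),
        (AttentionConfig, {"projection_dim": -1}),
        (AdamConfig, {"beta1": 1.0}),
        (AdamConfig, {"lr": 0.0}),
        (GAWeightConfig, {"population_size": 1}),
    ])
    def test_invalid_configs_rejected(self, cfg, kw):
        with pytest.raises(ValueError):
            cfg(**kw)
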