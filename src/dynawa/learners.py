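"""Base-learner registry, grid search and out-of-fold prediction.

The default registry declares 34 regressors in three families:

* ``TM`` — 9 tree-based models (decision tree through gradient boosting);
* ``DL`` — 15 flexible nonlinear models: small neural networks (dense,
  convolutional, recurrent, extreme-learning, autoencoder and adversarial
  variants) plus two nonlinear basis/mixture models (MARS-style splines and
  Gaussian-mixture regression);
* ``LRM`` — 10 linear / regularised / instance-based models.

Printed reference hyperparameters (e.g. 770 random-forest trees, SVR with a
linear kernel and C = 1.0, PLSR with 3 components, KNR with 10 uniform
neighbours, Ridge/Lasso/elastic-net alpha 1.2 with mixing 0.65) are the
registry defaults; a ``fast`` profile shrinks tree counts and training
epochs for desk-scale experiments without changing the model set.

Every learner is trained on the calibration set with k-fold
cross-validation: out-of-fold (OOF) predictions — each sample predicted by
the model not trained on its fold — feed the weight-allocation strategies
without leakage, and a refit on the full calibration set predicts the
validation samples.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import (
    AdaBoostRegressor,
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    HistGradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import ARDRegression, ElasticNet, Lasso, Ridge, TweedieRegressor
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from . import nn
from .synthetic import SpectraSet

__all__ = [
    "LearnerSpec",
    "LearnerRegistry",
    "PredictionMatrix",
    "TrainingTrace",
    "default_registry",
    "build_estimator",
    "grid_search",
    "fit_predict_all",
    "fold_assignments",
]


# ---------------------------------------------------------------------------
# registry data types


@dataclass(frozen=True)
class LearnerSpec:
    """Declaration of one base learner."""

    name: str
    family: str  # TM | DL | LRM
    builder: str
    hyperparams: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    backend: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("TM", "DL", "LRM"):
            raise ValueError(f"family must be TM/DL/LRM, got {self.family!r}")


@dataclass(frozen=True)
class LearnerRegistry:
    specs: tuple[LearnerSpec, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("learner names must be unique")

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.specs:
            counts[s.family] = counts.get(s.family, 0) + 1
        return counts

    def subset(self, names) -> "LearnerRegistry":
        keep = set(names)
        return LearnerRegistry(tuple(s for s in self.specs if s.name in keep))

    def family_of(self) -> dict[str, str]:
        return {s.name: s.family for s in self.specs}


@dataclass
class PredictionMatrix:
    """n_samples x K matrix of base-learner predictions (g kg^-1)."""

    values: np.ndarray
    learner_names: list[str]
    sample_idx: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.sample_idx = np.asarray(self.sample_idx, dtype=int)
        if self.values.shape[1] != len(self.learner_names):
            raise ValueError("column count must equal learner count")
        if self.values.shape[0] != len(self.sample_idx):
            raise ValueError("row count must equal sample_idx length")
        if not np.isfinite(self.values).all():
            raise ValueError("prediction matrix contains non-finite values")

    @property
    def n_learners(self) -> int:
        return self.values.shape[1]

    def select(self, names) -> "PredictionMatrix":
        cols = [self.learner_names.index(n) for n in names]
        return PredictionMatrix(
            values=self.values[:, cols],
            learner_names=list(names),
            sample_idx=self.sample_idx.copy(),
        )


@dataclass
class TrainingTrace:
    """Per-learner, per-fold error records from cross-validated training."""

    records: dict
    fold_of: np.ndarray

    def mae(self, name: str) -> float:
        return float(np.mean(self.records[name]["fold_mae"]))

    def mae_vector(self, names) -> np.ndarray:
        return np.array([self.mae(n) for n in names])


# ---------------------------------------------------------------------------
# bespoke estimators


class ELMRegressor(BaseEstimator, RegressorMixin):
    """Extreme learning machine: fixed random hidden layer + ridge readout."""

    def __init__(self, n_hidden=64, activation="identity", alpha=1e-3, seed=0):
        self.n_hidden = n_hidden
        self.activation = activation
        self.alpha = alpha
        self.seed = seed

    def _hidden(self, X):
        H = X @ self.W_ + self.b_
        return np.tanh(H) if self.activation == "tanh" else H

    def fit(self, X, y):
        X = np.asarray(X, float)
        rng = np.random.default_rng(self.seed)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        self.W_ = rng.normal(0, 1.0 / np.sqrt(X.shape[1]), (X.shape[1], self.n_hidden))
        self.b_ = rng.normal(0, 0.1, self.n_hidden)
        self.readout_ = Ridge(alpha=self.alpha).fit(self._hidden(Xs), y)
        return self

    def predict(self, X):
        return self.readout_.predict(self._hidden(self.scaler_.transform(np.asarray(X, float))))


class AutoencoderRegressor(BaseEstimator, RegressorMixin):
    """Dense autoencoder (Adam-trained reconstruction) + ridge on the code.

    ``noise_sd`` > 0 gives the denoising variant (noise added to the encoder
    input during reconstruction training only).
    """

    def __init__(self, hidden=64, code=16, epochs=60, lr=1e-2, noise_sd=0.0, seed=0):
        self.hidden = hidden
        self.code = code
        self.epochs = epochs
        self.lr = lr
        self.noise_sd = noise_sd
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, float)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        rng = np.random.default_rng(self.seed)
        f = X.shape[1]
        self.encoder_ = nn.Sequential([
            nn.Dense(f, self.hidden, rng), nn.Activation(),
            nn.Dense(self.hidden, self.code, rng),
        ])
        decoder = nn.Sequential([
            nn.Dense(self.code, self.hidden, rng), nn.Activation(),
            nn.Dense(self.hidden, f, rng),
        ])
        Xin = Xs + rng.normal(0, self.noise_sd, Xs.shape) if self.noise_sd > 0 else Xs
        auto = nn.Sequential(self.encoder_.layers + decoder.layers)
        self._train_recon(auto, Xin, Xs)  # reconstruction target is the clean input
        codes = self.encoder_.forward(Xs)
        self.readout_ = Ridge(alpha=1e-2).fit(codes, y)
        return self

    def _train_recon(self, auto, Xin, Xtarget, beta1=0.9, beta2=0.999, eps=1e-8):
        pairs = auto.parameters()
        m = [np.zeros_like(p) for p, _ in pairs]
        v = [np.zeros_like(p) for p, _ in pairs]
        for t in range(1, self.epochs + 1):
            pred = auto.forward(Xin, train=True)
            grad = 2.0 * (pred - Xtarget) / Xtarget.size
            auto.backward(grad)
            for idx, (p, g) in enumerate(pairs):
                m[idx] = beta1 * m[idx] + (1 - beta1) * g
                v[idx] = beta2 * v[idx] + (1 - beta2) * g ** 2
                p -= self.lr * (m[idx] / (1 - beta1 ** t)) / (
                    np.sqrt(v[idx] / (1 - beta2 ** t)) + eps
                )

    def predict(self, X):
        codes = self.encoder_.forward(self.scaler_.transform(np.asarray(X, float)))
        return self.readout_.predict(codes)


class GANRegressor(BaseEstimator, RegressorMixin):
    """Adversarially regularised regressor.

    The generator (random 24-dim input projection -> 256 hidden -> 1) is
    trained on MSE plus a small adversarial term from a discriminator
    (1 -> 256 -> 1 logit) that separates true targets from generated ones.
    """

    def __init__(self, gen_input=24, hidden=256, epochs=60, lr=5e-3,
                 adv_weight=0.1, seed=0):
        self.gen_input = gen_input
        self.hidden = hidden
        self.epochs = epochs
        self.lr = lr
        self.adv_weight = adv_weight
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        rng = np.random.default_rng(self.seed)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        self.y_mean_, self.y_sd_ = y.mean(), y.std() or 1.0
        ys = ((y - self.y_mean_) / self.y_sd_).reshape(-1, 1)
        d_in = min(self.gen_input, X.shape[1])
        self.proj_ = rng.normal(0, 1.0 / np.sqrt(X.shape[1]), (X.shape[1], d_in))
        Z = Xs @ self.proj_
        self.gen_ = nn.Sequential([
            nn.Dense(d_in, self.hidden, rng), nn.Activation(),
            nn.Dense(self.hidden, 1, rng),
        ])
        disc = nn.Sequential([
            nn.Dense(1, self.hidden, rng), nn.Activation(),
            nn.Dense(self.hidden, 1, rng),
        ])
        gp, dp = self.gen_.parameters(), disc.parameters()
        gm = [np.zeros_like(p) for p, _ in gp]
        gv = [np.zeros_like(p) for p, _ in gp]
        dm = [np.zeros_like(p) for p, _ in dp]
        dv = [np.zeros_like(p) for p, _ in dp]

        def adam_step(pairs, m, v, t, lr):
            for idx, (p, g) in enumerate(pairs):
                m[idx] = 0.9 * m[idx] + 0.1 * g
                v[idx] = 0.999 * v[idx] + 0.001 * g ** 2
                p -= lr * (m[idx] / (1 - 0.9 ** t)) / (
                    np.sqrt(v[idx] / (1 - 0.999 ** t)) + 1e-8
                )

        n = len(ys)
        for t in range(1, self.epochs + 1):
            # discriminator: real targets -> 1, generated -> 0
            fake = self.gen_.forward(Z)
            logits_real = disc.forward(ys, train=True)
            grad_real = (nn._sigmoid(logits_real) - 1.0) / (2 * n)
            disc.backward(grad_real)
            d_grads_real = [g.copy() for _, g in dp]
            logits_fake = disc.forward(fake, train=True)
            grad_fake = nn._sigmoid(logits_fake) / (2 * n)
            disc.backward(grad_fake)
            for (p, g), gr in zip(dp, d_grads_real):
                g += gr
            adam_step(dp, dm, dv, t, self.lr)
            # generator: MSE + adversarial (fool the discriminator)
            pred = self.gen_.forward(Z, train=True)
            logits = disc.forward(pred, train=True)
            d_in_grad = disc.backward((nn._sigmoid(logits) - 1.0) / n)
            grad = 2.0 * (pred - ys) / n + self.adv_weight * d_in_grad
            self.gen_.backward(grad)
            adam_step(gp, gm, gv, t, self.lr)
        return self

    def predict(self, X):
        Z = self.scaler_.transform(np.asarray(X, float)) @ self.proj_
        return self.gen_.predict(Z) * self.y_sd_ + self.y_mean_


class MARSRegressor(BaseEstimator, RegressorMixin):
    """Forward-selected hinge-basis (MARS-style) regression.

    Greedy residual-correlation screening over mirrored hinge pairs
    max(0, x - t) / max(0, t - x) at per-feature quantile knots; with
    ``degree`` = 2 products of two selected hinges are also candidates.
    Coefficients are refit by least squares after each addition.
    """

    def __init__(self, degree=2, max_terms=20, n_knots=10):
        self.degree = degree
        self.max_terms = max_terms
        self.n_knots = n_knots

    def _hinges(self, X):
        cols, meta = [], []
        for j in range(X.shape[1]):
            for t in self.knots_[j]:
                cols.append(np.maximum(X[:, j] - t, 0.0))
                cols.append(np.maximum(t - X[:, j], 0.0))
                meta.append((j, t, +1))
                meta.append((j, t, -1))
        return np.column_stack(cols), meta

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        qs = np.linspace(0.05, 0.95, self.n_knots)
        self.knots_ = [np.unique(np.quantile(Xs[:, j], qs)) for j in range(Xs.shape[1])]
        H, meta = self._hinges(Xs)
        self.terms_: list[tuple] = []  # each term: tuple of (j, t, sign) factors
        B = np.ones((len(y), 1))
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        resid = y - B @ coef
        while len(self.terms_) < self.max_terms:
            cand = H
            cand_meta = [(m,) for m in meta]
            if self.degree >= 2 and self.terms_:
                inter = []
                for term in self.terms_:
                    if len(term) >= self.degree:
                        continue
                    base = self._term_column(Xs, term)
                    inter.append(base[:, None] * H)
                    cand_meta.extend([term + (m,) for m in meta])
                cand = np.hstack([H] + inter)
            c = cand - cand.mean(axis=0)
            norms = np.linalg.norm(c, axis=0)
            norms[norms == 0] = np.inf
            scores = np.abs(c.T @ (resid - resid.mean())) / norms
            best = int(np.argmax(scores))
            if scores[best] <= 1e-10:
                break
            self.terms_.append(cand_meta[best])
            B = np.column_stack([np.ones(len(y))] +
                                [self._term_column(Xs, t) for t in self.terms_])
            coef, *_ = np.linalg.lstsq(B, y, rcond=None)
            new_resid = y - B @ coef
            if np.sum(resid ** 2) - np.sum(new_resid ** 2) < 1e-12:
                self.terms_.pop()
                break
            resid = new_resid
        self.coef_ = coef
        return self

    def _term_column(self, Xs, term):
        col = np.ones(Xs.shape[0])
        for j, t, sign in term:
            col = col * np.maximum(sign * (Xs[:, j] - t), 0.0)
        return col

    def predict(self, X):
        Xs = self.scaler_.transform(np.asarray(X, float))
        B = np.column_stack([np.ones(Xs.shape[0])] +
                            [self._term_column(Xs, t) for t in self.terms_])
        return B @ self.coef_


class GMMRegressor(BaseEstimator, RegressorMixin):
    """Gaussian-mixture regression: joint GMM over (PCA features, target).

    Prediction is the posterior-weighted conditional mean E[y | x] under a
    3-component full-covariance mixture.
    """

    def __init__(self, n_components=3, covariance_type="full", n_pca=10, seed=0):
        self.n_components = n_components
        self.covariance_type = covariance_type
        self.n_pca = n_pca
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        self.pca_ = make_pipeline(
            StandardScaler(), PCA(n_components=min(self.n_pca, X.shape[1], len(y) - 1))
        ).fit(X)
        Z = self.pca_.transform(X)
        self.y_mean_, self.y_sd_ = y.mean(), y.std() or 1.0
        joint = np.column_stack([Z, (y - self.y_mean_) / self.y_sd_])
        self.gmm_ = GaussianMixture(
            n_components=self.n_components,
            covariance_type=self.covariance_type,
            reg_covar=1e-4,
            random_state=self.seed,
        ).fit(joint)
        return self

    def predict(self, X):
        Z = self.pca_.transform(np.asarray(X, float))
        d = Z.shape[1]
        means, covs, weights = self.gmm_.means_, self.gmm_.covariances_, self.gmm_.weights_
        log_resp = np.zeros((len(Z), len(weights)))
        cond = np.zeros((len(Z), len(weights)))
        from scipy.stats import multivariate_normal

        for k in range(len(weights)):
            mx, my = means[k][:d], means[k][d]
            Sxx = covs[k][:d, :d]
            Syx = covs[k][d, :d]
            log_resp[:, k] = np.log(weights[k]) + multivariate_normal.logpdf(
                Z, mean=mx, cov=Sxx, allow_singular=True
            )
            sol = np.linalg.solve(Sxx, (Z - mx).T).T
            cond[:, k] = my + sol @ Syx
        log_resp -= log_resp.max(axis=1, keepdims=True)
        resp = np.exp(log_resp)
        resp /= resp.sum(axis=1, keepdims=True)
        return (resp * cond).sum(axis=1) * self.y_sd_ + self.y_mean_


class RVRRegressor(BaseEstimator, RegressorMixin):
    """Relevance-vector-style regression: RBF kernel basis + sparse
    Bayesian linear fit (automatic relevance determination)."""

    def __init__(self, gamma=None, n_centers=150, alpha_scale=1.2, seed=0):
        self.gamma = gamma
        self.n_centers = n_centers
        self.alpha_scale = alpha_scale
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, float)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        rng = np.random.default_rng(self.seed)
        n = len(Xs)
        idx = rng.permutation(n)[: min(self.n_centers, n)]
        self.centers_ = Xs[np.sort(idx)]
        self.gamma_ = self.gamma or 1.0 / Xs.shape[1]
        Phi = rbf_kernel(Xs, self.centers_, gamma=self.gamma_)
        self.model_ = ARDRegression(max_iter=150, alpha_1=1e-6 * self.alpha_scale).fit(Phi, y)
        return self

    def predict(self, X):
        Xs = self.scaler_.transform(np.asarray(X, float))
        return self.model_.predict(rbf_kernel(Xs, self.centers_, gamma=self.gamma_))


class PowerExpansion(BaseEstimator):
    """Per-feature polynomial powers 1..degree (no interaction terms)."""

    def __init__(self, degree=9):
        self.degree = degree

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, float)
        return np.hstack([X ** d for d in range(1, self.degree + 1)])

    def get_params(self, deep=False):
        return {"degree": self.degree}

    def set_params(self, **kw):
        self.degree = kw.get("degree", self.degree)
        return self


# ---------------------------------------------------------------------------
# architecture builders for the neural registry members


def _arch_dense(hidden_sizes, dropout=0.0, activation="identity"):
    def build(f, rng):
        layers, prev = [], f
        for h in hidden_sizes:
            layers += [nn.Dense(prev, h, rng), nn.Activation(activation)]
            if dropout > 0:
                layers.append(nn.Dropout(dropout, rng))
            prev = h
        layers.append(nn.Dense(prev, 1, rng))
        return layers
    return build


def _arch_cnn(filter_counts, kernel=3, pool=2):
    def build(f, rng):
        layers: list = [nn.ToSequence(f)]  # (n, f, 1)
        length, ch = f, 1
        for nf in filter_counts:
            if length < kernel:
                break
            layers.append(nn.Conv1D(ch, nf, kernel, rng))
            length -= kernel - 1
            ch = nf
            if length >= pool:
                layers.append(nn.AvgPool1D(pool))
                length //= pool
        layers += [nn.Flatten(), nn.Dense(length * ch, 1, rng)]
        return layers
    return build


def _arch_recurrent(cell, units, steps, dropout=0.2, activation="identity"):
    def build(f, rng):
        n_steps = min(steps, f)
        ch = f // n_steps
        layers: list = [nn.ToSequence(n_steps)]
        if cell == "lstm":
            layers.append(nn.LSTM(ch, units, rng))
        else:
            layers.append(nn.SimpleRNN(ch, units, rng, activation=activation))
        if dropout > 0:
            layers.append(nn.Dropout(dropout, rng))
        layers.append(nn.Dense(units, 1, rng))
        return layers
    return build


# ---------------------------------------------------------------------------
# registry definition


def _tm_specs() -> list[LearnerSpec]:
    return [
        LearnerSpec("RT", "TM", "rt",
                    {"max_depth": 4, "min_samples_split": 2, "min_samples_leaf": 2}),
        LearnerSpec("RF", "TM", "rf",
                    {"n_estimators": 770, "max_depth": 2, "min_samples_split": 2,
                     "min_samples_leaf": 3}),
        LearnerSpec("GBRT", "TM", "gbrt",
                    {"n_estimators": 560, "max_depth": 4, "learning_rate": 0.1,
                     "min_samples_split": 2, "min_samples_leaf": 2}),
        LearnerSpec("AdaBoost", "TM", "ada",
                    {"n_estimators": 480, "learning_rate": 0.1, "base_max_depth": 4}),
        LearnerSpec("XGBoost", "TM", "xgb",
                    {"n_estimators": 190, "max_depth": 3, "learning_rate": 0.2}),
        LearnerSpec("LightGBM", "TM", "lgbm",
                    {"n_estimators": 130, "max_depth": 4, "learning_rate": 0.05}),
        LearnerSpec("ExtraTrees", "TM", "extra",
                    {"n_estimators": 330, "max_depth": 5, "min_samples_split": 3,
                     "min_samples_leaf": 2}),
        LearnerSpec("HGBR", "TM", "hgbr",
                    {"max_iter": 400, "max_depth": 5, "learning_rate": 0.2,
                     "loss": "absolute_error"}),
        LearnerSpec("CatBoost", "TM", "cat",
                    {"n_estimators": 190, "max_depth": 3, "learning_rate": 0.1},
                    backend="sklearn.GradientBoostingRegressor"),
    ]


def _lrm_specs() -> list[LearnerSpec]:
    return [
        LearnerSpec("SVR", "LRM", "svr", {"kernel": "linear", "C": 1.0}),
        LearnerSpec("PLSR", "LRM", "plsr", {"n_components": 3}),
        LearnerSpec("Tweedie", "LRM", "tweedie", {"power": 0, "alpha": 1.0}),
        LearnerSpec("KNR", "LRM", "knr", {"n_neighbors": 10, "weights": "uniform"}),
        LearnerSpec("Ridge", "LRM", "ridge", {"alpha": 1.2}),
        LearnerSpec("Lasso", "LRM", "lasso", {"alpha": 1.2}),
        LearnerSpec("ENR", "LRM", "enr", {"alpha": 1.2, "l1_ratio": 0.65}),
        LearnerSpec("GAM", "LRM", "gam", {"smoothing": 0.7, "n_knots": 8}),
        LearnerSpec("ARS", "LRM", "ars", {"degree": 9, "alpha": 0.01},
                    grid={"alpha": [0.0001, 0.001, 0.01, 0.1]}),
        LearnerSpec("RVR", "LRM", "rvr", {"kernel": "rbf", "alpha_scale": 1.2}),
    ]


def _dl_specs() -> list[LearnerSpec]:
    return [
        LearnerSpec("MLP", "DL", "mlp",
                    {"hidden": 100, "activation": "identity", "solver": "adam"}),
        LearnerSpec("DNN", "DL", "dnn", {"hidden": (64, 32)}),
        LearnerSpec("CNN", "DL", "cnn", {"filters": (16, 32, 64, 128), "kernel": 3}),
        LearnerSpec("CNN-S", "DL", "cnn_s", {"filters": (8, 16), "kernel": 3}),
        LearnerSpec("LSTM", "DL", "lstm", {"units": 60, "dropout": 0.2, "steps": 10}),
        LearnerSpec("LSTM-S", "DL", "lstm_s", {"units": 24, "dropout": 0.2, "steps": 8}),
        LearnerSpec("RNN", "DL", "rnn",
                    {"units": 64, "dropout": 0.2, "steps": 10, "activation": "identity"}),
        LearnerSpec("RNN-T", "DL", "rnn_t",
                    {"units": 32, "dropout": 0.2, "steps": 10, "activation": "tanh"}),
        LearnerSpec("ELM", "DL", "elm", {"n_hidden": 64, "activation": "identity"}),
        LearnerSpec("ELM-T", "DL", "elm_t", {"n_hidden": 64, "activation": "tanh"}),
        LearnerSpec("AE", "DL", "ae", {"hidden": 64, "code": 16}),
        LearnerSpec("DAE", "DL", "dae", {"hidden": 64, "code": 16, "noise_sd": 0.1}),
        LearnerSpec("GAN", "DL", "gan", {"gen_input": 24, "hidden": 256}),
        LearnerSpec("MARS", "DL", "mars", {"degree": 2, "max_terms": 20}),
        LearnerSpec("GMMR", "DL", "gmmr",
                    {"n_components": 3, "covariance_type": "full"}),
    ]


def default_registry() -> LearnerRegistry:
    """The 34-learner default registry (families TM=9, DL=15, LRM=10)."""
    return LearnerRegistry(tuple(_tm_specs() + _dl_specs() + _lrm_specs()))


# fast-profile overrides: smaller tree counts / fewer epochs, same model set
_FAST = {
    "RF": {"n_estimators": 40},
    "GBRT": {"n_estimators": 40},
    "AdaBoost": {"n_estimators": 25},
    "XGBoost": {"n_estimators": 40},
    "LightGBM": {"n_estimators": 40},
    "ExtraTrees": {"n_estimators": 40},
    "HGBR": {"max_iter": 60},
    "CatBoost": {"n_estimators": 40},
    "MARS": {"max_terms": 8, "n_knots": 5},
    "RVR": {"n_centers": 40},
}
_FAST_EPOCHS = 25
_FULL_EPOCHS = 120


def learner_seed(name: str, global_seed: int) -> int:
    """Stable per-learner seed below 2**31, derived from the global seed."""
    return (zlib.crc32(f"{global_seed}:{name}".encode()) ^ global_seed) % (2 ** 31)


def build_estimator(spec: LearnerSpec, fast: bool = False, seed: int = 0):
    """Instantiate the estimator behind a LearnerSpec."""
    hp = dict(spec.hyperparams)
    if fast and spec.name in _FAST:
        hp.update(_FAST[spec.name])
    epochs = _FAST_EPOCHS if fast else _FULL_EPOCHS
    b = spec.builder
    if b == "rt":
        return DecisionTreeRegressor(random_state=seed, **hp)
    if b == "rf":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **hp)
    if b == "gbrt" or b == "cat":
        return GradientBoostingRegressor(random_state=seed, **hp)
    if b == "ada":
        depth = hp.pop("base_max_depth", 4)
        return AdaBoostRegressor(
            estimator=DecisionTreeRegressor(max_depth=depth, random_state=seed),
            random_state=seed, **hp)
    if b == "xgb":
        from xgboost import XGBRegressor
        return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0, **hp)
    if b == "lgbm":
        from lightgbm import LGBMRegressor
        return LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1,
                             min_child_samples=5, **hp)
    if b == "extra":
        return ExtraTreesRegressor(random_state=seed, n_jobs=1, **hp)
    if b == "hgbr":
        return HistGradientBoostingRegressor(random_state=seed, **hp)
    if b == "svr":
        return SVR(**hp)
    if b == "plsr":
        return _PLSWrapper(**hp)
    if b == "tweedie":
        return TweedieRegressor(max_iter=2000, **hp)
    if b == "knr":
        return KNeighborsRegressor(**hp)
    if b == "ridge":
        return Ridge(**hp)
    if b == "lasso":
        return Lasso(max_iter=5000, **hp)
    if b == "enr":
        return ElasticNet(max_iter=5000, **hp)
    if b == "gam":
        alpha = hp.get("smoothing", 0.7)
        return make_pipeline(
            StandardScaler(),
            SplineTransformer(n_knots=hp.get("n_knots", 8), degree=3),
            Ridge(alpha=alpha),
        )
    if b == "ars":
        return make_pipeline(
            StandardScaler(),
            PowerExpansion(degree=hp.get("degree", 9)),
            Ridge(alpha=hp.get("alpha", 0.01)),
        )
    if b == "rvr":
        return RVRRegressor(n_centers=hp.get("n_centers", 150),
                            alpha_scale=hp.get("alpha_scale", 1.2), seed=seed)
    if b == "mlp":
        return make_pipeline(
            StandardScaler(),
            MLPRegressor(hidden_layer_sizes=(hp.get("hidden", 100),),
                         activation=hp.get("activation", "identity"),
                         solver=hp.get("solver", "adam"),
                         max_iter=100 if fast else 400, random_state=seed))
    if b == "dnn":
        return nn.NeuralRegressor(_arch_dense(hp.get("hidden", (64, 32))),
                                  epochs=epochs, seed=seed)
    if b in ("cnn", "cnn_s"):
        lr = 5e-3 if len(hp.get("filters", ())) > 2 else 2e-2
        return nn.NeuralRegressor(
            _arch_cnn(hp.get("filters"), kernel=hp.get("kernel", 3)),
            epochs=epochs, lr=lr, seed=seed)
    if b in ("lstm", "lstm_s"):
        return nn.NeuralRegressor(
            _arch_recurrent("lstm", hp["units"], hp.get("steps", 10),
                            dropout=hp.get("dropout", 0.2)),
            epochs=epochs, lr=2e-2, seed=seed)
    if b in ("rnn", "rnn_t"):
        return nn.NeuralRegressor(
            _arch_recurrent("rnn", hp["units"], hp.get("steps", 10),
                            dropout=hp.get("dropout", 0.2),
                            activation=hp.get("activation", "identity")),
            epochs=epochs, lr=1e-2, seed=seed)
    if b in ("elm", "elm_t"):
        return ELMRegressor(n_hidden=hp.get("n_hidden", 64),
                            activation=hp.get("activation", "identity"), seed=seed)
    if b in ("ae", "dae"):
        return AutoencoderRegressor(hidden=hp.get("hidden", 64),
                                    code=hp.get("code", 16),
                                    noise_sd=hp.get("noise_sd", 0.0),
                                    epochs=epochs, seed=seed)
    if b == "gan":
        return GANRegressor(gen_input=hp.get("gen_input", 24),
                            hidden=hp.get("hidden", 256), epochs=epochs, seed=seed)
    if b == "mars":
        return MARSRegressor(degree=hp.get("degree", 2),
                             max_terms=hp.get("max_terms", 20),
                             n_knots=hp.get("n_knots", 10))
    if b == "gmmr":
        return GMMRegressor(n_components=hp.get("n_components", 3),
                            covariance_type=hp.get("covariance_type", "full"),
                            seed=seed)
    if b == "dummy":  # mean-predictor stub, used in tests
        return DummyRegressor(strategy="mean")
    raise ValueError(f"unknown builder '{b}'")


class _PLSWrapper(BaseEstimator, RegressorMixin):
    """PLS regression returning 1-D predictions."""

    def __init__(self, n_components=3):
        self.n_components = n_components

    def fit(self, X, y):
        ncomp = min(self.n_components, np.asarray(X).shape[1], len(y) - 1)
        self.model_ = PLSRegression(n_components=max(1, ncomp)).fit(X, y)
        return self

    def predict(self, X):
        return self.model_.predict(X).ravel()


# ---------------------------------------------------------------------------
# grid search and cross-validated training


def fold_assignments(n: int, folds: int, seed: int) -> np.ndarray:
    """Deterministic balanced fold labels from a seeded permutation."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    perm = np.random.default_rng(seed).permutation(n)
    labels = np.empty(n, dtype=int)
    labels[perm] = np.arange(n) % folds
    return labels


def grid_search(spec: LearnerSpec, cal: SpectraSet, folds: int = 10,
                fast: bool = False, seed: int = 0) -> LearnerSpec:
    """Exhaustive grid search by mean cross-validated RMSE.

    Returns the spec with its hyperparameters replaced by the argmin
    combination; ties break to the first combination in enumeration order.
    """
    if not spec.grid:
        raise ValueError(f"learner '{spec.name}' has an empty grid")
    keys = list(spec.grid)
    X, y = cal.reflectance, cal.target
    fold_of = fold_assignments(len(y), min(folds, len(y)), seed)
    best_combo, best_rmse = None, np.inf
    for values in product(*(spec.grid[k] for k in keys)):
        combo = dict(zip(keys, values))
        trial = replace(spec, hyperparams={**spec.hyperparams, **combo}, grid={})
        rmses = []
        for f in np.unique(fold_of):
            est = build_estimator(trial, fast=fast, seed=seed)
            tr = fold_of != f
            est.fit(X[tr], y[tr])
            pred = est.predict(X[~tr])
            rmses.append(np.sqrt(np.mean((pred - y[~tr]) ** 2)))
        mean_rmse = float(np.mean(rmses))
        if mean_rmse < best_rmse - 1e-12:
            best_rmse, best_combo = mean_rmse, combo
    return replace(spec, hyperparams={**spec.hyperparams, **best_combo})


def fit_predict_all(
    registry: LearnerRegistry,
    cal: SpectraSet,
    val: SpectraSet,
    folds: int = 10,
    fast: bool = False,
    seed: int = 0,
) -> tuple[PredictionMatrix, PredictionMatrix, TrainingTrace]:
    """Train every registered learner with k-fold CV on the calibration set.

    Returns out-of-fold calibration predictions, validation predictions from
    a full-calibration refit, and a per-fold error trace.  A learner whose
    fit raises is never dropped silently: its column is filled with
    training-fold target means and the failure is recorded in the trace with
    a warning.
    """
    if not np.array_equal(cal.wavelengths, val.wavelengths):
        raise ValueError("calibration and validation sets must share the wavelength grid")
    Xc, yc = cal.reflectance, cal.target
    Xv = val.reflectance
    n = len(yc)
    fold_of = fold_assignments(n, min(folds, n), seed)
    oof = np.zeros((n, len(registry)))
    valp = np.zeros((len(Xv), len(registry)))
    records: dict = {}
    warnings.filterwarnings(
        "ignore", message="X does not have valid feature names", category=UserWarning
    )
    for col, spec in enumerate(registry):
        sd = learner_seed(spec.name, seed)
        fold_mae, fold_mse, failed = [], [], False
        for f in np.unique(fold_of):
            tr = fold_of != f
            try:
                est = build_estimator(spec, fast=fast, seed=sd)
                est.fit(Xc[tr], yc[tr])
                pred = np.asarray(est.predict(Xc[~tr]), dtype=float).ravel()
                if not np.isfinite(pred).all():
                    raise FloatingPointError("non-finite predictions")
            except Exception as exc:  # noqa: BLE001 - contract: never drop a learner
                failed = True
                warnings.warn(f"learner '{spec.name}' failed on fold {f}: {exc}")
                pred = np.full((~tr).sum(), yc[tr].mean())
            oof[~tr, col] = pred
            fold_mae.append(float(np.mean(np.abs(pred - yc[~tr]))))
            fold_mse.append(float(np.mean((pred - yc[~tr]) ** 2)))
        try:
            est = build_estimator(spec, fast=fast, seed=sd)
            est.fit(Xc, yc)
            vp = np.asarray(est.predict(Xv), dtype=float).ravel()
            if not np.isfinite(vp).all():
                raise FloatingPointError("non-finite predictions")
        except Exception as exc:  # noqa: BLE001
            failed = True
            warnings.warn(f"learner '{spec.name}' failed on the full refit: {exc}")
            vp = np.full(len(Xv), yc.mean())
        valp[:, col] = vp
        records[spec.name] = {
            "fold_mae": fold_mae,
            "fold_mse": fold_mse,
            "failed": failed,
        }
    names = registry.names()
    return (
        PredictionMatrix(oof, names, np.arange(n)),
        PredictionMatrix(valp, names, np.arange(len(Xv))),
        TrainingTrace(records=records, fold_of=fold_of),
    )
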