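"""Minimal dense/convolutional/recurrent regressors in numpy.

The neural members of the learner registry are small networks trained by
full-batch Adam on mean-squared error.  Layers implement explicit forward
and backward passes; a finite-difference gradient check in the test suite
guards the hand-written derivatives.

Conventions: dense layers operate on (n, features); convolutional and
recurrent layers on (n, steps, channels).  Activations default to identity
("linear"), matching the registry's printed architecture text; ReLU and tanh
are available as options.  Recurrent layers read a spectrum as a short
sequence of contiguous wavelength chunks (see :class:`ToSequence`).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dense", "Activation", "Dropout", "Conv1D", "AvgPool1D", "Flatten",
    "ToSequence", "SimpleRNN", "LSTM", "Sequential", "NeuralRegressor",
]


def _act(name):
    if name in (None, "identity", "linear"):
        return lambda x: x, lambda x, y: np.ones_like(x)
    if name == "relu":
        return lambda x: np.maximum(x, 0), lambda x, y: (x > 0).astype(x.dtype)
    if name == "tanh":
        return np.tanh, lambda x, y: 1 - y ** 2
    raise ValueError(f"unknown activation '{name}'")


def _sigmoid(x):
    return 0.5 * (1 + np.tanh(0.5 * x))


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, in_dim, out_dim, rng, scale=None):
        super().__init__()
        scale = scale or np.sqrt(1.0 / in_dim)
        self.W = rng.normal(0, scale, (in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self.x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self.x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class Activation(Layer):
    def __init__(self, name="identity"):
        super().__init__()
        self.f, self.df = _act(name)

    def forward(self, x, train):
        self.x = x
        self.y = self.f(x)
        return self.y

    def backward(self, grad):
        return grad * self.df(self.x, self.y)


class Dropout(Layer):
    """Inverted dropout; identity at prediction time."""

    def __init__(self, rate, rng):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate <= 0:
            self.mask = None
            return x
        self.mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self.mask

    def backward(self, grad):
        return grad if self.mask is None else grad * self.mask


class ToSequence(Layer):
    """Reshape (n, f) features into (n, steps, f // steps) chunks."""

    def __init__(self, steps):
        super().__init__()
        self.steps = steps

    def forward(self, x, train):
        n, f = x.shape
        ch = f // self.steps
        self.in_shape = x.shape
        self.used = self.steps * ch
        return x[:, : self.used].reshape(n, self.steps, ch)

    def backward(self, grad):
        out = np.zeros(self.in_shape)
        out[:, : self.used] = grad.reshape(grad.shape[0], -1)
        return out


class Conv1D(Layer):
    """Valid-mode 1-D convolution (cross-correlation), stride 1."""

    def __init__(self, in_channels, filters, kernel_size, rng):
        super().__init__()
        scale = np.sqrt(1.0 / (in_channels * kernel_size))
        self.W = rng.normal(0, scale, (kernel_size, in_channels, filters))
        self.b = np.zeros(filters)
        self.k = kernel_size
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self.x = x
        windows = sliding_window_view(x, self.k, axis=1)  # (n, Lout, C, k)
        self.windows = windows
        out = np.tensordot(windows, self.W, axes=([3, 2], [0, 1])) + self.b
        return out

    def backward(self, grad):
        # grad: (n, Lout, F)
        self.grads[0][...] = np.transpose(
            np.tensordot(grad, self.windows, axes=([0, 1], [0, 1])), (2, 1, 0)
        )
        self.grads[1][...] = grad.sum(axis=(0, 1))
        dx = np.zeros_like(self.x)
        L_out = grad.shape[1]
        for i in range(self.k):
            dx[:, i : i + L_out, :] += grad @ self.W[i].T
        return dx


class AvgPool1D(Layer):
    def __init__(self, size=2):
        super().__init__()
        self.size = size

    def forward(self, x, train):
        n, L, c = x.shape
        self.in_L = L
        L2 = L // self.size
        self.L2 = L2
        return x[:, : L2 * self.size, :].reshape(n, L2, self.size, c).mean(axis=2)

    def backward(self, grad):
        n, L2, c = grad.shape
        out = np.zeros((n, self.in_L, c))
        out[:, : L2 * self.size, :] = np.repeat(grad / self.size, self.size, axis=1)
        return out


class Flatten(Layer):
    def forward(self, x, train):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self.shape)


class SimpleRNN(Layer):
    """Elman recurrence with configurable cell activation; returns the last state."""

    def __init__(self, in_dim, units, rng, activation="identity", backwards=False):
        super().__init__()
        self.f, self.df = _act(activation)
        self.Wx = rng.normal(0, np.sqrt(1.0 / in_dim), (in_dim, units))
        self.Wh = rng.normal(0, np.sqrt(0.5 / units), (units, units))
        self.b = np.zeros(units)
        self.units = units
        self.backwards = backwards
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train):
        if self.backwards:
            x = x[:, ::-1, :]
        self.x = x
        n, T, _ = x.shape
        h = np.zeros((n, self.units))
        self.pre, self.hs = [], [h]
        for t in range(T):
            z = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            h = self.f(z)
            self.pre.append(z)
            self.hs.append(h)
        return h

    def backward(self, grad):
        n, T, _ = self.x.shape
        for g in self.grads:
            g[...] = 0.0
        dx = np.zeros_like(self.x)
        dh = grad
        for t in range(T - 1, -1, -1):
            dz = dh * self.df(self.pre[t], self.hs[t + 1])
            self.grads[0] += self.x[:, t, :].T @ dz
            self.grads[1] += self.hs[t].T @ dz
            self.grads[2] += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
        return dx[:, ::-1, :] if self.backwards else dx


class LSTM(Layer):
    """LSTM returning the last hidden state.

    Gates use sigmoid; the cell candidate and cell output use an identity
    activation (the "linear" reading of the architecture text) — gate
    nonlinearities are retained because a gateless LSTM degenerates.
    """

    def __init__(self, in_dim, units, rng):
        super().__init__()
        d = in_dim + units
        scale = np.sqrt(1.0 / d)
        self.W = rng.normal(0, scale, (d, 4 * units))  # [i, f, o, g]
        self.b = np.zeros(4 * units)
        self.b[units: 2 * units] = 1.0  # forget-gate bias
        self.units = units
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self.x = x
        n, T, _ = x.shape
        u = self.units
        h = np.zeros((n, u))
        c = np.zeros((n, u))
        self.cache = []
        for t in range(T):
            z = np.concatenate([x[:, t, :], h], axis=1)
            gates = z @ self.W + self.b
            i = _sigmoid(gates[:, :u])
            f = _sigmoid(gates[:, u: 2 * u])
            o = _sigmoid(gates[:, 2 * u: 3 * u])
            g = gates[:, 3 * u:]  # identity candidate
            c_prev = c
            c = f * c_prev + i * g
            h = o * c  # identity cell output
            self.cache.append((z, i, f, o, g, c_prev, c))
        return h

    def backward(self, grad):
        n, T, in_dim = self.x.shape
        u = self.units
        for gr in self.grads:
            gr[...] = 0.0
        dx = np.zeros_like(self.x)
        dh, dc = grad, np.zeros((n, u))
        for t in range(T - 1, -1, -1):
            z, i, f, o, g, c_prev, c = self.cache[t]
            do = dh * c
            dc = dc + dh * o
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc = dc * f
            dgates = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o), dg], axis=1
            )
            self.grads[0] += z.T @ dgates
            self.grads[1] += dgates.sum(axis=0)
            dz = dgates @ self.W.T
            dx[:, t, :] = dz[:, :in_dim]
            dh = dz[:, in_dim:]
        return dx


class Sequential:
    """A feed-forward stack trained with full-batch Adam on MSE."""

    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(zip(layer.params, layer.grads))
        return out

    def fit(self, X, y, epochs=60, lr=1e-2, beta1=0.9, beta2=0.999, eps=1e-8,
            loss_grad=None):
        y = np.asarray(y, float).reshape(-1, 1)
        pairs = self.parameters()
        m = [np.zeros_like(p) for p, _ in pairs]
        v = [np.zeros_like(p) for p, _ in pairs]
        losses = []
        for t in range(1, epochs + 1):
            pred = self.forward(X, train=True)
            if loss_grad is None:
                diff = pred - y
                losses.append(float(np.mean(diff ** 2)))
                grad = 2.0 * diff / len(y)
            else:
                loss_val, grad = loss_grad(pred, y)
                losses.append(float(loss_val))
            self.backward(grad)
            for idx, (p, g) in enumerate(pairs):
                m[idx] = beta1 * m[idx] + (1 - beta1) * g
                v[idx] = beta2 * v[idx] + (1 - beta2) * g ** 2
                mhat = m[idx] / (1 - beta1 ** t)
                vhat = v[idx] / (1 - beta2 ** t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
        self.loss_curve_ = np.array(losses)
        return self

    def predict(self, X):
        return self.forward(X, train=False).ravel()


class NeuralRegressor:
    """sklearn-style wrapper: standardises X and y, builds a net, trains Adam.

    ``architecture`` is a callable (in_dim, rng) -> list[Layer].
    """

    def __init__(self, architecture, epochs=60, lr=1e-2, seed=0):
        self.architecture = architecture
        self.epochs = epochs
        self.lr = lr
        self.seed = seed

    def get_params(self, deep=False):
        return {"architecture": self.architecture, "epochs": self.epochs,
                "lr": self.lr, "seed": self.seed}

    def set_params(self, **kw):
        for k, val in kw.items():
            setattr(self, k, val)
        return self

    def _standardise(self, X):
        return (X - self.x_mean_) / self.x_sd_

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        self.x_mean_ = X.mean(axis=0)
        self.x_sd_ = X.std(axis=0)
        self.x_sd_[self.x_sd_ == 0] = 1.0
        self.y_mean_ = y.mean()
        self.y_sd_ = y.std() or 1.0
        rng = np.random.default_rng(self.seed)
        self.net_ = Sequential(self.architecture(X.shape[1], rng))
        self.net_.fit(self._standardise(X), (y - self.y_mean_) / self.y_sd_,
                      epochs=self.epochs, lr=self.lr)
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        return self.net_.predict(self._standardise(X)) * self.y_sd_ + self.y_mean_
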