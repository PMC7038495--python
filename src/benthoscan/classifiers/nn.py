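"""Minimal feed-forward neural networks over 1-D feature vectors.

Implements exactly what the classifier registry needs, in numpy/float32:
dense and 1-D convolutional layers, ReLU/tanh activations, max-pooling,
inverted dropout, a softmax head with categorical cross-entropy, and the
SGD, RMSProp and Adadelta optimizers.  All randomness (weight init, batch
shuffling, dropout masks) is drawn from a single ``numpy.random.Generator``
seeded at construction, so training is bit-reproducible.

Convolutions are "valid" (no padding), stride 1, and are evaluated as a
single matrix product over an im2col view, which keeps training on a few
hundred 532-long vectors to seconds per epoch on one CPU core.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Network", "Dense", "Conv1D", "MaxPool1D", "ReLU", "Tanh",
           "Dropout", "Flatten", "make_optimizer"]

_DT = np.float32


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(_DT)
        self.b = np.zeros(n_out, dtype=_DT)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


class Conv1D(Layer):
    """Valid 1-D convolution; input (N, L, C_in) -> (N, L-k+1, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in, fan_out = c_in * kernel, c_out * kernel
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, size=(c_in * kernel, c_out)).astype(_DT)
        self.b = np.zeros(c_out, dtype=_DT)
        self.k = kernel
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x):
        # (N, L, C) -> (N, L', C*k) with column order (tap, channel)
        win = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)
        # win: (N, L', C, k) -> (N, L', k, C) -> flatten
        win = np.ascontiguousarray(win.transpose(0, 1, 3, 2))
        return win.reshape(x.shape[0], -1, self.k * x.shape[2])

    def forward(self, x, train, rng):
        self._x_shape = x.shape
        self._col = self._im2col(x)
        return self._col @ self.W + self.b

    def backward(self, g):
        N, Lp, _ = g.shape
        col2 = self._col.reshape(-1, self._col.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        self.grads[0][...] = col2.T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        gcol = (g2 @ self.W.T).reshape(N, Lp, self.k, self._x_shape[2])
        gx = np.zeros(self._x_shape, dtype=_DT)
        for t in range(self.k):
            gx[:, t:t + Lp, :] += gcol[:, :, t, :]
        return gx


class MaxPool1D(Layer):
    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x, train, rng):
        N, L, C = x.shape
        Lp = L // self.size
        xt = x[:, :Lp * self.size, :].reshape(N, Lp, self.size, C)
        self._arg = xt.argmax(axis=2)
        self._in_shape = x.shape
        return xt.max(axis=2)

    def backward(self, g):
        N, Lp, C = g.shape
        gx = np.zeros(self._in_shape, dtype=_DT)
        gt = np.zeros((N, Lp, self.size, C), dtype=_DT)
        n_idx, l_idx, c_idx = np.ogrid[:N, :Lp, :C]
        gt[n_idx, l_idx, self._arg, c_idx] = g
        gx[:, :Lp * self.size, :] = gt.reshape(N, Lp * self.size, C)
        return gx


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Tanh(Layer):
    def forward(self, x, train, rng):
        self._y = np.tanh(x)
        return self._y

    def backward(self, g):
        return g * (1.0 - self._y * self._y)


class Dropout(Layer):
    def __init__(self, rate: float = 0.5) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(_DT) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _SGD:
    def __init__(self, params, lr=0.01):
        self.params, self.lr = params, lr

    def step(self, grads):
        for p, g in zip(self.params, grads):
            p -= self.lr * g


class _RMSProp:
    def __init__(self, params, lr=0.001, rho=0.9, eps=1e-7):
        self.params, self.lr, self.rho, self.eps = params, lr, rho, eps
        self.ms = [np.zeros_like(p) for p in params]

    def step(self, grads):
        for p, m, g in zip(self.params, self.ms, grads):
            m *= self.rho
            m += (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(m) + self.eps)


class _Adadelta:
    def __init__(self, params, lr=1.0, rho=0.95, eps=1e-6):
        self.params, self.lr, self.rho, self.eps = params, lr, rho, eps
        self.ms = [np.zeros_like(p) for p in params]
        self.us = [np.zeros_like(p) for p in params]

    def step(self, grads):
        for p, m, u, g in zip(self.params, self.ms, self.us, grads):
            m *= self.rho
            m += (1 - self.rho) * g * g
            delta = np.sqrt(u + self.eps) / np.sqrt(m + self.eps) * g
            u *= self.rho
            u += (1 - self.rho) * delta * delta
            p -= self.lr * delta


_OPTIMIZERS = {"sgd": _SGD, "rmsprop": _RMSProp, "adadelta": _Adadelta}


def make_optimizer(name: str, params: list[np.ndarray]):
    if name not in _OPTIMIZERS:
        raise ValueError(f"unknown optimizer {name!r}")
    return _OPTIMIZERS[name](params)


class Network:
    """A layer stack with a softmax head trained by cross-entropy."""

    def __init__(self, layers: list[Layer], seed: int = 0) -> None:
        self.layers = layers
        self.rng = np.random.default_rng(seed)

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, self.rng)
        return x

    def fit(
        self,
        X: np.ndarray,
        y_index: np.ndarray,
        n_classes: int,
        epochs: int,
        batch_size: int,
        optimizer: str,
    ) -> list[float]:
        """Train; returns the mean cross-entropy per epoch."""
        X = np.asarray(X, dtype=_DT)
        y_index = np.asarray(y_index)
        params = [p for layer in self.layers for p in layer.params]
        grads = [g for layer in self.layers for g in layer.grads]
        opt = make_optimizer(optimizer, params)
        n = len(X)
        history: list[float] = []
        for _ in range(epochs):
            order = self.rng.permutation(n)
            total_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                xb, yb = X[idx], y_index[idx]
                logits = self._forward(xb, train=True)
                probs = _softmax(logits)
                total_loss += -np.log(
                    np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)
                ).sum()
                g = probs
                g[np.arange(len(yb)), yb] -= 1.0
                g = (g / len(yb)).astype(_DT)
                for layer in reversed(self.layers):
                    g = layer.backward(g)
                opt.step(grads)
            history.append(total_loss / n)
        return history

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=_DT)
        if len(X) == 0:
            out_dim = self.layers[-1].params[1].shape[0] if self.layers[-1].params else 0
            return np.zeros((0, out_dim))
        return _softmax(self._forward(X, train=False)).astype(np.float64)
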