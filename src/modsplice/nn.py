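"""Minimal feed-forward neural network layers on numpy.

Just enough machinery for the sequence-scoring modules: dense and 1-D
convolution layers, batch normalization, dropout, global average
pooling, Adam, and binary cross-entropy on logits (which also accepts
fractional targets, as needed for PSI regression). Everything is
float64 and deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def state(self) -> list[np.ndarray]:
        """Non-trainable arrays that must survive serialization."""
        return []

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        if n_in <= 0 or n_out <= 0:
            raise ValueError("layer sizes must be positive")
        # He initialization, suited to the ReLU activations used throughout
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dropout(Layer):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class BatchNorm(Layer):
    """Normalizes over all axes but the last (features / channels)."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.dgamma = np.zeros(n_features)
        self.dbeta = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def state(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, train=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._m = int(np.prod([x.shape[a] for a in axes])) if axes else 1
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train = train
        return self.gamma * self._xhat + self.beta

    def backward(self, g):
        axes = self._axes
        self.dgamma[...] = (g * self._xhat).sum(axis=axes)
        self.dbeta[...] = g.sum(axis=axes)
        if not self._train:
            return g * self.gamma / self._std
        m = self._m
        gx = g * self.gamma
        return (
            gx - gx.mean(axis=axes) - self._xhat * (gx * self._xhat).mean(axis=axes)
        ) / self._std


class Conv1D(Layer):
    """1-D convolution over (batch, length, channels) input."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        width: int,
        padding: str,
        rng: np.random.Generator,
    ):
        if c_in <= 0 or c_out <= 0 or width <= 0:
            raise ValueError("layer sizes must be positive")
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        self.c_in, self.c_out, self.width, self.padding = c_in, c_out, width, padding
        self.W = rng.normal(0.0, np.sqrt(2.0 / (width * c_in)), size=(width * c_in, c_out))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _pad(self, x):
        if self.padding == "same":
            left = (self.width - 1) // 2
            right = self.width // 2
            return np.pad(x, ((0, 0), (left, right), (0, 0))), left
        return x, 0

    def forward(self, x, train=False, rng=None):
        xp, self._left = self._pad(x)
        self._in_len = x.shape[1]
        if xp.shape[1] < self.width:
            raise ValueError(
                f"input length {x.shape[1]} shorter than filter width {self.width}"
            )
        windows = np.lib.stride_tricks.sliding_window_view(xp, self.width, axis=1)
        # windows: (B, L_out, C, width) -> columns (B*L_out, width*C)
        cols = windows.transpose(0, 1, 3, 2).reshape(-1, self.width * self.c_in)
        self._cols = cols
        self._b = x.shape[0]
        out = cols @ self.W + self.b
        self._l_out = out.shape[0] // x.shape[0]
        return out.reshape(x.shape[0], self._l_out, self.c_out)

    def backward(self, g):
        gf = g.reshape(-1, self.c_out)
        self.dW[...] = self._cols.T @ gf
        self.db[...] = gf.sum(axis=0)
        gcols = (gf @ self.W.T).reshape(self._b, self._l_out, self.width, self.c_in)
        pad_len = self._in_len + (self.width - 1 if self.padding == "same" else 0)
        gx = np.zeros((self._b, pad_len, self.c_in))
        for k in range(self.width):
            gx[:, k:k + self._l_out, :] += gcols[:, :, k, :]
        if self._left:
            gx = gx[:, self._left:self._left + self._in_len, :]
        return gx


class GlobalAvgPool(Layer):
    """(batch, length, channels) -> (batch, channels); length-free."""

    def forward(self, x, train=False, rng=None):
        self._l = x.shape[1]
        return x.mean(axis=1)

    def backward(self, g):
        return np.repeat(g[:, None, :] / self._l, self._l, axis=1)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def grads(self):
        return [g for lay in self.layers for g in lay.grads()]

    def state(self):
        return [s for lay in self.layers for s in lay.state()]

    def forward(self, x, train=False, rng=None):
        for lay in self.layers:
            x = lay.forward(x, train=train, rng=rng)
        return x

    def backward(self, g):
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None
        self._t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits and its gradient wrt ``z``.

    Targets may be fractional (PSI values in [0, 1]); the loss is then
    the same cross-entropy form evaluated at the fractional target.
    """
    z = z.reshape(-1)
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    if z.shape != y.shape:
        raise ValueError("logit/target shape mismatch")
    if np.any(np.isnan(z)):
        raise FloatingPointError("NaN logits: training diverged")
    # stable: max(z,0) - z*y + log(1 + exp(-|z|))
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad


def snapshot(arrays: list[np.ndarray]) -> list[np.ndarray]:
    return [a.copy() for a in arrays]


def restore(arrays: list[np.ndarray], saved: list[np.ndarray]) -> None:
    for a, s in zip(arrays, saved):
        a[...] = s
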