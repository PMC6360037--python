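"""Small numpy neural-network core: dense/LSTM layers, Adam, backprop.

Implements exactly what the classifiers in :mod:`gaitdx.models` need —
fully connected stacks with ReLU and inverted dropout, a single LSTM layer
read out at its final hidden state, softmax outputs, and the Adam
optimizer.  All computation is float64 and fully deterministic given a
seeded :class:`numpy.random.Generator`, which makes training runs
reproducible bit-for-bit at the loss-trace level.

Gradient correctness is covered by numerical finite-difference checks in
the test suite.
"""

from __future__ import annotations

import numpy as np


class Dense:
    """Affine layer ``y = x W + b`` with He-scaled initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask

    def params(self):
        return []


class Dropout:
    """Inverted dropout: active only during training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    def params(self):
        return []


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class LSTM:
    """Single LSTM layer consuming (batch, time, features), returning the
    final hidden state.

    Gate order in the fused weight matrices is (input, forget, cell, output);
    gate activations are sigmoids, cell and hidden activations are tanh.
    The forget-gate bias starts at 1 (standard remember-by-default init).
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(n_hidden)
        self.Wx = rng.uniform(-k, k, size=(n_in, 4 * n_hidden))
        self.Wh = rng.uniform(-k, k, size=(n_hidden, 4 * n_hidden))
        self.b = np.zeros(4 * n_hidden)
        self.b[n_hidden : 2 * n_hidden] = 1.0
        self.n_hidden = n_hidden
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x, training=False):
        B, T, D = x.shape
        H = self.n_hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        gates, cells, hiddens = [], [], []
        for t in range(T):
            z = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c = f * c + i * g
            h = o * np.tanh(c)
            gates.append((i, f, g, o))
            cells.append(c)
            hiddens.append(h)
        self._cache = (x, gates, cells, hiddens)
        return h

    def backward(self, dh_last):
        x, gates, cells, hiddens = self._cache
        B, T, D = x.shape
        H = self.n_hidden
        self.dWx.fill(0.0)
        self.dWh.fill(0.0)
        self.db.fill(0.0)
        dx = np.empty_like(x)
        dh = dh_last.copy()
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o = gates[t]
            c = cells[t]
            c_prev = cells[t - 1] if t > 0 else np.zeros((B, H))
            h_prev = hiddens[t - 1] if t > 0 else np.zeros((B, H))
            tc = np.tanh(c)
            dc = dc + dh * o * (1.0 - tc * tc)
            dz = np.concatenate(
                [
                    dc * g * i * (1.0 - i),
                    dc * c_prev * f * (1.0 - f),
                    dc * i * (1.0 - g * g),
                    dh * tc * o * (1.0 - o),
                ],
                axis=1,
            )
            self.dWx += x[:, t, :].T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        return dx

    def params(self):
        return [(self.Wx, self.dWx), (self.Wh, self.dWh), (self.b, self.db)]


class Sequential:
    """A feed-forward stack of layers sharing the forward/backward protocol."""

    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params())


class Adam:
    """Adam at its canonical defaults (lr 1e-3, betas 0.9/0.999, eps 1e-8)."""

    def __init__(self, model, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in model.params()]
        self.v = [np.zeros_like(p) for p, _ in model.params()]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        # params() is re-queried so freshly assigned gradient arrays are seen
        for k, (p, g) in enumerate(self.model.params()):
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
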