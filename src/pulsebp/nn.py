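"""Minimal NumPy sequence-regression layers with backpropagation.

Implements exactly what the blood-pressure regressors need: an LSTM
layer, a bidirectional LSTM whose forward and backward outputs are
summed (so its output width equals the hidden width and identity
residual shortcuts are well-defined downstream), a parameter-free
residual wrapper Y = F(x) + x, inverted dropout, a time-distributed
dense layer, ReLU, and an Adam optimizer with a step-decay learning
rate.  Shapes are ``(batch, time, channels)`` throughout.

Weight layout of an LSTM layer follows the common (i, f, g, o) gate
order with Glorot-uniform input/recurrent kernels and a forget-gate
bias of 1.  All initialization is driven by an explicit
``numpy.random.Generator`` so builds are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "LSTM",
    "BiLSTM",
    "Residual",
    "Dropout",
    "ReLU",
    "Sequential",
    "Adam",
    "mse_loss",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base layer: parameter/gradient registry plus forward/backward."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())


class Dense(Layer):
    """Time-distributed affine map: y[t] = x[t] W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = _glorot(rng, n_in, n_out)
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        x = self._x
        self.dw[...] = np.tensordot(x, dy, axes=([0, 1], [0, 1]))
        self.db[...] = dy.sum(axis=(0, 1))
        return dy @ self.w.T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class LSTM(Layer):
    """Single unidirectional LSTM layer returning the full output sequence.

    Stateless across calls by default; an explicit initial state can be
    supplied for streaming use.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_in, self.n_hidden = n_in, n_hidden
        self.wx = _glorot(rng, n_in, 4 * n_hidden)
        self.wh = _glorot(rng, n_hidden, 4 * n_hidden)
        self.b = np.zeros(4 * n_hidden)
        self.b[n_hidden : 2 * n_hidden] = 1.0  # forget-gate bias
        self.dwx = np.zeros_like(self.wx)
        self.dwh = np.zeros_like(self.wh)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [self.wx, self.wh, self.b]

    def grads(self):
        return [self.dwx, self.dwh, self.db]

    def forward(self, x, train=False, h0=None, c0=None):
        batch, steps, _ = x.shape
        d = self.n_hidden
        h = np.zeros((batch, d)) if h0 is None else h0
        c = np.zeros((batch, d)) if c0 is None else c0
        hs = np.empty((batch, steps, d))
        cache = []
        for t in range(steps):
            z = x[:, t] @ self.wx + h @ self.wh + self.b
            i = _sigmoid(z[:, :d])
            f = _sigmoid(z[:, d : 2 * d])
            g = np.tanh(z[:, 2 * d : 3 * d])
            o = _sigmoid(z[:, 3 * d :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((x[:, t], h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            hs[:, t] = h
        self._cache = cache
        self.final_state = (h, c)
        return hs

    def backward(self, dy):
        cache = self._cache
        batch, steps, _ = dy.shape
        d = self.n_hidden
        self.dwx[...] = 0
        self.dwh[...] = 0
        self.db[...] = 0
        dx = np.empty((batch, steps, self.n_in))
        dh_next = np.zeros((batch, d))
        dc_next = np.zeros((batch, d))
        for t in range(steps - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = cache[t]
            dh = dy[:, t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.dwx += x_t.T @ dz
            self.dwh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t] = dz @ self.wx.T
            dh_next = dz @ self.wh.T
            dc_next = dc * f
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM; forward and backward outputs are summed.

    Summing (rather than concatenating) keeps the output width equal to
    the hidden width, so the stacked layers above can carry identity
    residual shortcuts without projection parameters.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.fwd = LSTM(n_in, n_hidden, rng)
        self.bwd = LSTM(n_in, n_hidden, rng)

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def grads(self):
        return self.fwd.grads() + self.bwd.grads()

    def forward(self, x, train=False):
        hf = self.fwd.forward(x, train)
        hb = self.bwd.forward(x[:, ::-1], train)[:, ::-1]
        return hf + hb

    def backward(self, dy):
        dx_f = self.fwd.backward(dy)
        dx_b = self.bwd.backward(dy[:, ::-1])[:, ::-1]
        return dx_f + dx_b


class Residual(Layer):
    """Identity shortcut around an inner layer: y = F(x) + x (parameter-free)."""

    def __init__(self, inner: Layer):
        self.inner = inner

    def params(self):
        return self.inner.params()

    def grads(self):
        return self.inner.grads()

    def forward(self, x, train=False):
        return self.inner.forward(x, train) + x

    def backward(self, dy):
        return self.inner.backward(dy) + dy


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements; returns (loss, dpred)."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / diff.size


class Adam:
    """Adam with a step-decay schedule: lr = lr0 * factor**(k // period)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 3e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        lr_drop_factor: float = 1.0,
        lr_drop_period: int | None = None,
    ):
        self.params = params
        self.lr0 = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.lr_drop_factor = lr_drop_factor
        self.lr_drop_period = lr_drop_period
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def current_lr(self, decay_steps: int | None = None) -> float:
        """Learning rate after ``decay_steps`` schedule units (default: t)."""
        if self.lr_drop_period is None:
            return self.lr0
        k = self.t if decay_steps is None else decay_steps
        return self.lr0 * self.lr_drop_factor ** (k // self.lr_drop_period)

    def step(self, grads: list[np.ndarray], decay_steps: int | None = None) -> None:
        self.t += 1
        lr = self.current_lr(decay_steps if decay_steps is not None else self.t - 1)
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= lr * m_hat / (np.sqrt(v_hat) + self.eps)
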