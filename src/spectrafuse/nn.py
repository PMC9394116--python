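"""Minimal NumPy neural-network engine for 1-D spectral classifiers.

Implements exactly the pieces the classifiers here need — dense and 1-D
convolution layers (im2col), max pooling, batch normalization, ReLU, a
multiplicative ReLU attention gate, softmax cross-entropy and plain SGD —
with explicit forward/backward passes and float32 arithmetic.  Layers
cache their forward activations, so a ``backward`` call must follow the
matching ``forward(training=True)``.

All randomness (initialization, shuffling) flows through explicitly
passed ``numpy.random.Generator`` objects, which makes every model run
reproducible from a single integer seed.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Parameter:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """Fan-in-scaled normal initialization (suits ReLU nonlinearities)."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Parameter(he_normal(rng, (n_in, n_out), n_in))
        self.b = Parameter(np.zeros(n_out))
        self._x = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self._x = x if training else None
        return x @ self.W.value + self.b.value

    def backward(self, g):
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training):
        out = np.maximum(x, 0.0)
        self._mask = x > 0 if training else None
        return out

    def backward(self, g):
        return g * self._mask


class Reshape1d(Layer):
    """(N, L) -> (N, 1, L): present a flat vector as a 1-channel signal."""

    def forward(self, x, training):
        return x[:, None, :]

    def backward(self, g):
        return g[:, 0, :]


class Flatten(Layer):
    """(N, C, L) -> (N, C*L)."""

    def __init__(self):
        self._shape = None

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Conv1d(Layer):
    """Same-length 1-D convolution (zero padding), arbitrary odd kernel."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator,
                 stride: int = 1):
        if stride != 1:
            raise NotImplementedError("only stride 1 is supported")
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same-length padding")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel_size
        fan_in = c_in * kernel_size
        self.W = Parameter(he_normal(rng, (fan_in, c_out), fan_in))
        self.b = Parameter(np.zeros(c_out))
        self._cols = None
        self._in_shape = None

    def parameters(self):
        return [self.W, self.b]

    def _im2col(self, x):
        # x: (N, C, L) -> (N*L, C*k) with zero padding of k//2 per side
        n, c, length = x.shape
        p = self.k // 2
        xp = np.zeros((n, c, length + 2 * p), dtype=x.dtype)
        xp[:, :, p : p + length] = x
        # windows: (N, C, k, L)
        cols = np.stack([xp[:, :, j : j + length] for j in range(self.k)], axis=2)
        return cols.transpose(0, 3, 1, 2).reshape(n * length, c * self.k)

    def forward(self, x, training):
        n, c, length = x.shape
        cols = self._im2col(x)
        out = cols @ self.W.value + self.b.value
        if training:
            self._cols, self._in_shape = cols, x.shape
        else:
            self._cols = None
        return out.reshape(n, length, self.c_out).transpose(0, 2, 1)

    def backward(self, g):
        n, _, length = self._in_shape
        g2 = g.transpose(0, 2, 1).reshape(n * length, self.c_out)
        self.W.grad += self._cols.T @ g2
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.W.value.T).reshape(n, length, self.c_in, self.k)
        p = self.k // 2
        dxp = np.zeros((n, self.c_in, length + 2 * p), dtype=g.dtype)
        for j in range(self.k):
            dxp[:, :, j : j + length] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, p : p + length]


class MaxPool1d(Layer):
    """Non-overlapping max pooling (pool size = stride); trailing remainder dropped."""

    def __init__(self, size: int = 2):
        self.size = size
        self._argmax = None
        self._in_shape = None

    def forward(self, x, training):
        n, c, length = x.shape
        lp = length // self.size
        xt = x[:, :, : lp * self.size].reshape(n, c, lp, self.size)
        if training:
            self._argmax = xt.argmax(axis=3)
            self._in_shape = x.shape
        return xt.max(axis=3)

    def backward(self, g):
        n, c, length = self._in_shape
        lp = length // self.size
        dxt = np.zeros((n, c, lp, self.size), dtype=g.dtype)
        np.put_along_axis(dxt, self._argmax[..., None], g[..., None], axis=3)
        dx = np.zeros((n, c, length), dtype=g.dtype)
        dx[:, :, : lp * self.size] = dxt.reshape(n, c, lp * self.size)
        return dx

    @staticmethod
    def out_length(length: int, size: int = 2) -> int:
        return length // size


class BatchNorm(Layer):
    """Batch normalization over the batch (and, for conv inputs, length) axes.

    Training mode normalizes with batch statistics and updates exponential
    running averages; inference mode uses the running averages.
    """

    def __init__(self, n_features: int, conv: bool, momentum: float = 0.9, eps: float = 1e-5):
        shape = (1, n_features, 1) if conv else (1, n_features)
        self.axes = (0, 2) if conv else (0,)
        self.gamma = Parameter(np.ones(shape))
        self.beta = Parameter(np.zeros(shape))
        self.running_mean = np.zeros(shape, dtype=DTYPE)
        self.running_var = np.ones(shape, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None
        self._calibrating = False
        self._acc = None

    def parameters(self):
        return [self.gamma, self.beta]

    def begin_calibration(self):
        """Start exact re-estimation of the running statistics.

        Between ``begin_calibration`` and ``end_calibration``, training-mode
        forwards accumulate population moments instead of updating the
        exponential averages; ``end_calibration`` replaces the running
        statistics with the accumulated population mean and variance.
        Useful when parameters move faster than the exponential averages
        can track (few batches per epoch).
        """
        self._calibrating = True
        self._acc = [0.0, np.zeros_like(self.running_mean, dtype=np.float64),
                     np.zeros_like(self.running_mean, dtype=np.float64)]

    def end_calibration(self):
        n, s, ss = self._acc
        if n > 0:
            mean = s / n
            var = ss / n - mean**2
            self.running_mean = mean.astype(DTYPE)
            self.running_var = np.maximum(var, 0.0).astype(DTYPE)
        self._calibrating = False
        self._acc = None

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=self.axes, keepdims=True)
            var = x.var(axis=self.axes, keepdims=True)
            if self._calibrating:
                m_elems = int(np.prod([x.shape[a] for a in self.axes]))
                self._acc[0] += m_elems
                self._acc[1] += x.sum(axis=self.axes, keepdims=True)
                self._acc[2] += (x.astype(np.float64) ** 2).sum(axis=self.axes, keepdims=True)
            else:
                m = self.momentum
                self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(DTYPE)
                self.running_var = (m * self.running_var + (1 - m) * var).astype(DTYPE)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            self._cache = (xhat, inv_std)
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv_std
        return self.gamma.value * xhat + self.beta.value

    def backward(self, g):
        xhat, inv_std = self._cache
        m = np.prod([xhat.shape[a] for a in self.axes])
        self.gamma.grad += (g * xhat).sum(axis=self.axes, keepdims=True)
        self.beta.grad += g.sum(axis=self.axes, keepdims=True)
        dxhat = g * self.gamma.value
        # closed-form batch-norm gradient
        term = (
            dxhat
            - dxhat.mean(axis=self.axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=self.axes, keepdims=True)
        )
        return (term * inv_std).astype(g.dtype)


class AttentionGate(Layer):
    """Multiplicative ReLU gate: out = ReLU(W1 @ ReLU(W2 @ x + b1) + b2) * x.

    W2 maps the d-length input to an h-length hidden vector and W1 maps it
    back; the doubly rectified result gates the input elementwise.  b2 is
    initialized to ones so the gate starts (approximately) open, which lets
    the surrounding network train from the identity mapping.
    """

    def __init__(self, d: int, h: int, rng: np.random.Generator):
        self.d, self.h = d, h
        self.W1 = Parameter(he_normal(rng, (d, h), h) * 0.1)
        self.W2 = Parameter(he_normal(rng, (h, d), d) * 0.1)
        self.b1 = Parameter(np.zeros(h))
        self.b2 = Parameter(np.ones(d))
        self._cache = None

    def parameters(self):
        return [self.W1, self.W2, self.b1, self.b2]

    def forward(self, x, training):
        inner_pre = x @ self.W2.value.T + self.b1.value
        inner = np.maximum(inner_pre, 0.0)
        gate_pre = inner @ self.W1.value.T + self.b2.value
        gate = np.maximum(gate_pre, 0.0)
        if training:
            self._cache = (x, inner_pre, inner, gate_pre, gate)
        return gate * x

    def backward(self, g):
        x, inner_pre, inner, gate_pre, gate = self._cache
        dgate = g * x
        dgate_pre = dgate * (gate_pre > 0)
        self.W1.grad += dgate_pre.T @ inner
        self.b2.grad += dgate_pre.sum(axis=0)
        dinner = dgate_pre @ self.W1.value
        dinner_pre = dinner * (inner_pre > 0)
        self.W2.grad += dinner_pre.T @ x
        self.b1.grad += dinner_pre.sum(axis=0)
        return g * gate + dinner_pre @ self.W2.value


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise stable softmax."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-12)))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)


def softmax_vjp(p: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Vector-Jacobian product of softmax: J^T g given probabilities p."""
    return p * (g - (g * p).sum(axis=-1, keepdims=True))


class SGD:
    """Plain stochastic gradient descent with an optional momentum buffer."""

    def __init__(self, params: list[Parameter], momentum: float = 0.0):
        self.params = params
        self.momentum = momentum
        self._buf = [np.zeros_like(p.value) for p in params] if momentum > 0 else None

    def zero_grad(self):
        for p in self.params:
            p.grad.fill(0.0)

    def step(self, lr: float):
        for i, p in enumerate(self.params):
            if self._buf is not None:
                self._buf[i] = self.momentum * self._buf[i] + p.grad
                p.value -= DTYPE(lr) * self._buf[i]
            else:
                p.value -= DTYPE(lr) * p.grad
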