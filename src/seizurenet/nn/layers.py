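"""Layer implementations for the sequence-classification networks.

All layers operate on float32 arrays shaped ``(batch, time, channels)`` until
``Flatten`` collapses them to ``(batch, features)``.  Each layer exposes
``forward``/``backward`` plus flat ``params``/``grads`` lists consumed by the
optimizer.  Weight initialization is Glorot-uniform for input/dense kernels
and orthogonal for recurrent kernels; the LSTM forget-gate bias starts at 1.
"""
from __future__ import annotations

import numpy as np

from .recurrent_kernels import (
    gru_backward,
    gru_forward,
    lstm_backward,
    lstm_forward,
)


class ShapeError(ValueError):
    """Raised when a layer cannot be applied to its input shape."""


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if rows < cols:
        q = q.T
    return np.ascontiguousarray(q[:rows, :cols], dtype=np.float32)


class Layer:
    name: str = "layer"

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple[int, int]) -> tuple[int, int]:
        """Map (time, channels) through the layer; raise ShapeError if invalid."""
        return in_shape

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Conv1D(Layer):
    """1-D convolution, stride 1, valid padding, fused ReLU activation."""

    name = "conv1d"

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 rng: np.random.Generator, activation: str = "relu"):
        if filters < 1 or kernel_size < 1:
            raise ValueError("filters and kernel_size must be >= 1")
        self.in_channels = in_channels
        self.filters = filters
        self.kernel_size = kernel_size
        self.activation = activation
        fan_in = kernel_size * in_channels
        fan_out = kernel_size * filters
        self.w = glorot_uniform(rng, fan_in, fan_out,
                                (kernel_size, in_channels, filters))
        self.b = np.zeros(filters, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.dw, self.db]

    def out_shape(self, in_shape):
        t, c = in_shape
        if c != self.in_channels:
            raise ShapeError(
                f"conv1d expects {self.in_channels} channels, got {c}")
        t_out = t - self.kernel_size + 1
        if t_out < 1:
            raise ShapeError(
                f"conv1d kernel {self.kernel_size} leaves no time steps "
                f"from input length {t}")
        return t_out, self.filters

    def forward(self, x, training=False):
        b_sz, t, _ = x.shape
        t_out = t - self.kernel_size + 1
        if t_out < 1:
            raise ShapeError("input too short for conv1d kernel")
        pre = np.broadcast_to(self.b, (b_sz, t_out, self.filters)).copy()
        for k in range(self.kernel_size):
            pre += x[:, k:k + t_out, :] @ self.w[k]
        self._x = x
        if self.activation == "relu":
            self._mask = pre > 0
            return np.where(self._mask, pre, np.float32(0.0))
        self._mask = None
        return pre

    def backward(self, dout):
        if self._mask is not None:
            dout = dout * self._mask
        x = self._x
        t_out = dout.shape[1]
        dx = np.zeros_like(x)
        self.db[:] = dout.sum(axis=(0, 1))
        for k in range(self.kernel_size):
            xk = x[:, k:k + t_out, :]
            self.dw[k] = np.tensordot(xk, dout, axes=([0, 1], [0, 1]))
            dx[:, k:k + t_out, :] += dout @ self.w[k].T
        return dx


class _RNNDirection:
    """Weights and state for one direction of a bidirectional layer."""

    def __init__(self, kind: str, in_channels: int, units: int,
                 rng: np.random.Generator):
        self.kind = kind
        h = units
        if kind == "lstm":
            self.wx = glorot_uniform(rng, in_channels, 4 * h,
                                     (in_channels, 4 * h))
            self.wh = orthogonal(rng, h, 4 * h)
            self.b = np.zeros(4 * h, dtype=np.float32)
            self.b[h:2 * h] = 1.0  # forget-gate bias
            self.weights = [self.wx, self.wh, self.b]
        else:  # gru
            self.wrz = glorot_uniform(rng, in_channels, 2 * h,
                                      (in_channels, 2 * h))
            self.wn = glorot_uniform(rng, in_channels, h, (in_channels, h))
            self.urz = orthogonal(rng, h, 2 * h)
            self.un = orthogonal(rng, h, h)
            self.brz = np.zeros(2 * h, dtype=np.float32)
            self.bn = np.zeros(h, dtype=np.float32)
            self.weights = [self.wrz, self.wn, self.urz, self.un,
                            self.brz, self.bn]
        self.wgrads = [np.zeros_like(w) for w in self.weights]

    def forward(self, x_tbc: np.ndarray) -> np.ndarray:
        """x_tbc: (T, B, C) time-major input; returns (T, B, H)."""
        if self.kind == "lstm":
            xg = x_tbc @ self.wx + self.b
            self._cache = lstm_forward(np.ascontiguousarray(xg), self.wh)
            self._x = x_tbc
            return self._cache[3]
        xrz = x_tbc @ self.wrz + self.brz
        xn = x_tbc @ self.wn + self.bn
        self._cache = gru_forward(np.ascontiguousarray(xrz),
                                  np.ascontiguousarray(xn), self.urz, self.un)
        self._x = x_tbc
        return self._cache[2]

    def backward(self, dh: np.ndarray) -> np.ndarray:
        t, b, c = self._x.shape
        xf = self._x.reshape(t * b, c)
        if self.kind == "lstm":
            gates, cells, tanhc, hs = self._cache
            dxg, dwh = lstm_backward(np.ascontiguousarray(dh), gates, cells,
                                     tanhc, hs, self.wh)
            df = dxg.reshape(t * b, -1)
            self.wgrads[0][:] = xf.T @ df
            self.wgrads[1][:] = dwh
            self.wgrads[2][:] = df.sum(axis=0)
            return (df @ self.wx.T).reshape(t, b, c)
        rz, ns, hs = self._cache
        dxrz, dxn, durz, dun = gru_backward(np.ascontiguousarray(dh), rz, ns,
                                            hs, self.urz, self.un)
        drz = dxrz.reshape(t * b, -1)
        dn = dxn.reshape(t * b, -1)
        self.wgrads[0][:] = xf.T @ drz
        self.wgrads[1][:] = xf.T @ dn
        self.wgrads[2][:] = durz
        self.wgrads[3][:] = dun
        self.wgrads[4][:] = drz.sum(axis=0)
        self.wgrads[5][:] = dn.sum(axis=0)
        return (drz @ self.wrz.T + dn @ self.wn.T).reshape(t, b, c)


class BiRNN(Layer):
    """Bidirectional recurrent layer (LSTM or GRU cells).

    Emits the full sequence with the two directions concatenated along the
    channel axis, so downstream convolution/pooling stages keep a time axis.
    """

    def __init__(self, in_channels: int, units: int, kind: str,
                 rng: np.random.Generator):
        if kind not in ("lstm", "gru"):
            raise ValueError(f"unknown RNN kind: {kind!r}")
        if units < 1:
            raise ValueError("units must be >= 1")
        self.in_channels = in_channels
        self.units = units
        self.kind = kind
        self.name = f"bi{kind}"
        self.fwd = _RNNDirection(kind, in_channels, units, rng)
        self.bwd = _RNNDirection(kind, in_channels, units, rng)

    @property
    def params(self):
        return self.fwd.weights + self.bwd.weights

    @property
    def grads(self):
        return self.fwd.wgrads + self.bwd.wgrads

    def out_shape(self, in_shape):
        t, c = in_shape
        if c != self.in_channels:
            raise ShapeError(
                f"{self.name} expects {self.in_channels} channels, got {c}")
        return t, 2 * self.units

    def forward(self, x, training=False):
        x_tbc = np.ascontiguousarray(x.transpose(1, 0, 2))
        h_f = self.fwd.forward(x_tbc)
        h_b = self.bwd.forward(np.ascontiguousarray(x_tbc[::-1]))
        out = np.concatenate([h_f, h_b[::-1]], axis=2)
        return np.ascontiguousarray(out.transpose(1, 0, 2))

    def backward(self, dout):
        d_tbc = dout.transpose(1, 0, 2)
        h = self.units
        dx_f = self.fwd.backward(d_tbc[:, :, :h])
        dx_b = self.bwd.backward(np.ascontiguousarray(d_tbc[::-1, :, h:]))
        dx = dx_f + dx_b[::-1]
        return np.ascontiguousarray(dx.transpose(1, 0, 2))


class AvgPool1D(Layer):
    """Average pooling along time; pool size == stride, remainder dropped."""

    name = "avgpool1d"

    def __init__(self, pool_size: int = 2):
        if pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        self.pool_size = pool_size

    def out_shape(self, in_shape):
        t, c = in_shape
        t_out = t // self.pool_size
        if t_out < 1:
            raise ShapeError(
                f"avgpool size {self.pool_size} leaves no time steps "
                f"from input length {t}")
        return t_out, c

    def forward(self, x, training=False):
        b, t, c = x.shape
        p = self.pool_size
        t_out = t // p
        if t_out < 1:
            raise ShapeError("input too short for pooling")
        self._in_t = t
        return x[:, :t_out * p, :].reshape(b, t_out, p, c).mean(axis=2)

    def backward(self, dout):
        b, t_out, c = dout.shape
        p = self.pool_size
        dx = np.zeros((b, self._in_t, c), dtype=dout.dtype)
        dx[:, :t_out * p, :] = np.repeat(dout / p, p, axis=1)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    name = "dropout"

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = np.float32(1.0 - self.rate)
        self._mask = (self.rng.random(x.shape, dtype=np.float32)
                      >= self.rate).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    name = "flatten"

    def out_shape(self, in_shape):
        t, c = in_shape
        return (t * c, 1)

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer with relu, softmax or linear activation.

    For softmax the incoming backward gradient is taken w.r.t. the
    pre-activation logits (the cross-entropy/softmax gradient is fused in
    the model's training loop).
    """

    name = "dense"

    def __init__(self, in_features: int, units: int, rng: np.random.Generator,
                 activation: str = "relu"):
        if units < 1:
            raise ValueError("units must be >= 1")
        if activation not in ("relu", "softmax", "linear"):
            raise ValueError(f"unknown activation: {activation!r}")
        self.in_features = in_features
        self.units = units
        self.activation = activation
        if activation == "softmax":
            self.name = "dense_softmax"
        self.w = glorot_uniform(rng, in_features, units, (in_features, units))
        self.b = np.zeros(units, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.dw, self.db]

    def out_shape(self, in_shape):
        return (self.units, 1)

    def forward(self, x, training=False):
        self._x = x
        pre = x @ self.w + self.b
        if self.activation == "relu":
            self._mask = pre > 0
            return np.where(self._mask, pre, np.float32(0.0))
        if self.activation == "softmax":
            z = pre - pre.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        return pre

    def backward(self, dout):
        if self.activation == "relu":
            dout = dout * self._mask
        # softmax: dout already w.r.t. logits
        self.dw[:] = self._x.T @ dout
        self.db[:] = dout.sum(axis=0)
        return dout @ self.w.T
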