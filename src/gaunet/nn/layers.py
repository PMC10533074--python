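"""Minimal layer zoo with explicit forward/backward passes.

All layers operate on NCHW float arrays.  Each layer caches what its
backward pass needs during ``forward`` and writes parameter gradients into
``Param.grad`` during ``backward`` (overwriting, one backward per step).
Convolutions use same-size padding; for even kernels the extra padding
pixel goes to the bottom/right.
"""

from __future__ import annotations

import numpy as np

from ..errors import ShapeError

DTYPE = np.float32


class Param:
    """A trainable tensor and its gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out, dtype=DTYPE):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    def params(self) -> list[Param]:
        return []

    def extra_state_size(self) -> int:
        """Non-trainable parameters (e.g. BN running statistics)."""
        return 0

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded k x k convolution implemented via im2col + matmul."""

    def __init__(self, cin, cout, k, rng, dtype=DTYPE):
        self.cin, self.cout, self.k = cin, cout, k
        self.W = Param(glorot_uniform(rng, (cout, cin, k, k), cin * k * k, cout * k * k, dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self.pt = (k - 1) // 2
        self.pb = k - 1 - self.pt

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        n, c, h, w = x.shape
        k = self.k
        xp = np.pad(x, ((0, 0), (0, 0), (self.pt, self.pb), (self.pt, self.pb)))
        col = np.empty((n, c, k, k, h, w), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                col[:, :, i, j] = xp[:, :, i : i + h, j : j + w]
        self._col = col.reshape(n, c * k * k, h * w)
        self._shape = (n, c, h, w)
        wm = self.W.value.reshape(self.cout, c * k * k)
        y = np.matmul(wm, self._col) + self.b.value[:, None]
        return y.reshape(n, self.cout, h, w)

    def backward(self, dy):
        n, c, h, w = self._shape
        k = self.k
        dyf = dy.reshape(n, self.cout, h * w)
        self.b.grad = dyf.sum(axis=(0, 2)).astype(self.b.value.dtype)
        dW = np.matmul(dyf, self._col.transpose(0, 2, 1)).sum(axis=0)
        self.W.grad = dW.reshape(self.W.value.shape)
        wm = self.W.value.reshape(self.cout, c * k * k)
        dcol = np.matmul(wm.T, dyf).reshape(n, c, k, k, h, w)
        dxp = np.zeros((n, c, h + k - 1, w + k - 1), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcol[:, :, i, j]
        self._col = None
        return dxp[:, :, self.pt : self.pt + h, self.pt : self.pt + w]


class ConvTranspose2D(Layer):
    """2x2 stride-2 transposed convolution (learned up-sampling)."""

    def __init__(self, cin, cout, rng, dtype=DTYPE):
        self.cin, self.cout = cin, cout
        self.W = Param(glorot_uniform(rng, (cin, cout, 2, 2), cin * 4, cout * 4, dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        n, c, h, w = x.shape
        self._x = x
        y = np.empty((n, self.cout, 2 * h, 2 * w), dtype=x.dtype)
        for a in range(2):
            for bb in range(2):
                contrib = np.tensordot(x, self.W.value[:, :, a, bb], axes=([1], [0]))
                y[:, :, a::2, bb::2] = np.moveaxis(contrib, -1, 1)
        y += self.b.value[None, :, None, None]
        return y

    def backward(self, dy):
        x = self._x
        self.b.grad = dy.sum(axis=(0, 2, 3)).astype(self.b.value.dtype)
        dx = np.zeros_like(x)
        dW = np.empty_like(self.W.value)
        for a in range(2):
            for bb in range(2):
                dsub = dy[:, :, a::2, bb::2]
                dx += np.moveaxis(
                    np.tensordot(dsub, self.W.value[:, :, a, bb], axes=([1], [1])),
                    -1,
                    1,
                )
                dW[:, :, a, bb] = np.tensordot(x, dsub, axes=([0, 2, 3], [0, 2, 3]))
        self.W.grad = dW
        self._x = None
        return dx


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c, momentum=0.99, eps=1e-3, dtype=DTYPE):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def extra_state_size(self):
        return self.running_mean.size + self.running_var.size

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(
                self.running_mean.dtype
            )
            self.running_var = (m * self.running_var + (1 - m) * var).astype(
                self.running_var.dtype
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, training)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, dy):
        xhat, inv_std, training = self._cache
        self.beta.grad = dy.sum(axis=(0, 2, 3)).astype(self.beta.value.dtype)
        self.gamma.grad = (dy * xhat).sum(axis=(0, 2, 3)).astype(self.gamma.value.dtype)
        dxhat = dy * self.gamma.value[None, :, None, None]
        if not training:
            return dxhat * inv_std[None, :, None, None]
        n, c, h, w = dy.shape
        m = n * h * w
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        self._cache = None
        return (inv_std[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class Activation(Layer):
    """ReLU, ELU (alpha=1) or LeakyReLU (slope 0.3)."""

    LEAKY_SLOPE = 0.3

    def __init__(self, kind: str):
        if kind not in ("relu", "elu", "leaky_relu"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x, training):
        if self.kind == "relu":
            y = np.maximum(x, 0)
            self._cache = x > 0
        elif self.kind == "leaky_relu":
            pos = x > 0
            y = np.where(pos, x, self.LEAKY_SLOPE * x)
            self._cache = pos
        else:  # elu
            pos = x > 0
            y = np.where(pos, x, np.expm1(np.minimum(x, 0.0)))
            self._cache = (pos, y)
        return y

    def backward(self, dy):
        if self.kind == "relu":
            return dy * self._cache
        if self.kind == "leaky_relu":
            return dy * np.where(self._cache, 1.0, self.LEAKY_SLOPE).astype(dy.dtype)
        pos, y = self._cache
        return dy * np.where(pos, 1.0, y + 1.0)


class Pool2D(Layer):
    """2x2 stride-2 max or average pooling."""

    def __init__(self, kind: str):
        if kind not in ("max", "average"):
            raise ValueError(f"unknown pooling {kind!r}")
        self.kind = kind

    def forward(self, x, training):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ShapeError(f"pooling needs even spatial dims, got {h}x{w}")
        xr = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        self._shape = (n, c, h, w)
        if self.kind == "max":
            self._idx = xr.argmax(axis=-1)
            return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]
        return xr.mean(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        if self.kind == "max":
            np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        else:
            dxr[...] = dy[..., None] / 4.0
        return (
            dxr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, training):
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        self._y = y
        return y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)
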