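"""Minimal numpy convolutional-network backend.

Implements exactly the layer set the segmentation network needs — 3x3
'same' convolution, batch normalization, ReLU, dropout, 2x2 max pooling,
2x2 stride-2 transposed convolution, channel concatenation, sigmoid —
with hand-derived backward passes and an Adam optimizer.  Convolutions
are evaluated as im2col + BLAS matmul in float32; the input-gradient of
a convolution is itself computed as a correlation with the rotated
kernel, so both directions run on matmul.

Tensors are NCHW.  Every layer exposes ``forward(x, training)`` and
``backward(dout)``; parameters live in :class:`Param` objects collected
by the model and stepped by :class:`Adam`.  Gradient correctness is
established by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patches for a 3x3 'same' correlation."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * 9
    )


class Conv3x3:
    """3x3 convolution, stride 1, zero 'same' padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        std = np.sqrt(2.0 / (c_in * 9))
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(rng.normal(0.0, std, size=(c_in * 9, c_out)).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col3(x)
        y = cols @ self.w.value + self.b.value
        if training:
            self._cols, self._shape = cols, (n, c, h, w)
        return np.ascontiguousarray(
            y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(
            n * h * w, self.c_out
        )
        self.w.grad = self._cols.T @ dflat
        self.b.grad = dflat.sum(axis=0)
        self._cols = None
        # dx = correlation of dout with the 180deg-rotated, transposed kernel
        wr = self.w.value.reshape(c, 3, 3, self.c_out)[:, ::-1, ::-1, :]
        wrot = np.ascontiguousarray(wr.transpose(3, 1, 2, 0)).reshape(
            self.c_out * 9, c
        )
        dcols = _im2col3(dout)
        dx = dcols @ wrot
        return np.ascontiguousarray(dx.reshape(n, h, w, c).transpose(0, 3, 1, 2))


class Conv1x1:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        std = np.sqrt(2.0 / c_in)
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(rng.normal(0.0, std, size=(c_in, c_out)).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        flat = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, c)
        if training:
            self._flat, self._shape = flat, (n, c, h, w)
        y = flat @ self.w.value + self.b.value
        return np.ascontiguousarray(
            y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(
            -1, self.c_out
        )
        self.w.grad = self._flat.T @ dflat
        self.b.grad = dflat.sum(axis=0)
        dx = dflat @ self.w.value.T
        return np.ascontiguousarray(dx.reshape(n, h, w, c).transpose(0, 3, 1, 2))


class UpConv2x2:
    """Transposed convolution, kernel 2, stride 2 (non-overlapping)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        std = np.sqrt(2.0 / c_in)
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(rng.normal(0.0, std, size=(c_in, c_out * 4)).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        flat = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, c)
        if training:
            self._flat, self._shape = flat, (n, c, h, w)
        y = flat @ self.w.value  # (N*H*W, c_out*4)
        y = y.reshape(n, h, w, self.c_out, 2, 2)
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 4, 2, 5)).reshape(
            n, self.c_out, 2 * h, 2 * w
        )
        return y + self.b.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        d = dout.reshape(n, self.c_out, h, 2, w, 2)
        dflat = np.ascontiguousarray(d.transpose(0, 2, 4, 1, 3, 5)).reshape(
            -1, self.c_out * 4
        )
        self.w.grad = self._flat.T @ dflat
        self.b.grad = dout.sum(axis=(0, 2, 3))
        dx = dflat @ self.w.value.T
        return np.ascontiguousarray(dx.reshape(n, h, w, c).transpose(0, 3, 1, 2))


class BatchNorm:
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(self.running_mean.dtype)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(self.running_var.dtype)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
            self._xhat, self._inv = xhat, inv
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean[None, :, None, None]) * inv[
                None, :, None, None
            ]
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad = (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3))[None, :, None, None]
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        )
        self._xhat = None
        return term * inv[None, :, None, None]


class ReLU:
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


class Dropout:
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (
            self.rng.random(x.shape) < keep
        ).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling, stride 2.  Gradient is routed to every argmax
    tie (ties are measure-zero for continuous activations)."""

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = r.max(axis=(3, 5))
        if training:
            self._mask = r == out[:, :, :, None, :, None]
            self._shape = (n, c, h, w)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        d = self._mask * dout[:, :, :, None, :, None]
        return d.reshape(n, c, h, w)

    def params(self):
        return []


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam with bias correction; one instance per model."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p in self.params:
            p.m = self.beta1 * p.m + (1 - self.beta1) * p.grad
            p.v = self.beta2 * p.v + (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)
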