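"""Minimal NumPy neural-network primitives used by the twin-CNN model.

Implements exactly the pieces the architecture needs — 1D convolution
(im2col), max pooling with ceiling semantics, dense layers, ReLU, logistic
output, inverted dropout and the Adam optimizer — with hand-written
backpropagation.  Everything is deterministic given the generators passed
in; no global random state is touched.

Shapes follow the (batch, channels, length) convention for sequence layers
and (batch, features) for dense layers.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Conv1D", "MaxPool1D", "Dense", "ReLU", "Sigmoid", "Dropout",
    "Flatten", "Adam", "conv_output_len", "pool_output_len",
]


def conv_output_len(length: int, width: int, stride: int, padding: str) -> int:
    """Sequence length after a 1D convolution."""
    if padding == "same":
        return -(-length // stride)
    if padding == "valid":
        out = (length - width) // stride + 1
        if out < 1:
            raise ValueError(
                f"length {length} collapses under valid conv width {width}")
        return out
    raise ValueError(f"unknown padding mode {padding!r}")


def pool_output_len(length: int, width: int, stride: int, padding: str) -> int:
    """Sequence length after max pooling (``same`` = ceiling pooling)."""
    if padding == "same":
        return -(-length // stride)
    if padding == "valid":
        out = (length - width) // stride + 1
        if out < 1:
            raise ValueError(
                f"length {length} collapses under valid pool width {width}")
        return out
    raise ValueError(f"unknown padding mode {padding!r}")


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    params: list[Param]

    def forward(self, x, *, train=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """1D convolution over (batch, channels, length) via im2col."""

    def __init__(self, in_channels: int, out_channels: int, width: int,
                 stride: int, padding: str, rng: np.random.Generator,
                 dtype=np.float32):
        scale = math.sqrt(2.0 / (in_channels * width))  # He init
        self.W = Param(rng.normal(0.0, scale,
                                  (in_channels * width, out_channels)
                                  ).astype(dtype), "conv.W")
        self.b = Param(np.zeros(out_channels, dtype=dtype), "conv.b")
        self.width, self.stride, self.padding = width, stride, padding
        self.in_channels = in_channels
        self.params = [self.W, self.b]
        self._cache = None

    def _pads(self, length: int) -> tuple[int, int, int]:
        out_len = conv_output_len(length, self.width, self.stride, self.padding)
        if self.padding == "same":
            total = max((out_len - 1) * self.stride + self.width - length, 0)
            return out_len, total // 2, total - total // 2
        return out_len, 0, 0

    def forward(self, x, *, train=False, rng=None):
        n, c, length = x.shape
        out_len, left, right = self._pads(length)
        xp = np.pad(x, ((0, 0), (0, 0), (left, right))) if left or right else x
        # windows: (n, c, positions, width) -> gather strided positions
        win = sliding_window_view(xp, self.width, axis=2)
        if self.stride == 1:
            win = win[:, :, :out_len, :]
        else:
            win = win[:, :, np.arange(out_len) * self.stride, :]
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            n * out_len, c * self.width)
        out = cols @ self.W.value + self.b.value
        self._cache = (cols, n, c, length, out_len, left)
        return out.reshape(n, out_len, -1).transpose(0, 2, 1)

    def backward(self, dout):
        cols, n, c, length, out_len, left = self._cache
        dr = np.ascontiguousarray(dout.transpose(0, 2, 1)).reshape(
            n * out_len, -1)
        self.W.grad += cols.T @ dr
        self.b.grad += dr.sum(axis=0)
        dcols = (dr @ self.W.value.T).reshape(n, out_len, c, self.width)
        _, l_pad, r_pad = self._pads(length)
        dxp = np.zeros((n, c, length + l_pad + r_pad), dtype=dout.dtype)
        for w in range(self.width):  # window starts are duplicate-free per w
            piece = dcols[:, :, :, w].transpose(0, 2, 1)
            if self.stride == 1:
                dxp[:, :, w:w + out_len] += piece
            else:
                dxp[:, :, np.arange(out_len) * self.stride + w] += piece
        return dxp[:, :, left:left + length]


class MaxPool1D(Layer):
    """Max pooling with ceiling output length (right-padded with -inf)."""

    def __init__(self, width: int, stride: int, padding: str = "same"):
        self.width, self.stride, self.padding = width, stride, padding
        self.params = []
        self._cache = None

    def forward(self, x, *, train=False, rng=None):
        n, c, length = x.shape
        out_len = pool_output_len(length, self.width, self.stride, self.padding)
        need = (out_len - 1) * self.stride + self.width
        pad = max(need - length, 0)
        xp = np.pad(x, ((0, 0), (0, 0), (0, pad)),
                    constant_values=-np.inf) if pad else x
        win = sliding_window_view(xp, self.width, axis=2)
        idx = np.arange(out_len) * self.stride
        win = win[:, :, idx, :]
        arg = win.argmax(axis=3)
        out = np.take_along_axis(win, arg[..., None], axis=3)[..., 0]
        self._cache = (arg, idx, n, c, length, pad)
        return out

    def backward(self, dout):
        arg, idx, n, c, length, pad = self._cache
        dxp = np.zeros((n, c, length + pad), dtype=dout.dtype)
        pos = idx[None, None, :] + arg  # (n, c, out_len) indices into length axis
        flat = (np.arange(n)[:, None, None] * c * (length + pad)
                + np.arange(c)[None, :, None] * (length + pad) + pos)
        if self.stride >= self.width:  # non-overlapping: indices are unique
            dxp.reshape(-1)[flat.ravel()] += dout.ravel()
        else:
            np.add.at(dxp.reshape(-1), flat.ravel(), dout.ravel())
        return dxp[:, :, :length]


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = math.sqrt(2.0 / in_dim)
        self.W = Param(rng.normal(0.0, scale, (in_dim, out_dim)).astype(dtype),
                       "dense.W")
        self.b = Param(np.zeros(out_dim, dtype=dtype), "dense.b")
        self.params = [self.W, self.b]
        self._x = None

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class ReLU(Layer):
    def __init__(self):
        self.params = []
        self._mask = None

    def forward(self, x, *, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Sigmoid(Layer):
    def __init__(self):
        self.params = []
        self._out = None

    def forward(self, x, *, train=False, rng=None):
        # clip keeps exp within float32 range; saturation is exact anyway
        out = np.clip(x, -80.0, 80.0)
        np.negative(out, out=out)
        np.exp(out, out=out)
        out += 1.0
        np.reciprocal(out, out=out)
        self._out = out
        return out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


class Dropout(Layer):
    """Inverted dropout: active only in training mode, identity at inference."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability {p} outside [0, 1)")
        self.p = p
        self.params = []
        self._mask = None

    def forward(self, x, *, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def __init__(self):
        self.params = []
        self._shape = None

    def forward(self, x, *, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Adam:
    """Adam with bias correction; slots keyed per parameter."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._scratch = [np.empty_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        # update = lr' * m / (sqrt(v) + eps') with the bias corrections
        # folded into scalars, computed in place via one scratch buffer.
        lr_t = self.lr * math.sqrt(bc2) / bc1
        eps_t = self.eps * math.sqrt(bc2)
        for p, m, v, s in zip(self.params, self._m, self._v, self._scratch):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            np.multiply(p.grad, p.grad, out=s)
            v *= self.b2
            s *= 1.0 - self.b2
            v += s
            np.sqrt(v, out=s)
            s += eps_t
            np.divide(m, s, out=s)
            s *= lr_t
            p.value -= s
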