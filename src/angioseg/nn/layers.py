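"""Minimal NumPy layers with manual backpropagation.

Only what the encoder-decoder segmentation network needs: stride-1
same-padded convolution, 2x2/stride-2 transposed convolution, 2x2/stride-2
max pooling and the ReLU/sigmoid nonlinearities.  Forward passes cache what
the matching ``backward`` needs; gradients accumulate into ``Parameter.grad``.
All arithmetic is float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    """A trainable array with its gradient buffer."""

    __slots__ = ("data", "grad", "label")

    def __init__(self, data: np.ndarray, label: str = ""):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.label = label

    @property
    def size(self) -> int:
        return self.data.size


def kaiming_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """Fan-in scaled normal initialisation (gain for ReLU)."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d:
    """Stride-1 convolution with symmetric zero ("same") padding.

    Weight layout ``(c_out, c_in, k, k)``; implemented as an im2col matrix
    product so that one BLAS call carries each forward/backward pass.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator | None = None, label: str = ""):
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel * kernel
        w = (kaiming_normal(rng, (c_out, c_in, kernel, kernel), fan_in)
             if rng is not None else np.zeros((c_out, c_in, kernel, kernel), np.float32))
        self.W = Parameter(w, f"{label}.W")
        self.b = Parameter(np.zeros(c_out, np.float32), f"{label}.b")
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))          # (n,c,h,w,k,k)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5))
        cols = cols.reshape(n * h * w, c * k * k)
        wmat = self.W.data.reshape(self.c_out, -1)
        out = cols @ wmat.T
        out += self.b.data
        self._cache = (cols, (n, c, h, w))
        return np.ascontiguousarray(out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        k, p = self.k, self.k // 2
        dr = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.W.grad += (dr.T @ cols).reshape(self.W.data.shape)
        self.b.grad += dr.sum(axis=0)
        dcols = (dr @ self.W.data.reshape(self.c_out, -1)).reshape(n, h, w, c, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)                     # (n,c,h,w,k,k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j]
        self._cache = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ConvTranspose2d:
    """2x2 transposed convolution with stride 2 (the up-convolution).

    Output patches do not overlap at this kernel/stride, so the operation is
    a per-pixel channel mix followed by a 2x2 spatial unfold.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 2,
                 rng: np.random.Generator | None = None, label: str = ""):
        assert kernel == 2, "up-convolution is fixed at kernel 2, stride 2"
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        w = (kaiming_normal(rng, (c_in, c_out, 2, 2), c_in)
             if rng is not None else np.zeros((c_in, c_out, 2, 2), np.float32))
        self.W = Parameter(w, f"{label}.W")
        self.b = Parameter(np.zeros(c_out, np.float32), f"{label}.b")
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        t = np.tensordot(x, self.W.data, axes=([1], [0]))            # (n,h,w,c_out,2,2)
        out = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.c_out, 2 * h, 2 * w)
        out = np.ascontiguousarray(out)
        out += self.b.data[None, :, None, None]
        self._cache = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        n, c, h, w = x.shape
        dt = dout.reshape(n, self.c_out, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        self.W.grad += np.tensordot(x, dt, axes=([0, 2, 3], [0, 1, 2]))
        self.b.grad += dout.sum(axis=(0, 2, 3))
        dx = np.tensordot(dt, self.W.data, axes=([3, 4, 5], [1, 2, 3]))
        self._cache = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class MaxPool2d:
    """2x2 max pooling with stride 2; routes gradient to the arg-max pixel."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        windows = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (n, c, h, w))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dwin = np.zeros((n, c, h // 2, w // 2, 4), np.float32)
        np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
        dx = dwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = None
        return np.ascontiguousarray(dx.reshape(n, c, h, w))


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dout, np.float32(0.0))
        self._mask = None
        return dx


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic squashing to (0, 1)."""
    out = np.empty_like(z, dtype=np.float32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
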