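"""Minimal NumPy neural-network layers with explicit backward passes.

The surrogate classifier needs full gradient access — both for training and
for class-activation mapping, where gradients of a class logit with respect
to an intermediate feature layer are required — so every layer here caches
its forward inputs and implements an exact analytic backward pass.

Conventions: activations are float32 arrays shaped (N, C, H, W); convolutions
are 3x3, stride 1, zero-padded to preserve spatial size.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C, kh, kw, H, W) sliding windows of the padded input."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N, C, H, W, kh, kw)
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3))


def _col2im(dcols: np.ndarray, x_shape: tuple, kh: int, kw: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add windows back onto the input grid."""
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Conv2d:
    """3x3 same-padding convolution, He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = (rng.standard_normal((c_out, c_in, k, k)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.pad = k // 2
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols = _im2col(x, self.k, self.k, self.pad)
        self._cols, self._x_shape = cols, x.shape
        out = np.einsum("fcij,ncijhw->nfhw", self.w, cols, optimize=True)
        return out + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = np.einsum("nfhw,ncijhw->fcij", dout, self._cols, optimize=True)
        self.db = dout.sum(axis=(0, 2, 3))
        dcols = np.einsum("nfhw,fcij->ncijhw", dout, self.w, optimize=True)
        return _col2im(dcols, self._x_shape, self.k, self.k, self.pad)

    @property
    def params(self):
        return {"w": self.w, "b": self.b}

    @property
    def grads(self):
        return {"w": self.dw, "b": self.db}


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; input sides must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class GlobalMaxPool:
    """Global spatial max: presence = strongest response over all locations."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        flat = x.reshape(n, c, -1)
        self._argmax = flat.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(flat, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        dflat = np.zeros((n, c, h * w), dtype=dout.dtype)
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=-1)
        return dflat.reshape(self._x_shape)


class GlobalAvgPool:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._spatial = x.shape[2] * x.shape[3]
        self._x_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / self._spatial


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / d_in)
        self.w = (rng.standard_normal((d_out, d_in)) * scale).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = dout.T @ self._x
        self.db = dout.sum(axis=0)
        return dout @ self.w

    @property
    def params(self):
        return {"w": self.w, "b": self.b}

    @property
    def grads(self):
        return {"w": self.dw, "b": self.db}


class Adam:
    """Adam over a flat dict of parameter arrays; learning rate passed per step."""

    def __init__(self, params: dict[str, np.ndarray], betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)
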