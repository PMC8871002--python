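"""NumPy layer primitives with explicit forward/backward passes.

Data layout is NCHW float32.  Convolutions go through an im2col matmul so
the heavy lifting lands in BLAS; the transpose convolution is a single
matmul followed by a strided scatter of its 4x4 taps.

Weight tensors follow the (kh, kw, cin, cout) convention — the same order
the architecture table prints — and transpose-conv weights are
(kh, kw, cout, cin).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2x2",
    "TransposeConv2D",
    "Softmax",
    "Identity",
]


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base: parameter-free identity."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {}

    @property
    def grads(self) -> dict[str, np.ndarray]:
        return {}


class Identity(Layer):
    pass


class Conv2D(Layer):
    """3x3 (or kxk) same-padded convolution, stride 1."""

    def __init__(self, cin: int, cout: int, kernel: int = 3, rng: np.random.Generator | None = None):
        if kernel % 2 != 1:
            raise ValueError("same-padded convolution requires an odd kernel")
        self.cin, self.cout, self.k = cin, cout, kernel
        rng = rng or np.random.default_rng(0)
        self.weights = he_uniform(rng, (kernel, kernel, cin, cout), fan_in=kernel * kernel * cin)
        self.bias = np.zeros(cout, dtype=np.float32)
        self.dweights = np.zeros_like(self.weights)
        self.dbias = np.zeros_like(self.bias)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def _wmat(self) -> np.ndarray:
        # (cin*k*k, cout) with (cin, kh, kw) fastest-varying order of the cols
        return self.weights.transpose(2, 0, 1, 3).reshape(self.cin * self.k * self.k, self.cout)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # (n,c,h,w,k,k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * self.k * self.k
        )
        out = cols @ self._wmat() + self.bias
        self._cols = cols if train else None
        self._in_shape = x.shape
        return np.ascontiguousarray(out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cols is None:
            raise RuntimeError("backward called without a train-mode forward")
        n, c, h, w = self._in_shape
        k, p = self.k, self.k // 2
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(n * h * w, self.cout)
        dw = self._cols.T @ dmat  # (cin*k*k, cout)
        self.dweights = np.ascontiguousarray(
            dw.reshape(self.cin, k, k, self.cout).transpose(1, 2, 0, 3)
        )
        self.dbias = dmat.sum(axis=0)
        dcols = (dmat @ self._wmat().T).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + h, kj : kj + w] += dcols[:, :, :, :, ki, kj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + h, p : p + w]

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"weights": self.weights, "bias": self.bias}

    @property
    def grads(self) -> dict[str, np.ndarray]:
        return {"weights": self.dweights, "bias": self.dbias}


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.c = channels
        self.eps = eps
        self.momentum = momentum
        self.scale = np.ones(channels, dtype=np.float32)
        self.offset = np.zeros(channels, dtype=np.float32)
        self.dscale = np.zeros_like(self.scale)
        self.doffset = np.zeros_like(self.offset)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3), dtype=np.float64)
            var = x.var(axis=(0, 2, 3), dtype=np.float64)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean.astype(np.float32)[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.scale[None, :, None, None] * xhat + self.offset[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dscale = (dout * xhat).sum(axis=(0, 2, 3))
        self.doffset = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.scale[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        return dx.astype(np.float32)

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"scale": self.scale, "offset": self.offset}

    @property
    def grads(self) -> dict[str, np.ndarray]:
        return {"scale": self.dscale, "offset": self.doffset}


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2; ties route the gradient to the first max."""

    def __init__(self) -> None:
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims {h}x{w} not divisible by the pooling stride 2")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        return (
            dxr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class TransposeConv2D(Layer):
    """4x4 stride-2 transpose convolution with symmetric crop to exactly 2x.

    The raw scatter output has size 2*in + 2; one row/column is cropped on
    each side, matching a "same"-style 2x upsampling.
    """

    def __init__(self, cin: int, cout: int, kernel: int = 4, stride: int = 2,
                 rng: np.random.Generator | None = None):
        if kernel != 2 * stride:
            raise ValueError("kernel must equal 2*stride for symmetric-crop 2x upsampling")
        self.cin, self.cout, self.k, self.stride = cin, cout, kernel, stride
        rng = rng or np.random.default_rng(0)
        self.weights = he_uniform(rng, (kernel, kernel, cout, cin), fan_in=kernel * kernel * cin)
        self.bias = np.zeros(cout, dtype=np.float32)
        self.dweights = np.zeros_like(self.weights)
        self.dbias = np.zeros_like(self.bias)
        self._xm: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def _wmat(self) -> np.ndarray:
        # (cin, k*k*cout)
        return self.weights.transpose(3, 0, 1, 2).reshape(self.cin, self.k * self.k * self.cout)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        k, s = self.k, self.stride
        xm = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(n * h * w, c)
        taps = (xm @ self._wmat()).reshape(n, h, w, k, k, self.cout)
        full = np.zeros((n, self.cout, s * h + k - s, s * w + k - s), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                full[:, :, ki : ki + s * h : s, kj : kj + s * w : s] += taps[
                    :, :, :, ki, kj, :
                ].transpose(0, 3, 1, 2)
        crop = (k - s) // 2
        out = full[:, :, crop : crop + s * h, crop : crop + s * w]
        out = out + self.bias[None, :, None, None]
        if train:
            self._xm, self._in_shape = xm, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        k, s = self.k, self.stride
        crop = (k - s) // 2
        dfull = np.pad(dout, ((0, 0), (0, 0), (crop, crop), (crop, crop)))
        dtaps = np.empty((n, h, w, k, k, self.cout), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dtaps[:, :, :, ki, kj, :] = dfull[
                    :, :, ki : ki + s * h : s, kj : kj + s * w : s
                ].transpose(0, 2, 3, 1)
        dmat = dtaps.reshape(n * h * w, k * k * self.cout)
        dwm = self._xm.T @ dmat  # (cin, k*k*cout)
        self.dweights = np.ascontiguousarray(
            dwm.reshape(self.cin, k, k, self.cout).transpose(1, 2, 3, 0)
        )
        self.dbias = dout.sum(axis=(0, 2, 3))
        dxm = dmat @ self._wmat().T
        return np.ascontiguousarray(dxm.reshape(n, h, w, c).transpose(0, 3, 1, 2))

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"weights": self.weights, "bias": self.bias}

    @property
    def grads(self) -> dict[str, np.ndarray]:
        return {"weights": self.dweights, "bias": self.dbias}


class Softmax(Layer):
    """Channel-axis softmax; every pixel's channel vector sums to one."""

    def __init__(self) -> None:
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=1, keepdims=True)
        if train:
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        p = self._out
        return p * (dout - (dout * p).sum(axis=1, keepdims=True))
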