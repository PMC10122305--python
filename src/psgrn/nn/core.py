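"""Parameter container, dense/convolutional/pooling layers, activations.

All layers follow the same contract: ``forward(x)`` caches whatever the
backward pass needs, ``backward(dout)`` accumulates parameter gradients
and returns the gradient with respect to the input.  Arithmetic is
float32 throughout.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: parameter discovery and gradient zeroing."""

    def params(self) -> list[Param]:
        found: list[Param] = []
        for attr in vars(self).values():
            if isinstance(attr, Param):
                found.append(attr)
            elif isinstance(attr, Module):
                found.extend(attr.params())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Param):
                        found.append(item)
                    elif isinstance(item, Module):
                        found.extend(item.params())
        return found

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0

    def iter_modules(self):
        """Yield this module and every nested sub-module, depth-first."""
        yield self
        for attr in vars(self).values():
            if isinstance(attr, Module):
                yield from attr.iter_modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield from item.iter_modules()


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


def orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if rows < cols:
        q = q.T
    return q[:rows, :cols].astype(DTYPE)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int):
        self.W = Param(kaiming(rng, (in_dim, out_dim), in_dim))
        self.b = Param(np.zeros(out_dim))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class ReLU(Module):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics for evaluation."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self.training = True
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        if not self.training:
            return dxhat * inv[None, :, None, None]
        B, C, H, W = dout.shape
        m = B * H * W
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: tuple[int, int]):
    B, C, H, W = xp.shape
    sh, sw = stride
    Ho = (H - kh) // sh + 1
    Wo = (W - kw) // sw + 1
    cols = np.empty((B, C, kh, kw, Ho, Wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw]
    return cols.reshape(B, C * kh * kw, Ho * Wo), Ho, Wo


def _col2im(dcols: np.ndarray, xp_shape, kh: int, kw: int, stride: tuple[int, int], Ho: int, Wo: int):
    B, C, H, W = xp_shape
    sh, sw = stride
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    dcols = dcols.reshape(B, C, kh, kw, Ho, Wo)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw] += dcols[:, :, i, j]
    return dxp


class Conv2d(Module):
    """2-D convolution over (B, C, H, W) via im2col."""

    def __init__(
        self,
        rng: np.random.Generator,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        stride: int | tuple[int, int] = 1,
        pad: int = 1,
    ):
        fan_in = in_ch * kernel * kernel
        self.W = Param(kaiming(rng, (out_ch, fan_in), fan_in))
        self.b = Param(np.zeros(out_ch))
        self.kernel, self.pad = kernel, pad
        self.stride = (stride, stride) if isinstance(stride, int) else stride
        self.in_ch, self.out_ch = in_ch, out_ch
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols, Ho, Wo = _im2col(xp, k, k, s)
        out = np.matmul(self.W.value[None], cols)
        out += self.b.value[None, :, None]
        self._cache = (cols, xp.shape, x.shape, Ho, Wo)
        return out.reshape(x.shape[0], self.out_ch, Ho, Wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xp_shape, x_shape, Ho, Wo = self._cache
        B = dout.shape[0]
        dflat = dout.reshape(B, self.out_ch, Ho * Wo)
        self.W.grad += np.matmul(dflat, cols.transpose(0, 2, 1)).sum(axis=0)
        self.b.grad += dflat.sum(axis=(0, 2))
        dcols = np.matmul(self.W.value.T[None], dflat)
        dxp = _col2im(dcols, xp_shape, self.kernel, self.kernel, self.stride, Ho, Wo)
        p = self.pad
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class AvgPool2d(Module):
    """Non-overlapping average pooling; odd trailing rows/cols are dropped.

    ``k`` may be an int or an (kh, kw) tuple for anisotropic pooling of
    tall, narrow merged pair matrices.
    """

    def __init__(self, k: int | tuple[int, int] = 2):
        self.kh, self.kw = (k, k) if isinstance(k, int) else k
        self._x_shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        kh, kw = self.kh, self.kw
        B, C, H, W = x.shape
        Ho, Wo = H // kh, W // kw
        self._x_shape = x.shape
        xc = x[:, :, : Ho * kh, : Wo * kw]
        return xc.reshape(B, C, Ho, kh, Wo, kw).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        kh, kw = self.kh, self.kw
        B, C, H, W = self._x_shape
        Ho, Wo = H // kh, W // kw
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        spread = np.repeat(np.repeat(dout, kh, axis=2), kw, axis=3) / (kh * kw)
        dx[:, :, : Ho * kh, : Wo * kw] = spread
        return dx


class GlobalAvgPool2d(Module):
    def __init__(self):
        self._x_shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._x_shape
        return np.broadcast_to(dout[:, :, None, None], self._x_shape) / (H * W)


class MaxPool1d(Module):
    """Pairwise max over feature vectors (B, F) -> (B, F // k)."""

    def __init__(self, k: int = 2):
        self.k = k
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        B, F = x.shape
        Fo = F // k
        xr = x[:, : Fo * k].reshape(B, Fo, k)
        arg = xr.argmax(axis=2)
        self._cache = (x.shape, arg)
        return xr.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, arg = self._cache
        B, F = x_shape
        Fo = F // self.k
        dx = np.zeros(x_shape, dtype=dout.dtype)
        dxr = dx[:, : Fo * self.k].reshape(B, Fo, self.k)
        rows = np.arange(B)[:, None]
        cols = np.arange(Fo)[None, :]
        dxr[rows, cols, arg] = dout
        return dx
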