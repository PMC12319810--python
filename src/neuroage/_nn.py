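"""Minimal 3D neural-network layers with explicit forward/backward passes.

All tensors are float32 and batched as (B, C, D, H, W). Each layer caches
what its backward pass needs on ``forward`` and releases it on
``backward``; gradients accumulate into ``Param.grad`` so batches can be
combined by the caller. Nothing here is stochastic except ``Dropout`` in
training mode, which consumes an explicit numpy Generator, so runs are
reproducible end to end.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
from scipy.special import erf

from .errors import ShapeError

_INV_SQRT2 = np.float32(1.0 / np.sqrt(2.0))
_INV_SQRT2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.decay = decay
        self.name = name


class Layer:
    def params(self) -> Iterator[Param]:
        yield from ()

    def forward(self, x, *, train=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover
        raise NotImplementedError


class DepthwiseConv3d(Layer):
    """k^3 spatial convolution applied per channel ('same' zero padding)."""

    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator):
        self.k = kernel_size
        std = np.sqrt(2.0 / kernel_size**3)
        self.w = Param(
            rng.normal(0.0, std, size=(channels, kernel_size**3)), decay=True
        )
        self.b = Param(np.zeros(channels), decay=False)
        self._cache = None

    def params(self):
        yield self.w
        yield self.b

    def _offsets(self):
        k = self.k
        return [(i, j, l) for i in range(k) for j in range(k) for l in range(k)]

    def forward(self, x, *, train=False, rng=None):
        p = self.k // 2
        B, C, D, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        out = np.empty_like(x)
        out[:] = self.b.value[None, :, None, None, None]
        for idx, (i, j, l) in enumerate(self._offsets()):
            out += (
                self.w.value[:, idx][None, :, None, None, None]
                * xp[:, :, i : i + D, j : j + H, l : l + W]
            )
        self._cache = xp
        return out

    def backward(self, gy):
        xp = self._cache
        self._cache = None
        B, C, D, H, W = gy.shape
        p = self.k // 2
        self.b.grad += gy.sum(axis=(0, 2, 3, 4))
        gxp = np.zeros_like(xp)
        for idx, (i, j, l) in enumerate(self._offsets()):
            window = xp[:, :, i : i + D, j : j + H, l : l + W]
            self.w.grad[:, idx] += np.einsum("bcdhw,bcdhw->c", gy, window)
            gxp[:, :, i : i + D, j : j + H, l : l + W] += (
                self.w.value[:, idx][None, :, None, None, None] * gy
            )
        return gxp[:, :, p : p + D, p : p + H, p : p + W]


class PointwiseConv(Layer):
    """1x1x1 convolution: a channel-mixing matrix applied at every voxel."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.w = Param(rng.normal(0.0, std, size=(cout, cin)), decay=True)
        self.b = Param(np.zeros(cout), decay=False)
        self._cache = None

    def params(self):
        yield self.w
        yield self.b

    def forward(self, x, *, train=False, rng=None):
        B, C = x.shape[:2]
        spatial = x.shape[2:]
        xr = x.reshape(B, C, -1)
        y = np.einsum("oc,bcn->bon", self.w.value, xr)
        y += self.b.value[None, :, None]
        self._cache = (xr, spatial)
        return y.reshape(B, -1, *spatial)

    def backward(self, gy):
        xr, spatial = self._cache
        self._cache = None
        B = gy.shape[0]
        gyr = gy.reshape(B, gy.shape[1], -1)
        self.w.grad += np.einsum("bon,bcn->oc", gyr, xr)
        self.b.grad += gyr.sum(axis=(0, 2))
        gx = np.einsum("oc,bon->bcn", self.w.value, gyr)
        return gx.reshape(B, -1, *spatial)


class ChannelNorm(Layer):
    """Instance-style per-channel normalization over spatial voxels."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels), decay=False)
        self.beta = Param(np.zeros(channels), decay=False)
        self.eps = np.float32(eps)
        self._cache = None

    def params(self):
        yield self.gamma
        yield self.beta

    def forward(self, x, *, train=False, rng=None):
        B, C = x.shape[:2]
        spatial = x.shape[2:]
        xr = x.reshape(B, C, -1)
        mu = xr.mean(axis=2, keepdims=True)
        var = xr.var(axis=2, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (xr - mu) * inv_std
        y = self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]
        self._cache = (xhat, inv_std, spatial)
        return y.reshape(x.shape)

    def backward(self, gy):
        xhat, inv_std, spatial = self._cache
        self._cache = None
        B, C = gy.shape[:2]
        gyr = gy.reshape(B, C, -1)
        self.gamma.grad += np.einsum("bcn,bcn->c", gyr, xhat)
        self.beta.grad += gyr.sum(axis=(0, 2))
        gxhat = gyr * self.gamma.value[None, :, None]
        m1 = gxhat.mean(axis=2, keepdims=True)
        m2 = (gxhat * xhat).mean(axis=2, keepdims=True)
        gx = inv_std * (gxhat - m1 - xhat * m2)
        return gx.reshape(gy.shape)


class GELU(Layer):
    def __init__(self):
        self._cache = None

    def forward(self, x, *, train=False, rng=None):
        phi = 0.5 * (1.0 + erf(x * _INV_SQRT2))
        self._cache = (x, phi)
        return x * phi

    def backward(self, gy):
        x, phi = self._cache
        self._cache = None
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
        return gy * (phi + x * pdf)


class ReLU(Layer):
    def __init__(self):
        self._cache = None

    def forward(self, x, *, train=False, rng=None):
        mask = x > 0
        self._cache = mask
        return x * mask

    def backward(self, gy):
        mask = self._cache
        self._cache = None
        return gy * mask


class Dropout(Layer):
    def __init__(self, p: float):
        self.p = p
        self._cache = None

    def forward(self, x, *, train=False, rng=None):
        if not train or self.p == 0.0:
            self._cache = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        mask = (rng.random(x.shape) >= self.p).astype(np.float32) / np.float32(
            1.0 - self.p
        )
        self._cache = mask
        return x * mask

    def backward(self, gy):
        mask = self._cache
        self._cache = None
        return gy if mask is None else gy * mask


class Downsample(Layer):
    """Stride-2 2^3 convolution: halves each spatial dim, remaps channels."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (8 * cin))
        self.w = Param(rng.normal(0.0, std, size=(cout, 8 * cin)), decay=True)
        self.b = Param(np.zeros(cout), decay=False)
        self._cache = None

    def params(self):
        yield self.w
        yield self.b

    def forward(self, x, *, train=False, rng=None):
        B, C, D, H, W = x.shape
        if D % 2 or H % 2 or W % 2:
            raise ShapeError(f"downsampling requires even dims, got {x.shape}")
        d, h, w = D // 2, H // 2, W // 2
        blocks = (
            x.reshape(B, C, d, 2, h, 2, w, 2)
            .transpose(0, 1, 3, 5, 7, 2, 4, 6)
            .reshape(B, 8 * C, d * h * w)
        )
        y = np.einsum("oc,bcn->bon", self.w.value, blocks)
        y += self.b.value[None, :, None]
        self._cache = (blocks, (B, C, d, h, w))
        return y.reshape(B, -1, d, h, w)

    def backward(self, gy):
        blocks, (B, C, d, h, w) = self._cache
        self._cache = None
        gyr = gy.reshape(B, gy.shape[1], -1)
        self.w.grad += np.einsum("bon,bcn->oc", gyr, blocks)
        self.b.grad += gyr.sum(axis=(0, 2))
        gblocks = np.einsum("oc,bon->bcn", self.w.value, gyr)
        gx = (
            gblocks.reshape(B, C, 2, 2, 2, d, h, w)
            .transpose(0, 1, 5, 2, 6, 3, 7, 4)
            .reshape(B, C, 2 * d, 2 * h, 2 * w)
        )
        return np.ascontiguousarray(gx)


class GlobalAvgPool(Layer):
    def __init__(self):
        self._cache = None

    def forward(self, x, *, train=False, rng=None):
        B, C = x.shape[:2]
        self._cache = x.shape
        return x.reshape(B, C, -1).mean(axis=2)

    def backward(self, gy):
        shape = self._cache
        self._cache = None
        n = int(np.prod(shape[2:]))
        gx = np.broadcast_to(
            (gy / n)[:, :, None, None, None], shape
        )
        return np.ascontiguousarray(gx, dtype=np.float32)


class Dense(Layer):
    def __init__(
        self, nin: int, nout: int, rng: np.random.Generator,
        bias_init: float = 0.0,
    ):
        std = np.sqrt(2.0 / nin)
        self.w = Param(rng.normal(0.0, std, size=(nout, nin)), decay=True)
        self.b = Param(np.full(nout, bias_init), decay=False)
        self._cache = None

    def params(self):
        yield self.w
        yield self.b

    def forward(self, x, *, train=False, rng=None):
        self._cache = x
        return x @ self.w.value.T + self.b.value[None, :]

    def backward(self, gy):
        x = self._cache
        self._cache = None
        self.w.grad += gy.T @ x
        self.b.grad += gy.sum(axis=0)
        return gy @ self.w.value


class AdamW:
    """Adam with decoupled weight decay; decay only touches Param.decay."""

    def __init__(
        self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and p.decay:
                update = update + self.weight_decay * p.value
            p.value -= np.float32(lr) * update.astype(np.float32)
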