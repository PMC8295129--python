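"""Minimal CPU conv-net framework (forward + manual backprop + Adam).

Supports exactly what the translation networks need: 2D convolution with
reflect/zero padding and stride, instance normalization, ReLU / LeakyReLU /
Tanh, nearest-neighbor upsampling, residual blocks, and a sequential
container.  Layers are pure in the sense that ``forward`` returns
``(output, cache)`` and ``backward(cache, grad_out)`` returns the input
gradient while accumulating parameter gradients, so the same network can be
applied several times inside one training step (as both cycle directions
require) without cache clashes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "InstanceNorm2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Upsample2x",
    "ResidualBlock",
    "Sequential",
    "Adam",
    "receptive_field",
]


DTYPE = np.float32


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray) -> None:
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x):  # -> (y, cache)
        raise NotImplementedError

    def backward(self, cache, dy):  # -> dx
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, NCHW layout, reflect or zero padding."""

    def __init__(self, cin, cout, k, stride=1, pad=0, pad_mode="zero", rng=None, bias=True):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad, self.pad_mode = k, stride, pad, pad_mode
        self.cin, self.cout = cin, cout
        self.W = Param(rng.normal(0.0, 0.02, size=(cin * k * k, cout)))
        self.b = Param(np.zeros(cout)) if bias else None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def _pad(self, x):
        p = self.pad
        if p == 0:
            return x
        mode = "reflect" if self.pad_mode == "reflect" else "constant"
        return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode=mode)

    def forward(self, x):
        k, s, c = self.k, self.stride, self.cin
        x = np.asarray(x, dtype=DTYPE)
        xp = self._pad(x)
        n, _, hp, wp = xp.shape
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        if ho < 1 or wo < 1:
            raise ValueError(f"input {x.shape[2:]} too small for a {k}x{k} conv after padding")
        # k^2-slice im2col in a GEMM-friendly (k, k, c, n*ho*wo) layout:
        # each (i, j) tap is one cheap strided 4D copy
        xp_t = xp.transpose(1, 0, 2, 3)  # view (c, n, hp, wp)
        cols = np.empty((k, k, c, n, ho, wo), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                cols[i, j] = xp_t[:, :, i : i + s * ho : s, j : j + s * wo : s]
        cols2 = cols.reshape(k * k * c, n * ho * wo)
        # param layout is (c*k*k, cout); rearrange once per call (small)
        w_kkc = self.W.data.reshape(c, k, k, self.cout).transpose(3, 1, 2, 0).reshape(self.cout, k * k * c)
        y2 = w_kkc @ cols2
        if self.b is not None:
            y2 += self.b.data[:, None]
        y = y2.reshape(self.cout, n, ho, wo).transpose(1, 0, 2, 3)
        return y, (cols2, x.shape, (n, ho, wo, hp, wp))

    def backward(self, cache, dy):
        cols2, x_shape, (n, ho, wo, hp, wp) = cache
        k, s, c = self.k, self.stride, self.cin
        dy = np.asarray(dy, dtype=DTYPE)
        dyf = dy.transpose(1, 0, 2, 3).reshape(self.cout, n * ho * wo)
        dw_kkc = dyf @ cols2.T  # (cout, k*k*c)
        self.W.grad += (
            dw_kkc.reshape(self.cout, k, k, c).transpose(3, 1, 2, 0).reshape(c * k * k, self.cout)
        )
        if self.b is not None:
            self.b.grad += dyf.sum(axis=1)
        w_kkc = self.W.data.reshape(c, k, k, self.cout).transpose(3, 1, 2, 0).reshape(self.cout, k * k * c)
        dcols = (w_kkc.T @ dyf).reshape(k, k, c, n, ho, wo)
        dxp = np.zeros((c, n, hp, wp), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[i, j]
        dxp = dxp.transpose(1, 0, 2, 3)
        p = self.pad
        if p == 0:
            return dxp
        if self.pad_mode != "reflect":
            return dxp[:, :, p:-p, p:-p]
        # adjoint of reflect padding: scatter-add padded rows/cols back
        h, w = x_shape[2], x_shape[3]
        idx_h = np.pad(np.arange(h), p, mode="reflect")
        idx_w = np.pad(np.arange(w), p, mode="reflect")
        dx_h = np.zeros((n, c, h, wp), dtype=DTYPE)
        np.add.at(dx_h, (slice(None), slice(None), idx_h), dxp)
        dx = np.zeros((n, c, h, w), dtype=DTYPE)
        np.add.at(dx.swapaxes(2, 3), (slice(None), slice(None), idx_w), dx_h.swapaxes(2, 3))
        return dx


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels, eps=1e-5, affine=True):
        self.eps = eps
        self.gamma = Param(np.ones(channels)) if affine else None
        self.beta = Param(np.zeros(channels)) if affine else None

    def params(self):
        return [p for p in (self.gamma, self.beta) if p is not None]

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivar
        y = xhat
        if self.gamma is not None:
            y = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        return y, (xhat, ivar)

    def backward(self, cache, dy):
        xhat, ivar = cache
        m = xhat.shape[2] * xhat.shape[3]
        if self.gamma is not None:
            self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
            self.beta.grad += dy.sum(axis=(0, 2, 3))
            dxhat = dy * self.gamma.data[None, :, None, None]
        else:
            dxhat = dy
        # standard normalization backward, spatial reduction per (n, c)
        s1 = dxhat.sum(axis=(2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(2, 3), keepdims=True)
        return ivar * (dxhat - s1 / m - xhat * s2 / m)


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, cache, dy):
        return dy * cache


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        self.slope = slope

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, cache, dy):
        return np.where(cache, dy, self.slope * dy)


class Tanh(Layer):
    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, cache, dy):
        return dy * (1.0 - cache**2)


class Upsample2x(Layer):
    """Nearest-neighbor 2x spatial upsampling."""

    def forward(self, x):
        y = x.repeat(2, axis=2).repeat(2, axis=3)
        return y, x.shape

    def backward(self, cache, dy):
        n, c, h, w = cache
        return dy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x):
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x)
            caches.append(cache)
        return x, caches

    def backward(self, caches, dy):
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(cache, dy)
        return dy

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def __call__(self, x):
        y, _ = self.forward(x)
        return y

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.params())


class ResidualBlock(Layer):
    """conv3-IN-ReLU-conv3-IN with an identity skip (reflect padding)."""

    def __init__(self, channels, rng=None):
        self.body = Sequential(
            Conv2d(channels, channels, 3, 1, 1, "reflect", rng=rng),
            InstanceNorm2d(channels),
            ReLU(),
            Conv2d(channels, channels, 3, 1, 1, "reflect", rng=rng),
            InstanceNorm2d(channels),
        )

    def params(self):
        return self.body.params()

    def forward(self, x):
        y, cache = self.body.forward(x)
        return x + y, cache

    def backward(self, cache, dy):
        return dy + self.body.backward(cache, dy)


class Adam:
    """Adam over a parameter list (beta1 = 0.5 as is conventional for
    adversarial training)."""

    def __init__(self, params: list[Param], lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


def receptive_field(layers: list[tuple[int, int]]) -> int:
    """Effective receptive field of a stack of (kernel, stride) conv layers.

    Standard recursion r_in = (r_out - 1) * stride + kernel, applied from the
    last layer back to the input with r = 1 at the output.
    """
    r = 1
    for k, s in reversed(layers):
        r = (r - 1) * s + k
    return r
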