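"""Minimal CPU neural-network layers with explicit backpropagation.

A small, self-contained layer library (conv / transposed conv / batch &
instance norm / pointwise nonlinearities / Adam) sufficient to express the
U-shape generator and patch discriminator.  Data layout is NCHW float64.
Every layer caches what its backward pass needs; ``backward`` consumes the
upstream gradient and accumulates parameter gradients in ``Param.g``.

Nothing here is clever: correctness (verified by finite-difference tests)
and determinism are the goals, and problem sizes are desk-scale.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=np.float64)
        self.g = np.zeros_like(self.v)


class Module:
    training: bool = True

    def params(self) -> list[Param]:
        return []

    def train_mode(self, flag: bool = True) -> None:
        self.training = flag
        for m in getattr(self, "children", []):
            m.train_mode(flag)

    def zero_grad(self) -> None:
        for p in self.params():
            p.g[...] = 0.0


# ---------------------------------------------------------------------------
# convolution primitives (im2col / col2im)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (n, c, ho, wo, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (n, c, h, w, ho, wo)


def _col2im(gcols: np.ndarray, shape, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w, ho, wo = shape
    gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    g = gcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            gx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += g[
                :, :, i, j
            ]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


def conv2d_fwd(x, w, b, stride, pad):
    """w: (out_ch, in_ch, k, k); returns (out, cache)."""
    oc, ic, k, _ = w.shape
    cols, shape = _im2col(x, k, stride, pad)
    out = cols @ w.reshape(oc, -1).T
    if b is not None:
        out = out + b
    n, _, _, _, ho, wo = shape
    out = out.reshape(n, ho, wo, oc).transpose(0, 3, 1, 2)
    return out, (cols, shape, w.shape, stride, pad)


class Conv2d(Module):
    """k x k strided convolution, pix2pix-style init N(0, 0.02)."""

    def __init__(self, in_ch, out_ch, k=4, stride=2, pad=1, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, 0.02, (out_ch, in_ch, k, k)))
        self.b = Param(np.zeros(out_ch)) if bias else None
        self.k, self.stride, self.pad = k, stride, pad

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x):
        out, (cols, shape, _, _, _) = conv2d_fwd(
            x, self.w.v, self.b.v if self.b else None, self.stride, self.pad
        )
        self._cache = (cols, shape)
        return out

    def backward(self, gout):
        cols, shape = self._cache
        oc = self.w.v.shape[0]
        n, c, h, w_, ho, wo = shape
        g = gout.transpose(0, 2, 3, 1).reshape(n * ho * wo, oc)
        self.w.g += (g.T @ cols).reshape(self.w.v.shape)
        if self.b is not None:
            self.b.g += g.sum(axis=0)
        if self.stride == 1:
            # input gradient of a stride-1 conv is a full correlation with
            # the spatially flipped, channel-transposed kernel — one
            # im2col+gemm instead of a 9/16-way scatter-add
            wT = self.w.v[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gx, _ = conv2d_fwd(gout, wT, None, 1, self.k - 1 - self.pad)
            return gx
        gcols = g @ self.w.v.reshape(oc, -1)
        return _col2im(gcols, shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Module):
    """Fractionally-strided convolution; exact adjoint of Conv2d.

    Weight shape (in_ch, out_ch, k, k).  Forward scatters input gradients
    the way Conv2d.backward scatters; backward is a plain convolution.
    """

    def __init__(self, in_ch, out_ch, k=4, stride=2, pad=1, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, 0.02, (in_ch, out_ch, k, k)))
        self.b = Param(np.zeros(out_ch)) if bias else None
        self.k, self.stride, self.pad = k, stride, pad

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def _out_hw(self, h, w):
        s, k, p = self.stride, self.k, self.pad
        return (h - 1) * s + k - 2 * p, (w - 1) * s + k - 2 * p

    def forward(self, x):
        n, ic, h, w_ = x.shape
        oc = self.w.v.shape[1]
        ho, wo = self._out_hw(h, w_)
        # treat x as the upstream gradient of a Conv2d(out->in): col scatter
        g = x.transpose(0, 2, 3, 1).reshape(n * h * w_, ic)
        gcols = g @ self.w.v.reshape(ic, -1)
        shape = (n, oc, ho, wo, h, w_)
        out = _col2im(gcols, shape, self.k, self.stride, self.pad)
        if self.b is not None:
            out = out + self.b.v[None, :, None, None]
        self._cache = (x, shape)
        return out

    def backward(self, gout):
        x, shape = self._cache
        n, ic, h, w_ = x.shape
        oc = self.w.v.shape[1]
        cols, _ = _im2col(gout, self.k, self.stride, self.pad)
        gin = cols @ self.w.v.reshape(ic, -1).T  # (n*h*w_, ic)
        xg = x.transpose(0, 2, 3, 1).reshape(n * h * w_, ic)
        self.w.g += (xg.T @ cols).reshape(self.w.v.shape)
        if self.b is not None:
            self.b.g += gout.sum(axis=(0, 2, 3))
        return gin.reshape(n, h, w_, ic).transpose(0, 3, 1, 2)


class Upsample2x(Module):
    """Nearest-neighbour 2x spatial upsampling; backward sums 2x2 blocks."""

    def forward(self, x):
        self._in_shape = x.shape
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gout):
        n, c, h, w = self._in_shape
        return gout.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


class _NormBase(Module):
    def __init__(self, ch, rng=None, eps=1e-5):
        rng = rng or np.random.default_rng(0)
        self.gamma = Param(rng.normal(1.0, 0.02, ch))
        self.beta = Param(np.zeros(ch))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]


class BatchNorm2d(_NormBase):
    def __init__(self, ch, rng=None, eps=1e-5, momentum=0.1):
        super().__init__(ch, rng, eps)
        self.momentum = momentum
        self.run_mean = np.zeros(ch)
        self.run_var = np.ones(ch)

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.v[None, :, None, None] * xhat + self.beta.v[None, :, None, None]

    def backward(self, gout):
        xhat, inv, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.g += (gout * xhat).sum(axis=(0, 2, 3))
        self.beta.g += gout.sum(axis=(0, 2, 3))
        gxhat = gout * self.gamma.v[None, :, None, None]
        if not self.training:
            return gxhat * inv[None, :, None, None]
        s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / m) * (m * gxhat - s1 - xhat * s2)


class InstanceNorm2d(_NormBase):
    def forward(self, x):
        mean = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, x.shape)
        return self.gamma.v[None, :, None, None] * xhat + self.beta.v[None, :, None, None]

    def backward(self, gout):
        xhat, inv, shape = self._cache
        n, c, h, w = shape
        m = h * w
        self.gamma.g += (gout * xhat).sum(axis=(0, 2, 3))
        self.beta.g += gout.sum(axis=(0, 2, 3))
        gxhat = gout * self.gamma.v[None, :, None, None]
        s1 = gxhat.sum(axis=(2, 3), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(2, 3), keepdims=True)
        return (inv / m) * (m * gxhat - s1 - xhat * s2)


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gout):
        return np.where(self._mask, gout, self.slope * gout)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(0.0)


class Tanh(Module):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gout):
        return gout * (1.0 - self._y**2)


class Sequential(Module):
    def __init__(self, *layers):
        self.children = list(layers)

    def params(self):
        return [p for m in self.children for p in m.params()]

    def forward(self, x):
        for m in self.children:
            x = m.forward(x)
        return x

    def backward(self, gout):
        for m in reversed(self.children):
            gout = m.backward(gout)
        return gout


class Adam:
    """Adam with the bias-corrected first/second moments."""

    def __init__(self, params: list[Param], lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in params]
        self.v = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.g
            v[...] = self.b2 * v + (1 - self.b2) * p.g**2
            p.v -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.g[...] = 0.0


def bce_logits(logits: np.ndarray, target: float):
    """Numerically stable binary cross-entropy from logits.

    Returns (mean loss, gradient of the mean loss w.r.t. logits).
    """
    z = logits
    loss = np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z)))
    ez = np.exp(-np.abs(z))
    sig = np.where(z >= 0, 1.0 / (1.0 + ez), ez / (1.0 + ez))
    return float(loss.mean()), (sig - target) / z.size
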