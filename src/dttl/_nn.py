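"""Minimal NumPy neural-network core used by every trainable stage.

Implements exactly the layer types the desk-scale architectures need
(dense, 3x3 convolution via im2col, ReLU, dropout, nearest-neighbour
upsampling, residual wrapping, global average pooling) with explicit
forward caches and hand-written backward passes, plus an Adam optimiser
with decoupled weight decay.  Arrays are float32 in NCHW layout for
images and (N, d) for feature vectors.

The core is deliberately small: single-threaded NumPy keeps runs
bit-reproducible for a fixed seed, and every layer's backward pass is
covered by a finite-difference gradient check in the test suite.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-7  # probability clamp applied before every log


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: forward caches whatever backward needs."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, zero_init: bool = False):
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.W = Param(w)
        self.b = Param(np.zeros(d_out))
        self._stack: list[np.ndarray] = []

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        if train:
            self._stack.append(x)
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        x = self._stack.pop()
        self.W.grad += x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    if pad:
        xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=x.dtype)
        xp[:, :, pad:-pad, pad:-pad] = x
    else:
        xp = x
    sn, sc, sh, sw = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, k, k, ho, wo),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
    )
    cols = view.transpose(0, 4, 5, 1, 2, 3).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int, ho: int, wo: int):
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    dview = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dview[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Module):
    """3x3 (or kxk) convolution, stride/pad configurable, He init."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, zero_init: bool = False):
        fan_in = c_in * k * k
        if zero_init:
            w = np.zeros((fan_in, c_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.W = Param(w)
        self.b = Param(np.zeros(c_out))
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self._stack: list[tuple] = []

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        if train:
            self._stack.append((cols, x.shape, ho, wo))
        out = cols @ self.W.value + self.b.value
        n = x.shape[0]
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, x_shape, ho, wo = self._stack.pop()
        n = dout.shape[0]
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.c_out)
        self.W.grad += cols.T @ dflat
        self.b.grad += dflat.sum(axis=0)
        dcols = dflat @ self.W.value.T
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, ho, wo)


class ReLU(Module):
    def __init__(self):
        self._stack: list[np.ndarray] = []

    def forward(self, x, train=False):
        mask = x > 0
        if train:
            self._stack.append(mask)
        return x * mask

    def backward(self, dout):
        return dout * self._stack.pop()


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Draws from its own stream."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._stack: list[np.ndarray | float] = []

    def forward(self, x, train=False):
        if train and self.p > 0:
            mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        else:
            mask = 1.0
        if train:
            self._stack.append(mask)
        return x * mask

    def backward(self, dout):
        return dout * self._stack.pop()


class Upsample2x(Module):
    """Nearest-neighbour 2x upsampling; backward sums 2x2 blocks."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class PixelShuffle2x(Module):
    """(N, 4c, H, W) -> (N, c, 2H, 2W) sub-pixel rearrangement."""

    def __init__(self):
        self._stack: list[tuple] = []

    def forward(self, x, train=False):
        n, c4, h, w = x.shape
        c = c4 // 4
        if train:
            self._stack.append(x.shape)
        return (x.reshape(n, c, 2, 2, h, w)
                 .transpose(0, 1, 4, 2, 5, 3)
                 .reshape(n, c, 2 * h, 2 * w))

    def backward(self, dout):
        n, c4, h, w = self._stack.pop()
        c = c4 // 4
        return (dout.reshape(n, c, h, 2, w, 2)
                    .transpose(0, 1, 3, 5, 2, 4)
                    .reshape(n, c4, h, w))


class GlobalAvgPool(Module):
    def __init__(self):
        self._stack: list[tuple] = []

    def forward(self, x, train=False):
        if train:
            self._stack.append(x.shape)
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        shape = self._stack.pop()
        n, c, h, w = shape
        return np.broadcast_to(dout[:, :, None, None], shape) / (h * w)


class Flatten(Module):
    def __init__(self):
        self._stack: list[tuple] = []

    def forward(self, x, train=False):
        if train:
            self._stack.append(x.shape)
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._stack.pop())


class SpatialMean(Module):
    """(N, 1, H, W) patch map -> (N,) scalar logit."""

    def __init__(self):
        self._stack: list[tuple] = []

    def forward(self, x, train=False):
        if train:
            self._stack.append(x.shape)
        return x.mean(axis=(1, 2, 3))

    def backward(self, dout):
        shape = self._stack.pop()
        n, c, h, w = shape
        return np.broadcast_to(dout[:, None, None, None], shape) / (c * h * w)


class Residual(Module):
    def __init__(self, *inner: Module):
        self.inner = list(inner)

    def params(self):
        return [p for m in self.inner for p in m.params()]

    def forward(self, x, train=False):
        out = x
        for m in self.inner:
            out = m.forward(out, train=train)
        return x + out

    def backward(self, dout):
        d = dout
        for m in reversed(self.inner):
            d = m.backward(d)
        return dout + d


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self):
        return [p for m in self.layers for p in m.params()]

    def forward(self, x, train=False):
        for m in self.layers:
            x = m.forward(x, train=train)
        return x

    def backward(self, dout):
        for m in reversed(self.layers):
            dout = m.backward(dout)
        return dout


class Adam:
    """Adam with decoupled weight decay (applied to the raw parameter)."""

    def __init__(self, params: list[Param], lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.wd:
                update = update + self.wd * p.value
            p.value -= (self.lr * update).astype(np.float32)


# ---------------------------------------------------------------------------
# numerically-safe probability helpers


def clamp_prob(p: np.ndarray | float) -> np.ndarray:
    """Clamp probabilities to [EPS, 1-EPS] before any log."""
    return np.clip(np.asarray(p, dtype=np.float64), EPS, 1.0 - EPS)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def numerical_gradient(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central finite differences; test-support utility."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + h
        fp = f()
        x[i] = orig - h
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * h)
        it.iternext()
    return g
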