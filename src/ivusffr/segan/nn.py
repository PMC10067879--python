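"""Minimal reverse-mode autodiff on numpy arrays.

Just enough machinery for a small convolutional encoder-decoder and its
adversary to be trained on CPU: tensors with taped gradients, im2col
convolution, nearest-neighbour upsampling, leaky ReLU, sigmoid, channel
concatenation, elementwise arithmetic and an L1 reduction, plus Adam.
float32 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "leaky_relu", "sigmoid", "upsample2", "concat", "l1_mean", "Adam"]


class Tensor:
    """An array plus the tape entry needed to backpropagate through it."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in self.parents)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"

    # -- graph walk -------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() only from a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if self.requires_grad and self.grad is not None:
            self.grad += g

    # -- arithmetic -------------------------------------------------------
    def __mul__(self, other):
        if isinstance(other, Tensor):
            a, b = self, other

            def bw(g):
                a._accum(g * b.data)
                b._accum(g * a.data)

            return Tensor(a.data * b.data, (a, b), bw)
        c = float(other)

        def bw(g):
            self._accum(g * c)

        return Tensor(self.data * c, (self,), bw)

    __rmul__ = __mul__

    def __add__(self, other):
        if not isinstance(other, Tensor):
            other = Tensor(np.asarray(other, dtype=np.float32))
        a, b = self, other

        def bw(g):
            a._accum(g if g.shape == a.data.shape else _unbroadcast(g, a.data.shape))
            b._accum(g if g.shape == b.data.shape else _unbroadcast(g, b.data.shape))

        return Tensor(a.data + b.data, (a, b), bw)

    def __sub__(self, other):
        return self + (other * -1.0 if isinstance(other, Tensor) else -other)

    def __neg__(self):
        return self * -1.0

    def item(self) -> float:
        return float(self.data)


def _unbroadcast(g, shape):
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- convolution ---------------------------------------------------------

def _im2col(x, kh, kw, stride, pad):
    n, c, h, w = x.shape
    hp = (h + 2 * pad - kh) // stride + 1
    wp = (w + 2 * pad - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    sn, sc, sh, sw = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, (n, c, kh, kw, hp, wp), (sn, sc, sh, sw, sh * stride, sw * stride)
    )
    return np.ascontiguousarray(cols).reshape(n, c * kh * kw, hp * wp), hp, wp


def _col2im(dcols, xshape, kh, kw, stride, pad, hp, wp):
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    dcols = dcols.reshape(n, c, kh, kw, hp, wp)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * hp : stride, j : j + stride * wp : stride] += dcols[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution, NCHW layout; w is (F, C, kh, kw), b is (F,)."""
    f, c, kh, kw = w.shape
    n = x.shape[0]
    cols, hp, wp = _im2col(x.data, kh, kw, stride, pad)
    wm = w.data.reshape(f, c * kh * kw)
    out = (wm @ cols).reshape(n, f, hp, wp) + b.data.reshape(1, f, 1, 1)

    def bw(g):
        gm = np.ascontiguousarray(g.reshape(n, f, hp * wp), dtype=np.float32)
        if b.requires_grad:
            b._accum(gm.sum(axis=(0, 2)))
        if w.requires_grad:
            dw = np.tensordot(gm, cols, axes=([0, 2], [0, 2]))
            w._accum(dw.reshape(w.data.shape))
        if x.requires_grad:
            dcols = wm.T @ gm  # (c*kh*kw, f) @ (n, f, p) -> (n, c*kh*kw, p)
            x._accum(_col2im(dcols, x.data.shape, kh, kw, stride, pad, hp, wp))

    return Tensor(out, (x, w, b), bw)


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, alpha * x.data)

    def bw(g):
        x._accum(g * np.where(mask, 1.0, alpha).astype(np.float32))

    return Tensor(out, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-np.clip(x.data, -30.0, 30.0)))

    def bw(g):
        x._accum(g * out * (1.0 - out))

    return Tensor(out, (x,), bw)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        n, c, h, w = x.data.shape
        x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor(out, (x,), bw)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, gp in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(gp)

    return Tensor(out, tensors, bw)


def l1_mean(a: Tensor, b: Tensor) -> Tensor:
    """Mean absolute difference, averaged over every element."""
    if a.data.shape != b.data.shape:
        raise ValueError("shape mismatch in l1_mean")
    d = a.data - b.data
    sign = np.sign(d) / d.size

    def bw(g):
        a._accum(g * sign)
        b._accum(-g * sign)

    return Tensor(np.abs(d).mean(), (a, b), bw)


class Adam:
    """Adam on a list of parameter Tensors; set maximize=True for ascent."""

    def __init__(self, params, lr=2e-4, betas=(0.5, 0.999), eps=1e-8, maximize=False):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.maximize = lr, betas, eps, maximize
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            if self.maximize:
                g = -g
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
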