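"""Tape-based reverse-mode autodiff on numpy arrays (NCHW layout)."""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "conv2d", "batchnorm2d", "relu", "sigmoid",
    "upsample2x", "concat_channels",
]


class Tensor:
    """A float32 array plus the closure that propagates its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # -- elementwise arithmetic (scalars or same-shape tensors) -------------
    def __add__(self, other):
        other = _wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    def __sub__(self, other):
        other = _wrap(other)
        out = Tensor(self.data - other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g), other._accum(-g))
        return out

    def __rsub__(self, other):
        return _wrap(other) - self

    def __mul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g * other.data), other._accum(g * self.data))
        return out

    __radd__ = __add__
    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def back(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data ** 2))

        out._backward = back
        return out

    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g, self.data.shape))
        return out

    def square(self):
        out = Tensor(self.data ** 2, parents=(self,))
        out._backward = lambda g: self._accum(2.0 * g * self.data)
        return out


def _wrap(x):
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float32))


# ---------------------------------------------------------------------------
# convolution

def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad=None) -> Tensor:
    """2D convolution, weights (Cout, Cin, k, k).

    Default padding keeps 'same'-style sizes: k=3 -> 1 each side, k=1 -> 0,
    k=2 -> (0, 1) asymmetric.  Output spatial size is (H + pl + pr - k)//stride + 1.

    Implemented as a shift-accumulate: one full-grid matmul contracts the
    channel dimension for all k² kernel offsets at once (no im2col copies),
    and the k² partial products are added at their spatial shifts.  This
    keeps all BLAS operands contiguous, which matters on a single CPU core.
    """
    cout, cin, k, _ = w.data.shape
    if pad is None:
        pad = {3: (1, 1), 2: (0, 1), 1: (0, 0)}[k]
    pl, pr = pad
    n, c, h, wid = x.data.shape
    assert c == cin, f"channel mismatch {c} vs {cin}"
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr), (pl, pr))) if (pl or pr) else x.data
    hp, wp = xp.shape[2], xp.shape[3]
    oh = (h + pl + pr - k) // stride + 1
    ow = (wid + pl + pr - k) // stride + 1
    offsets = [(i, j) for i in range(k) for j in range(k)]

    # z[idx] = W_offset @ x over the full padded grid; y[p] = Σ z[idx][s·p+δ]
    wmat = w.data.transpose(2, 3, 0, 1).reshape(k * k * cout, cin)
    z = np.matmul(wmat, xp.reshape(n, cin, hp * wp)).reshape(n, k * k, cout, hp, wp)
    y = np.zeros((n, cout, oh, ow), dtype=np.float32)
    for idx, (i, j) in enumerate(offsets):
        y += z[:, idx, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
    del z
    if b is not None:
        y += b.data.reshape(1, cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def back(g):
        gmat = g.reshape(n, cout, oh * ow)
        if w.requires_grad:
            dw = np.empty((k * k, cout, cin), dtype=np.float32)
            for idx, (i, j) in enumerate(offsets):
                xs = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
                dw[idx] = np.einsum("nohw,nchw->oc", g, xs, optimize=True)
            w._accum(dw.reshape(k, k, cout, cin).transpose(2, 3, 0, 1))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            wt = w.data.transpose(2, 3, 1, 0).reshape(k * k * cin, cout)
            dz = np.matmul(wt, gmat).reshape(n, k * k, cin, oh, ow)
            dxp = np.zeros_like(xp)
            for idx, (i, j) in enumerate(offsets):
                dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += dz[:, idx]
            dx = dxp[:, :, pl:pl + h, pl:pl + wid] if (pl or pr) else dxp
            x._accum(dx)

    out._backward = back
    return out


# ---------------------------------------------------------------------------
# normalization and activations

def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running, training: bool,
                momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    ``running`` is a dict with 'mean' and 'var' float32 arrays, updated in
    place during training and used verbatim in eval mode.
    """
    axes = (0, 2, 3)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mu, var = running["mean"], running["var"]
    std = np.sqrt(var + eps).astype(np.float32)
    xhat = (x.data - mu.reshape(1, -1, 1, 1)) / std.reshape(1, -1, 1, 1)
    y = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)
    out = Tensor(y, parents=(x, gamma, beta))

    def back(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gs = gamma.data.reshape(1, -1, 1, 1) / std.reshape(1, -1, 1, 1)
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                gmean = g.mean(axis=axes).reshape(1, -1, 1, 1)
                gxhat = (g * xhat).mean(axis=axes).reshape(1, -1, 1, 1)
                x._accum(gs * (g - gmean - xhat * gxhat))
            else:
                x._accum(gs * g)

    out._backward = back
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda g: x._accum(g * mask)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -30, 30)))
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: x._accum(g * s * (1.0 - s))
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x spatial upsampling."""
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor(y, parents=(x,))

    def back(g):
        n, c, h2, w2 = g.shape
        x._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    out._backward = back
    return out


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    out = Tensor(np.concatenate([a.data, b.data], axis=1), parents=(a, b))

    def back(g):
        a._accum(g[:, :ca])
        b._accum(g[:, ca:])

    out._backward = back
    return out
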