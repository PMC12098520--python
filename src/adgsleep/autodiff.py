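"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The network in this package (convolutional residual channel-attention
blocks, a bidirectional GRU, a gradient reversal layer and two softmax
heads) needs gradients through a graph with skip connections and a
sign-flipping branch.  This module provides exactly the operation set the
model uses — nothing more — as a tape-based autodiff on ``float32``
ndarrays, plus an Adam optimizer.

Design notes
------------
* Every op builds a closure that accumulates gradients into its parents'
  ``grad`` buffers.  ``Tensor.backward()`` runs the closures in reverse
  topological order.
* Broadcasting follows NumPy semantics; gradients are summed back over
  broadcast axes (``_unbroadcast``).
* Inference runs under :func:`no_grad`, which skips tape construction so
  large forward passes hold no intermediate state.
* Convolutions are im2col: ``sliding_window_view`` + one matmul forward,
  a strided scatter-add backward.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A float32 ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g.astype(np.float32, copy=False)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    return _make(data, (a, b), backward)


def relu(x) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    data = np.where(mask, x.data, 0.0).astype(np.float32)

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return _make(data, (x,), backward)


def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    # numerically stable logistic: exp of a non-positive argument only
    pos = x.data >= 0
    e = np.exp(np.where(pos, -x.data, x.data))
    data = np.where(pos, 1.0 / (1.0 + e), e / (1.0 + e)).astype(np.float32)

    def backward(g):
        if x.requires_grad:
            x._accum(g * data * (1.0 - data))

    return _make(data, (x,), backward)


def tanh(x) -> Tensor:
    x = as_tensor(x)
    data = np.tanh(x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(g * (1.0 - data * data))

    return _make(data, (x,), backward)


def safe_log(x, eps: float = 1e-12) -> Tensor:
    """log(max(x, eps)); the gradient is zero where the clamp engages."""
    x = as_tensor(x)
    mask = x.data > eps
    clipped = np.maximum(x.data, eps)
    data = np.log(clipped)

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask / clipped)

    return _make(data, (x,), backward)


def mean(x, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    data = x.data.mean(axis=axis, keepdims=keepdims)
    n = x.data.size if axis is None else np.prod(
        [x.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )

    def backward(g):
        if not x.requires_grad:
            return
        g = np.asarray(g)
        if not keepdims and axis is not None:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for a in sorted(a % x.ndim for a in axes):
                g = np.expand_dims(g, a)
        x._accum(np.broadcast_to(g / n, x.shape).astype(np.float32))

    return _make(np.asarray(data, dtype=np.float32), (x,), backward)


def tsum(x, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not x.requires_grad:
            return
        g = np.asarray(g)
        if not keepdims and axis is not None:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for a in sorted(a % x.ndim for a in axes):
                g = np.expand_dims(g, a)
        x._accum(np.broadcast_to(g, x.shape).astype(np.float32))

    return _make(np.asarray(data, dtype=np.float32), (x,), backward)


def reshape(x, shape) -> Tensor:
    x = as_tensor(x)
    data = x.data.reshape(shape)

    def backward(g):
        if x.requires_grad:
            x._accum(g.reshape(x.shape))

    return _make(data, (x,), backward)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return _make(data, tuple(ts), backward)


def take(x, index, axis: int) -> Tensor:
    """Select one slice along ``axis`` (used for GRU time steps)."""
    x = as_tensor(x)
    data = np.take(x.data, index, axis=axis)

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            idx = [slice(None)] * x.ndim
            idx[axis] = index
            full[tuple(idx)] = g
            x._accum(full)

    return _make(data, (x,), backward)


def softmax(x, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * data).sum(axis=axis, keepdims=True)
            x._accum(data * (g - dot))

    return _make(data, (x,), backward)


def grl(x, lam: float) -> Tensor:
    """Gradient reversal layer: identity forward, gradient × (−λ) backward."""
    x = as_tensor(x)
    if lam < 0:
        raise ValueError(f"GRL weight must be >= 0, got {lam}")
    data = x.data.copy()

    def backward(g):
        if x.requires_grad:
            x._accum(-lam * g)

    return _make(data, (x,), backward)


# ---------------------------------------------------------------------------
# spatial ops
# ---------------------------------------------------------------------------

def _same_pad(size: int, k: int, s: int) -> tuple[int, int]:
    out = -(-size // s)  # ceil
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


def conv2d(x, w, b=None, stride: int = 1) -> Tensor:
    """2-D convolution, NHWC layout, 'same' zero padding.

    x: (N, H, W, Cin); w: (kh, kw, Cin, Cout); b: (Cout,) or None.
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    n, h, wdt, cin = x.shape
    kh, kw, cin_w, cout = w.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, kernel {cin_w}")
    pt, pb = _same_pad(h, kh, stride)
    pl, pr = _same_pad(wdt, kw, stride)
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    # win: (N, Ho, Wo, Cin, kh, kw) -> cols (N*Ho*Wo, kh*kw*Cin)
    ho, wo = win.shape[1], win.shape[2]
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * ho * wo, kh * kw * cin
    )
    wmat = w.data.reshape(kh * kw * cin, cout)
    out = cols @ wmat
    if b is not None:
        out = out + b.data
    out = out.reshape(n, ho, wo, cout)

    def backward(g):
        gflat = g.reshape(n * ho * wo, cout)
        if w.requires_grad:
            w._accum((cols.T @ gflat).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(gflat.sum(axis=0))
        if x.requires_grad:
            dcols = (gflat @ wmat.T).reshape(n, ho, wo, kh, kw, cin)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i : i + ho * stride : stride,
                        j : j + wo * stride : stride, :] += dcols[:, :, :, i, j, :]
            x._accum(dxp[:, pt : pt + h, pl : pl + wdt, :])

    parents = (x, w) if b is None else (x, w, b)
    return _make(out.astype(np.float32), parents, backward)


def upsample2(x) -> Tensor:
    """Nearest-neighbour 2× spatial upsampling, NHWC."""
    x = as_tensor(x)
    data = x.data.repeat(2, axis=1).repeat(2, axis=2)

    def backward(g):
        if x.requires_grad:
            n, h2, w2, c = g.shape
            x._accum(g.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4)))

    return _make(data, (x,), backward)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with conventional moments (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 2e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 frozen: Iterable[str] = ()):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.frozen = set(frozen)
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, p in self.params.items():
            if k in self.frozen or p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
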