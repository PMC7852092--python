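"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the substrate for the dual-attention network: a tape of
:class:`Tensor` nodes, each holding an ndarray and a closure that
propagates the upstream gradient to its parents.  Only the operations the
network needs are provided (elementwise arithmetic, matmul, activations,
softmax, reductions, slicing/concat, 1-D convolution and max-pooling).

Gradients are accumulated in ``float64``.  ``no_grad()`` disables tape
construction for inference-only passes.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables gradient-tape construction."""
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
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff tape wrapping a float ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers ------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the tape."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None


def _make(data: np.ndarray, parents: Iterable[Tensor], backward) -> Tensor:
    parents = tuple(p for p in parents)
    requires = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    if not requires:
        return Tensor(data)
    return Tensor(data, requires_grad=True, _parents=parents, _backward=backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise arithmetic --------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(-g)

    return _make(-a.data, (a,), backward)


def sub(a, b) -> Tensor:
    return add(as_tensor(a), neg(as_tensor(b)))


def scale(a: Tensor, c: float) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * c)

    return _make(a.data * c, (a,), backward)


# -- matmul ------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.matmul(a.data, b.data)

    def backward(g):
        if a.requires_grad:
            if b.data.ndim == 1:
                ga = np.multiply.outer(g, b.data) if g.ndim else g * b.data
            else:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            if a.data.ndim == 1:
                gb = np.multiply.outer(a.data, g)
            else:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


# -- activations -------------------------------------------------------------

def sigmoid(a: Tensor) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    a = as_tensor(a)
    t = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - t * t))

    return _make(t, (a,), backward)


def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def log(a: Tensor, eps: float = 0.0) -> Tensor:
    a = as_tensor(a)
    out = np.log(a.data + eps)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / (a.data + eps))

    return _make(out, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (max-subtraction)."""
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            inner = (g * s).sum(axis=axis, keepdims=True)
            a._accumulate(s * (g - inner))

    return _make(s, (a,), backward)


# -- reductions and reshaping ------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(out, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return scale(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a: Tensor, shape) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    a = as_tensor(a)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), backward)


def getitem(a: Tensor, idx) -> Tensor:
    """Basic (slice/int) indexing; backward scatters into a zero tensor."""
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[idx] += g
            a._accumulate(full)

    return _make(a.data[idx], (a,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(out, tuple(tensors), backward)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    take_a = a.data >= b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * take_a, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * ~take_a, b.data.shape))

    return _make(np.where(take_a, a.data, b.data), (a, b), backward)


# -- network-specific primitives ---------------------------------------------

def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid 1-D convolution (cross-correlation), stride 1.

    x: (B, L, C); w: (K, C, F); b: (F) -> (B, L-K+1, F)
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    B, L, C = x.data.shape
    K, _, F = w.data.shape
    Lout = L - K + 1
    windows = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=1)
    # windows: (B, Lout, C, K) -> (B, Lout, K*C) matching w.reshape(K*C, F)
    col = np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(B, Lout, K * C)
    wmat = w.data.reshape(K * C, F)
    out = col @ wmat + b.data

    def backward(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1)))
        if w.requires_grad:
            gw = np.einsum("blm,blf->mf", col, g)
            w._accumulate(gw.reshape(K, C, F))
        if x.requires_grad:
            gcol = (g @ wmat.T).reshape(B, Lout, K, C)
            gx = np.zeros_like(x.data)
            for k in range(K):
                gx[:, k : k + Lout, :] += gcol[:, :, k, :]
            x._accumulate(gx)

    return _make(out, (x, w, b), backward)


def maxpool1d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max-pooling along the length axis; trailing
    positions that do not fill a window are dropped."""
    x = as_tensor(x)
    B, L, C = x.data.shape
    Lout = L // pool
    trimmed = x.data[:, : Lout * pool, :].reshape(B, Lout, pool, C)
    arg = trimmed.argmax(axis=2)
    out = trimmed.max(axis=2)

    def backward(g):
        if x.requires_grad:
            gx = np.zeros((B, Lout, pool, C), dtype=np.float64)
            bi, li, ci = np.ogrid[:B, :Lout, :C]
            gx[bi, li, arg, ci] = g
            full = np.zeros_like(x.data)
            full[:, : Lout * pool, :] = gx.reshape(B, Lout * pool, C)
            x._accumulate(full)

    return _make(out, (x,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate == 0."""
    if rate <= 0.0:
        return x
    x = as_tensor(x)
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return _make(x.data * mask, (x,), backward)
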