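"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the graph-transformer denoiser and the
training loss need: broadcasting arithmetic, batched matmul, reductions,
softmax, layer-norm building blocks and fancy indexing.  Everything runs in
float64 on CPU; graphs are built define-by-run and freed after ``backward``.

Constants (inputs, noise tables, one-hot data) are wrapped with
``requires_grad=False`` and are pruned from the tape, so a forward pass over
frozen parameters records nothing.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "no_grad"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._prev = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, prev, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(prev)
            out._backward = backward
        return out

    def _accum(self, g):
        # gradients are never mutated in place, so aliasing is safe
        if self.grad is None:
            self.grad = np.asarray(g)
        else:
            self.grad = self.grad + g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
            node._backward = None
            node._prev = ()

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), bw)

    def __pow__(self, p: float):
        out_data = self.data**p

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, other.data.swapaxes(-1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(self.data.swapaxes(-1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0.0

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bw)

    def clamp_min(self, floor: float):
        """Lower clamp; gradient is blocked on clamped entries."""
        mask = self.data > floor

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(np.maximum(self.data, floor), (self,), bw)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def swapaxes(self, a: int, b: int):
        def bw(g):
            self._accum(g.swapaxes(a, b))

        return Tensor._make(self.data.swapaxes(a, b), (self,), bw)

    def broadcast_to(self, shape):
        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))

        return Tensor._make(np.broadcast_to(self.data, shape).copy(), (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), bw)

    # -- softmax -----------------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))

        return Tensor._make(s, (self,), bw)

    # -- misc --------------------------------------------------------------
    def item(self) -> float:
        return float(self.data)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    return Tensor._make(out_data, tuple(tensors), bw)
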