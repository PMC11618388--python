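"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a ``float32`` ndarray together with an optional
gradient and a backward closure.  Calling :meth:`Tensor.backward` on a scalar
loss walks the recorded graph in reverse topological order and accumulates
gradients into every reachable tensor with ``requires_grad=True``.

Only the operations the detector actually needs are implemented; each one
carries a hand-written backward rule (see :mod:`ginsengdet.nn.functional`
for the layer-level fused ops such as convolution and batch normalisation).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer to our reflected operators
    __array_priority__ = 1000
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype != np.float64:
            arr = arr.astype(np.float32, copy=False)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=self.data.dtype).reshape(self.shape).copy()
        else:
            self.grad += g.reshape(self.shape)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def numpy(self):
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        o = as_tensor(other)
        out_data = self.data + o.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g, o.shape))

        return Tensor._make(out_data, (self, o), bw)

    __radd__ = __add__

    def __sub__(self, other):
        o = as_tensor(other)
        out_data = self.data - o.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g, o.shape))

        return Tensor._make(out_data, (self, o), bw)

    def __rsub__(self, other):
        return as_tensor(other).__sub__(self)

    def __mul__(self, other):
        o = as_tensor(other)
        out_data = self.data * o.data
        a_data, b_data = self.data, o.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * b_data, self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * a_data, o.shape))

        return Tensor._make(out_data, (self, o), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = as_tensor(other)
        out_data = self.data / o.data
        a_data, b_data = self.data, o.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / b_data, self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g * a_data / (b_data * b_data), o.shape))

        return Tensor._make(out_data, (self, o), bw)

    def __rtruediv__(self, other):
        return as_tensor(other).__truediv__(self)

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __pow__(self, p: float):
        out_data = self.data ** p
        x = self.data

        def bw(g):
            self._accum(g * p * x ** (p - 1))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        o = as_tensor(other)
        out_data = np.matmul(self.data, o.data)
        a, b = self.data, o.data

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if o.requires_grad:
                gb = np.matmul(np.swapaxes(a, -1, -2), g)
                o._accum(_unbroadcast(gb, o.shape))

        return Tensor._make(out_data, (self, o), bw)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = np.ascontiguousarray(self.data.transpose(axes))

        def bw(g):
            self._accum(g.transpose(tuple(inv)))

        return Tensor._make(out_data, (self,), bw)

    def narrow(self, axis: int, start: int, length: int):
        """Contiguous slice along one axis (autodiff-aware)."""
        idx = [slice(None)] * self.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)
        out_data = self.data[idx]
        shape = self.shape

        def bw(g):
            full = np.zeros(shape, dtype=g.dtype)
            full[idx] = g
            self._accum(full)

        return Tensor._make(np.ascontiguousarray(out_data), (self,), bw)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, shape))

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = 1
            for a in axes:
                n *= self.shape[a]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float32))
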