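"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operator set the model needs: broadcasting arithmetic,
matmul, elementwise nonlinearities, reductions, reshaping/indexing,
2-D convolution and bilinear grid sampling.  Gradients accumulate into
``Tensor.grad`` after calling :meth:`Tensor.backward` on a scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "as_tensor", "concat", "stack", "maximum",
           "minimum", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = (requires_grad or any(p.requires_grad for p in parents)) \
            and _GRAD_ENABLED
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # ------------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(-g * self.data / other.data**2, other.data.shape)

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * p * self.data ** (p - 1)

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self.grad += _unbroadcast(ga, self.data.shape)
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other.grad += _unbroadcast(gb, other.data.shape)

        out._backward = bwd
        return out

    # -- elementwise ---------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * out.data

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g / self.data

        out._backward = bwd
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * 0.5 / np.maximum(out.data, 1e-30)

        out._backward = bwd
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * (1.0 - out.data**2)

        out._backward = bwd
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * out.data * (1.0 - out.data)

        out._backward = bwd
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * (self.data > 0)

        out._backward = bwd
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * np.sign(self.data)

        out._backward = bwd
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, self.data.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g.reshape(self.data.shape)

        out._backward = bwd
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                inv = np.argsort(axes) if axes else None
                self.grad += g.transpose(inv)

        out._backward = bwd
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            if self.requires_grad:
                np.add.at(self.grad, idx, g)

        out._backward = bwd
        return out

    # -- composite helpers --------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self - self.data.max(axis=axis, keepdims=True)  # constant shift
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def softplus(self):
        # log(1 + e^x), numerically stable: max(x,0) + log1p(exp(-|x|))
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        out = Tensor(out_data, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g / (1.0 + np.exp(-self.data))

        out._backward = bwd
        return out


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]

    out._backward = bwd
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t.grad += np.take(g, i, axis=axis)

    out._backward = bwd
    return out


def maximum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(np.maximum(a.data, b.data), parents=(a, b))

    def bwd(g):
        mask = a.data >= b.data  # ties route to the first argument
        if a.requires_grad:
            a.grad += _unbroadcast(g * mask, a.data.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g * ~mask, b.data.shape)

    out._backward = bwd
    return out


def minimum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(np.minimum(a.data, b.data), parents=(a, b))

    def bwd(g):
        mask = a.data <= b.data
        if a.requires_grad:
            a.grad += _unbroadcast(g * mask, a.data.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g * ~mask, b.data.shape)

    out._backward = bwd
    return out
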