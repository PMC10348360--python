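"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The encoder in this package is a small transformer trained on desk-scale
molecule sets, so a compact tape-based autodiff with the dozen primitives a
post-norm transformer needs (matmul, softmax building blocks, layer-norm
building blocks, embedding gather, arccos/atan2 for geometry losses) is the
whole numerical core.  All tensors are float64 for tight agreement with the
brute-force oracles used in the test suite.

Only the operations actually used by the model are implemented; each primitive
stores a closure computing vector-Jacobian products for its parents.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "stack", "no_grad", "is_grad_enabled"]

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


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=np.float64)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad = None
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data)
        out.requires_grad = req
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        topo, visited = [], set()
        stack = [self]
        while stack:
            node = stack[-1]
            if id(node) in visited:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in visited]
            if unvisited:
                stack.extend(unvisited)
            else:
                visited.add(id(node))
                topo.append(node)
                stack.pop()
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                if node.requires_grad:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = grads[key] + pg if key in grads else pg

    # -------------------------------------------------------------- arithmetic
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other
        return Tensor._make(
            a.data + b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        return Tensor._make(
            a.data * b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other
        return Tensor._make(
            a.data / b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g / b.data, a.data.shape),
                _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        a = self
        return Tensor._make(
            a.data ** p, (a,), lambda g: (g * p * a.data ** (p - 1),)
        )

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # ------------------------------------------------------------- elementwise
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g * out_data,))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g * 0.5 / out_data,))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: (g * mask,))

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(out_data, (a,), lambda g: (g * out_data * (1 - out_data),))

    def arccos(self):
        a = self
        return Tensor._make(
            np.arccos(a.data),
            (a,),
            lambda g: (-g / np.sqrt(np.maximum(1.0 - a.data ** 2, 1e-12)),),
        )

    def atan2(self, other):
        """Elementwise atan2(self, other) — self is y, other is x."""
        other = self._coerce(other)
        y, x = self, other
        denom = y.data ** 2 + x.data ** 2

        def backward(g):
            return (
                _unbroadcast(g * x.data / denom, y.data.shape),
                _unbroadcast(-g * y.data / denom, x.data.shape),
            )

        return Tensor._make(np.arctan2(y.data, x.data), (y, x), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.data.shape).copy(),)
            g2 = g
            if not keepdims:
                g2 = np.expand_dims(g2, axis)
            return (np.broadcast_to(g2, a.data.shape).copy(),)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---------------------------------------------------------------- shaping
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(
            a.data.reshape(shape), (a,), lambda g: (g.reshape(a.data.shape),)
        )

    def transpose(self, *axes):
        a = self
        if not axes:
            axes = tuple(range(a.data.ndim))[::-1]
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),)
        )

    def swapaxes(self, ax1, ax2):
        a = self
        return Tensor._make(
            np.swapaxes(a.data, ax1, ax2),
            (a,),
            lambda g: (np.swapaxes(g, ax1, ax2),),
        )

    def __getitem__(self, idx):
        a = self

        def backward(g):
            out = np.zeros_like(a.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(a.data[idx], (a,), backward)

    def softmax(self, axis=-1):
        """Numerically stable softmax along `axis`."""
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis=-1, keepdims=False):
        m = Tensor(self.data.max(axis=axis, keepdims=True))
        out = ((self - m).exp().sum(axis=axis, keepdims=True)).log() + m
        if not keepdims:
            out = out.reshape(tuple(np.delete(out.data.shape, axis)))
        return out


class Parameter(Tensor):
    """A leaf tensor that is always trainable."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # trainable even if created under no_grad


def concat(tensors, axis=-1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        outs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            outs.append(g[tuple(sl)])
        return tuple(outs)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def stack(tensors, axis=0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]

    def backward(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return Tensor._make(
        np.stack([t.data for t in tensors], axis=axis), tensors, backward
    )
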