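"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports the small operator set needed by the graph models in this package:
broadcasting arithmetic, (batched) matrix products, row-softmax, smooth
nonlinearities, reductions, concatenation and slicing.  Gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward` via a topological
sweep.  Everything is float64 for reproducibility across platforms.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "glorot", "set_param_data"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None,
                 name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def _needs(self, *others):
        return self.requires_grad or any(o.requires_grad for o in others)

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
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, self._needs(other), (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(g)
            if other.requires_grad or other._parents:
                other._accum(g)
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad or bool(self._parents), (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, self._needs(other), (self, other))

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, self._needs(other), (self, other))

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data ** 2))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, self._needs(other), (self, other))

        def bw(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)
        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad or bool(self._parents), (self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    # ------------------------------------------------------------- elementwise
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad or bool(self._parents), (self,))
        out._backward = lambda g: self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad or bool(self._parents), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, self.requires_grad or bool(self._parents), (self,))
        out._backward = lambda g: self._accum(g * (1.0 - val ** 2))
        return out

    def relu(self):
        val = np.maximum(self.data, 0.0)
        out = Tensor(val, self.requires_grad or bool(self._parents), (self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, self.requires_grad or bool(self._parents), (self,))
        out._backward = lambda g: self._accum(g * val * (1.0 - val))
        return out

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        val = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(val, self.requires_grad or bool(self._parents), (self,))

        def bw(g):
            dot = (g * val).sum(axis=axis, keepdims=True)
            self._accum(val * (g - dot))
        out._backward = bw
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad or bool(self._parents), (self,))

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis if isinstance(axis, int) else tuple(axis))
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        val = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor(val, self.requires_grad or bool(self._parents), (self,))

        def bw(g):
            g = np.asarray(g)
            vk = self.data.max(axis=axis, keepdims=True)
            mask = (self.data == vk)
            mask = mask / mask.sum(axis=axis, keepdims=True)  # split ties
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(mask * g)
        out._backward = bw
        return out

    # ---------------------------------------------------------------- reshapes
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad or bool(self._parents), (self,))
        out._backward = lambda g: self._accum(np.asarray(g).reshape(self.data.shape))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b),
                     self.requires_grad or bool(self._parents), (self,))
        out._backward = lambda g: self._accum(np.swapaxes(np.asarray(g), a, b))
        return out

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad or bool(self._parents), (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = bw
        return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad or t._parents for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(np.asarray(g), splits, axis=axis)):
            t._accum(piece)
    out._backward = bw
    return out


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    """Glorot-uniform initialised parameter tensor."""
    if shape is None:
        shape = (fan_in, fan_out)
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def set_param_data(param: Tensor, data: np.ndarray) -> None:
    param.data = np.asarray(data, dtype=np.float64).reshape(param.data.shape)


class Adam:
    """Adam over a list of parameter tensors; skips frozen (requires_grad=False) ones."""

    def __init__(self, params, lr: float = 1e-2, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self.t)
            vhat = self._v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
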