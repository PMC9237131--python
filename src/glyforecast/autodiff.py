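"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the recurrent network, the attention block and the
evidential negative log-likelihood: broadcast-aware elementwise arithmetic,
matmul, the activations used by the model, reductions, concatenation and
log-gamma. Gradients are accumulated by a topologically ordered backward
sweep. Correctness is enforced by finite-difference checks in the test suite.
"""
from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln as _gammaln_np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach ``grad.shape``."""
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
    __slots__ = ("value", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, value, parents=(), backward=None, requires_grad=True):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.value.shape

    # -- graph bookkeeping ---------------------------------------------------
    def backward(self, grad=None):
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.value) if grad is None else np.asarray(grad, float)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, contrib in node._backward(node.grad):
                if not parent.requires_grad:
                    continue
                c = _unbroadcast(np.asarray(contrib), parent.value.shape)
                parent.grad = c if parent.grad is None else parent.grad + c

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        o = as_tensor(other)
        return Tensor(self.value + o.value, (self, o),
                      lambda g: ((self, g), (o, g)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, (self,), lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        o = as_tensor(other)
        return Tensor(self.value * o.value, (self, o),
                      lambda g: ((self, g * o.value), (o, g * self.value)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = as_tensor(other)
        return Tensor(self.value / o.value, (self, o),
                      lambda g: ((self, g / o.value),
                                 (o, -g * self.value / o.value**2)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        return Tensor(self.value ** p, (self,),
                      lambda g: ((self, g * p * self.value ** (p - 1)),))

    def __matmul__(self, other):
        o = as_tensor(other)
        return Tensor(self.value @ o.value, (self, o),
                      lambda g: ((self, g @ o.value.T), (o, self.value.T @ g)))

    def __getitem__(self, key):
        def back(g):
            out = np.zeros_like(self.value)
            np.add.at(out, key, g)
            return ((self, out),)
        return Tensor(self.value[key], (self,), back)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def back(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.value.shape).copy()),)
        return Tensor(self.value.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(x, requires_grad=False)


def constant(x) -> Tensor:
    return Tensor(x, requires_grad=False)


# -- elementwise functions ---------------------------------------------------

def tanh(x: Tensor) -> Tensor:
    v = np.tanh(x.value)
    return Tensor(v, (x,), lambda g: ((x, g * (1 - v**2)),))


def sigmoid(x: Tensor) -> Tensor:
    v = 0.5 * (1 + np.tanh(0.5 * x.value))  # numerically stable logistic
    return Tensor(v, (x,), lambda g: ((x, g * v * (1 - v)),))


def softplus(x: Tensor) -> Tensor:
    v = np.logaddexp(0.0, x.value)
    s = 0.5 * (1 + np.tanh(0.5 * x.value))
    return Tensor(v, (x,), lambda g: ((x, g * s),))


def exp(x: Tensor) -> Tensor:
    v = np.exp(x.value)
    return Tensor(v, (x,), lambda g: ((x, g * v),))


def log(x: Tensor) -> Tensor:
    return Tensor(np.log(x.value), (x,), lambda g: ((x, g / x.value),))


def absolute(x: Tensor) -> Tensor:
    return Tensor(np.abs(x.value), (x,), lambda g: ((x, g * np.sign(x.value)),))


def gammaln(x: Tensor) -> Tensor:
    return Tensor(_gammaln_np(x.value), (x,),
                  lambda g: ((x, g * digamma(x.value)),))


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    sizes = [t.value.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(ts, parts))
    return Tensor(np.concatenate([t.value for t in ts], axis=axis), tuple(ts), back)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]

    def back(g):
        parts = np.split(g, len(ts), axis=axis)
        return tuple((t, p.squeeze(axis)) for t, p in zip(ts, parts))
    return Tensor(np.stack([t.value for t in ts], axis=axis), tuple(ts), back)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Max-subtracted (numerically stable) softmax."""
    shifted = x.value - x.value.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    v = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        dot = (g * v).sum(axis=axis, keepdims=True)
        return ((x, v * (g - dot)),)
    return Tensor(v, (x,), back)


__all__ = ["Tensor", "as_tensor", "constant", "tanh", "sigmoid", "softplus",
           "exp", "log", "absolute", "gammaln", "concat", "stack", "softmax"]
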