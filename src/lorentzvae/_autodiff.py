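"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine sized for the networks in this package: dense
layers, layer normalization, count log-likelihoods (log-gamma terms) and the
hyperboloid distance. Every primitive stores a closed-over backward function;
:meth:`Tensor.backward` runs the topologically sorted tape.

Gradients are accumulated in float64 throughout. Broadcasting follows numpy
semantics; the backward pass sums gradients over broadcast axes.
"""

from __future__ import annotations

import math
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy import special


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to the reflected operators below instead of trying
    # to broadcast over a Tensor as an object array
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # ---- infrastructure -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic ------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)
        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data ** 2,
                                               other.shape))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)
        out._backward = bw
        return out

    # ---- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n


# ---- elementwise functions ----------------------------------------------

def _unary(x: Tensor, value: np.ndarray, dfun: Callable[[], np.ndarray]) -> Tensor:
    out = Tensor(value, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * dfun())
    out._backward = bw
    return out


def exp(x: Tensor) -> Tensor:
    v = np.exp(x.data)
    return _unary(x, v, lambda: v)


def log(x: Tensor) -> Tensor:
    return _unary(x, np.log(x.data), lambda: 1.0 / x.data)


def log1p(x: Tensor) -> Tensor:
    return _unary(x, np.log1p(x.data), lambda: 1.0 / (1.0 + x.data))


def sqrt(x: Tensor) -> Tensor:
    v = np.sqrt(x.data)
    return _unary(x, v, lambda: 0.5 / v)


def tanh(x: Tensor) -> Tensor:
    v = np.tanh(x.data)
    return _unary(x, v, lambda: 1.0 - v * v)


def sigmoid(x: Tensor) -> Tensor:
    v = special.expit(x.data)
    return _unary(x, v, lambda: v * (1.0 - v))


def softplus(x: Tensor) -> Tensor:
    # log(1+e^x), computed stably
    v = np.logaddexp(0.0, x.data)
    return _unary(x, v, lambda: special.expit(x.data))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return _unary(x, np.where(mask, x.data, 0.0), lambda: mask.astype(np.float64))


def cosh(x: Tensor) -> Tensor:
    v = np.cosh(x.data)
    return _unary(x, v, lambda: np.sinh(x.data))


def sinh(x: Tensor) -> Tensor:
    v = np.sinh(x.data)
    return _unary(x, v, lambda: np.cosh(x.data))


def lgamma(x: Tensor) -> Tensor:
    return _unary(x, special.gammaln(x.data), lambda: special.digamma(x.data))


def clamp(x: Tensor, lo: float = -np.inf, hi: float = np.inf) -> Tensor:
    """Clip; gradient is zero outside [lo, hi] (projection subgradient)."""
    mask = (x.data >= lo) & (x.data <= hi)
    return _unary(x, np.clip(x.data, lo, hi), lambda: mask.astype(np.float64))


def where(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select a where the (constant) mask is true, else b."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    m = np.asarray(mask, dtype=bool)
    out = Tensor(np.where(m, a.data, b.data), parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(np.where(m, g, 0.0), a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(np.where(m, 0.0, g), b.shape))
    out._backward = bw
    return out


def logaddexp(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._lift(a), Tensor._lift(b)
    v = np.logaddexp(a.data, b.data)
    out = Tensor(v, parents=(a, b))

    def bw(g):
        wa = special.expit(a.data - b.data)  # e^a/(e^a+e^b)
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * wa, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * (1.0 - wa), b.shape))
    out._backward = bw
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    lse = m + np.log(np.exp(x.data - m).sum(axis=axis, keepdims=True))
    v = x.data - lse
    out = Tensor(v, parents=(x,))

    def bw(g):
        if x.requires_grad:
            p = np.exp(v)
            x._accumulate(g - p * g.sum(axis=axis, keepdims=True))
    out._backward = bw
    return out


def arccosh_clamped(alpha: Tensor, floor: float = 1.0 + 1e-8,
                    branch: float = 1e4) -> Tensor:
    """Hyperboloid distance from the negated Lorentz inner product.

    alpha is clamped to >= floor; returns arccosh(alpha) for alpha <= branch
    and log(2*alpha) above it. The gradient is 1/sqrt(a^2-1) on the arccosh
    branch, 1/a on the log branch, and 0 where the clamp is active.
    """
    a = np.maximum(alpha.data, floor)
    big = a > branch
    v = np.where(big, np.log(2.0 * a), np.arccosh(a))
    out = Tensor(v, parents=(alpha,))

    def bw(g):
        if alpha.requires_grad:
            d = np.where(big, 1.0 / a, 1.0 / np.sqrt(a * a - 1.0))
            d = np.where(alpha.data < floor, 0.0, d)
            alpha._accumulate(g * d)
    out._backward = bw
    return out


# ---- layers --------------------------------------------------------------

def linear(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    return x @ W + b


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each row to zero mean / unit variance, then affine."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / sqrt(var + eps) * gain + bias


class Adam:
    """Adam with optional global-norm gradient clipping."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def clip_global_norm(self, max_norm: float) -> float:
        total = math.sqrt(sum(float((p.grad ** 2).sum())
                              for p in self.params if p.grad is not None))
        if total > max_norm and total > 0:
            scale = max_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale
        return total

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
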