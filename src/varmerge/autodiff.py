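"""Minimal reverse-mode automatic differentiation on numpy arrays.

The variational merging objective needs pathwise (reparameterized)
gradients through truncated-normal sampling, a deep multilayer
perceptron, and robust likelihoods.  This module provides exactly the
operator set those computations require: elementwise arithmetic,
matrix products, leaky ReLU, exp/log/softplus, the normal CDF family
(``ndtr``, ``log_ndtr``, ``ndtri``), gather/scatter by integer index,
and segment sums for harmonic (central-ray) reductions.

Every operator builds a node in a dynamic graph; :meth:`Tensor.backward`
runs a topological sweep accumulating gradients into leaf tensors
created with ``requires_grad=True``.  Broadcasting follows numpy rules;
gradients are summed back over broadcast axes.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special as sp

__all__ = [
    "Tensor",
    "as_tensor",
    "add", "sub", "mul", "div", "neg", "power", "square",
    "exp", "log", "sqrt", "softplus", "leaky_relu",
    "ndtr", "log_ndtr", "ndtri",
    "matmul", "matvec", "dense_leaky", "tsum", "gather", "segment_sum",
    "scatter_rows",
    "Adam",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes where the original dimension was 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, k):
        return power(self, k)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- backward pass ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological order (graphs here can be thousands deep)
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _data(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


# -- arithmetic -----------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data
    return Tensor._node(out, (a, b), lambda g: (
        _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)))


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data - b.data
    return Tensor._node(out, (a, b), lambda g: (
        _unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)))


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data
    return Tensor._node(out, (a, b), lambda g: (
        _unbroadcast(g * b.data, a.data.shape),
        _unbroadcast(g * a.data, b.data.shape)))


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data / b.data
    return Tensor._node(out, (a, b), lambda g: (
        _unbroadcast(g / b.data, a.data.shape),
        _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)))


def neg(a):
    a = as_tensor(a)
    return Tensor._node(-a.data, (a,), lambda g: (-g,))


def power(a, k: float):
    a = as_tensor(a)
    kf = float(k)
    out = a.data ** kf
    return Tensor._node(out, (a,), lambda g: (g * kf * a.data ** (kf - 1.0),))


def square(a):
    a = as_tensor(a)
    return Tensor._node(a.data * a.data, (a,), lambda g: (2.0 * g * a.data,))


# -- transcendental -------------------------------------------------------

def exp(a):
    a = as_tensor(a)
    out = np.exp(a.data)
    return Tensor._node(out, (a,), lambda g: (g * out,))


def log(a):
    a = as_tensor(a)
    return Tensor._node(np.log(a.data), (a,), lambda g: (g / a.data,))


def sqrt(a):
    a = as_tensor(a)
    out = np.sqrt(a.data)
    return Tensor._node(out, (a,), lambda g: (0.5 * g / out,))


def softplus(a):
    a = as_tensor(a)
    out = np.logaddexp(0.0, a.data)
    return Tensor._node(out, (a,), lambda g: (g * sp.expit(a.data),))


def leaky_relu(a, slope: float = 0.01):
    a = as_tensor(a)
    pos = a.data > 0
    out = np.where(pos, a.data, slope * a.data)
    return Tensor._node(out, (a,), lambda g: (g * np.where(pos, 1.0, slope),))


# -- normal CDF family ----------------------------------------------------

def ndtr(a):
    """Standard normal CDF Phi(x)."""
    a = as_tensor(a)
    out = sp.ndtr(a.data)
    pdf = np.exp(-0.5 * a.data ** 2 - _LOG_SQRT_2PI)
    return Tensor._node(out, (a,), lambda g: (g * pdf,))


def log_ndtr(a):
    """log Phi(x), stable in the lower tail; d/dx = exp(logpdf - logcdf)."""
    a = as_tensor(a)
    out = sp.log_ndtr(a.data)
    logpdf = -0.5 * a.data ** 2 - _LOG_SQRT_2PI
    return Tensor._node(out, (a,), lambda g: (g * np.exp(logpdf - out),))


def ndtri(a):
    """Inverse normal CDF; d/dx Phi^{-1}(x) = 1 / phi(Phi^{-1}(x))."""
    a = as_tensor(a)
    out = sp.ndtri(a.data)
    inv_pdf = np.exp(0.5 * out ** 2 + _LOG_SQRT_2PI)
    return Tensor._node(out, (a,), lambda g: (g * inv_pdf,))


# -- linear algebra and reductions ---------------------------------------

def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data
    return Tensor._node(out, (a, b), lambda g: (
        g @ b.data.T, a.data.T @ g))


def matvec(a, x):
    """(n, d) @ (d,) -> (n,) with gradients for both operands."""
    a, x = as_tensor(a), as_tensor(x)
    out = a.data @ x.data
    return Tensor._node(out, (a, x), lambda g: (
        np.outer(g, x.data), a.data.T @ g))


def dense_leaky(h, W, b, slope: float):
    """Fused leaky_relu(h @ W + b) — one graph node per MLP layer.

    Keeping the layer as a single node roughly halves the graph size of
    a deep scale function, which dominates per-iteration cost.
    """
    h, W, b = as_tensor(h), as_tensor(W), as_tensor(b)
    pre = h.data @ W.data + b.data
    pos = pre > 0
    out = np.where(pos, pre, slope * pre)

    def backward(g):
        gpre = g * np.where(pos, 1.0, slope)
        return (gpre @ W.data.T, h.data.T @ gpre, gpre.sum(axis=0))

    return Tensor._node(out, (h, W, b), backward)


def tsum(a, axis=None):
    a = as_tensor(a)
    out = a.data.sum(axis=axis)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        g_exp = np.expand_dims(g, axis)
        return (np.broadcast_to(g_exp, a.data.shape).copy(),)

    return Tensor._node(out, (a,), backward)


def gather(a, idx):
    """Row gather ``a[idx]`` along axis 0; backward scatter-adds."""
    a = as_tensor(a)
    idx = np.asarray(idx)
    out = a.data[idx]

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        return (ga,)

    return Tensor._node(out, (a,), backward)


def segment_sum(a, segment_ids, num_segments: int):
    """Sum elements of a 1-D tensor into ``num_segments`` buckets."""
    a = as_tensor(a)
    ids = np.asarray(segment_ids)
    out = np.zeros(num_segments, dtype=np.float64)
    np.add.at(out, ids, a.data)
    return Tensor._node(out, (a,), lambda g: (g[ids],))


def scatter_rows(pieces, n_rows: int):
    """Assemble rows of an output array from (index, tensor) pieces.

    ``pieces`` is a list of ``(row_indices, tensor)`` whose indices
    partition ``range(n_rows)``.  Used to reassemble per-image MLP
    branches into one observation-ordered array.
    """
    tensors = [t for _, t in pieces]
    first = tensors[0].data
    shape = (n_rows,) + first.shape[1:]
    out = np.empty(shape, dtype=np.float64)
    for idx, t in pieces:
        out[idx] = t.data

    def backward(g):
        return tuple(g[idx] for idx, _ in pieces)

    return Tensor._node(out, tensors, backward)


# -- optimizer ------------------------------------------------------------

class Adam:
    """Adam with the hyperparameters used for merging (alpha=1e-3,
    beta1=0.9, beta2=0.99)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.99, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self._t
        bias2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
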