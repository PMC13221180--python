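"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package's neural components (splice-site encoders, the fusion model,
the sequence VAE) are small enough to train on a single CPU, so they are
built on this compact tape-based autodiff core rather than a full deep
learning framework.  Only the operations those models need are provided.

Arrays default to float32; operations preserve the dtype of their inputs,
which lets the test suite run finite-difference gradient checks in
float64.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

DEFAULT_DTYPE = np.float32


def _as_array(x, dtype=None) -> np.ndarray:
    a = np.asarray(x)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(dtype or DEFAULT_DTYPE)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # collapse extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward: Callable | None = None):
        self.data = _as_array(data)
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward
        self._grad_owned = True

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _acc(self, g: np.ndarray) -> None:
        g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            if g.dtype == self.data.dtype and g.base is None:
                # take the array without copying; it may be aliased by
                # another consumer, so mark it not-owned and never
                # mutate it in place
                self.grad = g
                self._grad_owned = False
            else:
                self.grad = g.astype(self.data.dtype, copy=True)
                self._grad_owned = True
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        self._grad_owned = True
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -------------------------------------------------- basic arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._acc(g)
            if other.requires_grad:
                other._acc(g)
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._acc(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._acc(g * other.data)
            if other.requires_grad:
                other._acc(g * self.data)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._acc(g / other.data)
            if other.requires_grad:
                other._acc(-g * self.data / (other.data * other.data))
        out._backward = bw
        return out

    def __pow__(self, p: float):
        # float32 pow is slow in some NumPy builds; special-case p=2
        if p == 2:
            out = Tensor(self.data * self.data, _parents=(self,))
            out._backward = lambda g: self._acc(g * 2.0 * self.data)
            return out
        out = Tensor(self.data ** p, _parents=(self,))
        out._backward = lambda g: self._acc(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._acc(ga)
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._acc(gb)
        out._backward = bw
        return out

    # -------------------------------------------------- shape ops
    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self._acc(g.reshape(orig))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), _parents=(self,))
        out._backward = lambda g: self._acc(g.transpose(*inv))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(np.broadcast_to(g, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -------------------------------------------------- nonlinearities
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._acc(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._acc(g / self.data)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._acc(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._acc(g * y * (1.0 - y))
        return out

    def gelu(self):
        # tanh approximation (as used by BERT-family models)
        c = np.sqrt(2.0 / np.pi).astype(self.data.dtype)
        x = self.data
        x2 = x * x
        inner = c * (x + 0.044715 * (x2 * x))
        t = np.tanh(inner)
        y = 0.5 * x * (1.0 + t)
        out = Tensor(y, _parents=(self,))

        def bw(g):
            dinner = c * (1.0 + 3 * 0.044715 * x2)
            dy = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
            self._acc(g * dy)
        out._backward = bw
        return out


# ---------------------------------------------------------------- fused ops
def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """softmax(q k^T / sqrt(d)) v over the last two axes, fused.

    q, k, v: (..., T, d_head).  One hand-written backward avoids the
    large intermediate gradient tensors of the composite form.
    """
    d = q.data.shape[-1]
    scale = 1.0 / np.sqrt(d).astype(q.data.dtype)
    scores = (q.data @ np.swapaxes(k.data, -1, -2))
    scores *= scale
    scores -= scores.max(axis=-1, keepdims=True)
    np.exp(scores, out=scores)
    scores /= scores.sum(axis=-1, keepdims=True)
    att = scores
    out = Tensor(att @ v.data, _parents=(q, k, v))

    def bw(g):
        if v.requires_grad:
            v._acc(np.swapaxes(att, -1, -2) @ g)
        g_att = g @ np.swapaxes(v.data, -1, -2)
        # softmax backward in place
        g_att *= att
        g_att -= att * g_att.sum(axis=-1, keepdims=True)
        g_att *= scale
        if q.requires_grad:
            q._acc(g_att @ k.data)
        if k.requires_grad:
            k._acc(np.swapaxes(g_att, -1, -2) @ q.data)
    out._backward = bw
    return out


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._acc(piece)
    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _parents=(x,))

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._acc(y * (g - dot))
    out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gamma.data + beta.data, _parents=(x, gamma, beta))
    n = x.data.shape[-1]

    def bw(g):
        if gamma.requires_grad:
            gamma._acc((g * xhat).reshape(-1, n).sum(axis=0))
        if beta.requires_grad:
            beta._acc(g.reshape(-1, n).sum(axis=0))
        if x.requires_grad:
            gx = g * gamma.data
            t1 = gx - gx.mean(axis=-1, keepdims=True)
            t2 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            x._acc(inv * (t1 - t2))
    out._backward = bw
    return out


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    ids = np.asarray(ids)
    out = Tensor(weight.data[ids], _parents=(weight,))

    def bw(g):
        if weight.grad is None:
            weight.grad = np.zeros_like(weight.data)
        np.add.at(weight.grad, ids.reshape(-1),
                  g.reshape(-1, weight.data.shape[-1]))
    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Soft-label binary cross-entropy, averaged over all elements.

    Numerically stable form: max(l,0) - l*t + log(1 + exp(-|l|)).
    """
    lo = logits.data
    t = np.asarray(targets, dtype=lo.dtype)
    loss = np.maximum(lo, 0) - lo * t + np.log1p(np.exp(-np.abs(lo)))
    out = Tensor(loss.mean(), _parents=(logits,))
    n = lo.size

    def bw(g):
        p = 1.0 / (1.0 + np.exp(-lo))
        logits._acc(g * (p - t) / n)
    out._backward = bw
    return out


def cross_entropy_logits(logits: Tensor, labels: np.ndarray,
                         weights: np.ndarray | None = None) -> Tensor:
    """Categorical cross-entropy over rows; labels are class indices.

    With ``weights`` (one per row) the loss is the weighted mean —
    used e.g. to emphasize rare informative positions.
    """
    lo = logits.data
    labels = np.asarray(labels)
    z = lo - lo.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    n = labels.shape[0]
    nll_rows = -logp[np.arange(n), labels]
    if weights is None:
        nll = nll_rows.mean()
    else:
        weights = np.asarray(weights, dtype=lo.dtype).ravel()
        nll = (nll_rows * weights).sum() / weights.sum()
    out = Tensor(nll, _parents=(logits,))

    def bw(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        if weights is None:
            logits._acc(g * p / n)
        else:
            logits._acc(g * p * (weights / weights.sum())[:, None])
    out._backward = bw
    return out
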