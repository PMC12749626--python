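"""Compact reverse-mode automatic differentiation on NumPy arrays.

This module provides the minimal tensor algebra needed to express and train
the graph transformer reaction model: broadcast-aware elementwise ops,
(batched) matrix products, row gather / segment scatter-sum for sparse graph
message passing, dense and segment-wise softmax, and an Adam optimizer with
optional exponential moving averaging of the weights.

Arithmetic follows the input dtype: float64 where exactness matters (the
oracle tests), float32 for faster training. The tape is built eagerly;
``Tensor.backward`` runs a topological sweep. Only what the model needs is
implemented — this is not a general deep-learning framework.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "no_grad",
    "Tensor",
    "concat",
    "gather_rows",
    "segment_sum",
    "segment_softmax",
    "ScatterPlan",
    "Linear",
    "MLP",
    "Adam",
    "EMA",
]


import contextlib


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (evaluation passes)."""
    prev = Tensor.grad_enabled
    Tensor.grad_enabled = False
    try:
        yield
    finally:
        Tensor.grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (the inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # Sum away prepended axes.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_grad_owned")

    grad_enabled: bool = True

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype.kind in "iub":
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._grad_owned = False
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        # First contribution is stored by reference (never mutated); a second
        # contribution triggers an owned copy that can be accumulated in place.
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if Tensor.grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, (int, float)):
            out_data = self.data + other

            def backward_s(out=None):
                if self.requires_grad:
                    self._accum(out.grad)

            out = Tensor._make(out_data, (self,), None)
            out._backward = lambda: backward_s(out)
            return out
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(out=None):
            g = out.grad
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out = Tensor._make(out_data, (self, other), None)
        out._backward = lambda: backward(out)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (other * -1.0)

    def __rsub__(self, other):
        return Tensor(other) + (self * -1.0)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out_data = self.data * other

            def backward_s(out=None):
                if self.requires_grad:
                    self._accum(out.grad * other)

            out = Tensor._make(out_data, (self,), None)
            out._backward = lambda: backward_s(out)
            return out
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(out=None):
            g = out.grad
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out = Tensor._make(out_data, (self, other), None)
        out._backward = lambda: backward(out)
        return out

    __radd__ = __add__
    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def backward(out=None):
            g = out.grad
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        out = Tensor._make(out_data, (self, other), None)
        out._backward = lambda: backward(out)
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def backward(out=None):
            g = out.grad
            if self.requires_grad:
                if other.data.ndim == 2:
                    self._accum(g @ other.data.T)
                else:
                    self._accum(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                if other.data.ndim == 2 and self.data.ndim > 2:
                    a2 = self.data.reshape(-1, self.data.shape[-1])
                    g2 = g.reshape(-1, g.shape[-1])
                    other._accum(a2.T @ g2)
                elif other.data.ndim == 2:
                    other._accum(self.data.T @ g)
                else:
                    other._accum(np.swapaxes(self.data, -1, -2) @ g)

        out = Tensor._make(out_data, (self, other), None)
        out._backward = lambda: backward(out)
        return out

    # -- nonlinearities -------------------------------------------------------

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(out=None):
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        out = Tensor._make(s, (self,), None)
        out._backward = lambda: backward(out)
        return out

    def silu(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def backward(out=None):
            if self.requires_grad:
                self._accum(out.grad * (s + self.data * s * (1.0 - s)))

        out = Tensor._make(out_data, (self,), None)
        out._backward = lambda: backward(out)
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)

        def backward(out=None):
            if self.requires_grad:
                self._accum(out.grad * e)

        out = Tensor._make(e, (self,), None)
        out._backward = lambda: backward(out)
        return out

    # -- reductions / shaping -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(out=None):
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out = Tensor._make(out_data, (self,), None)
        out._backward = lambda: backward(out)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out_data = self.data.reshape(*shape)

        def backward(out=None):
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out = Tensor._make(out_data, (self,), None)
        out._backward = lambda: backward(out)
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out_data = np.swapaxes(self.data, a, b)

        def backward(out=None):
            if self.requires_grad:
                self._accum(np.swapaxes(out.grad, a, b))

        out = Tensor._make(out_data, (self,), None)
        out._backward = lambda: backward(out)
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(out=None):
            if self.requires_grad:
                g = out.grad
                self._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        out = Tensor._make(s, (self,), None)
        out._backward = lambda: backward(out)
        return out

    # -- autodiff driver ------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()


# -- structural ops ----------------------------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(out=None):
        g = out.grad
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    out = Tensor._make(out_data, tuple(tensors), None)
    out._backward = lambda: backward(out)
    return out


class ScatterPlan:
    """Precomputed sparse incidence matrix for repeated scatter-adds.

    Maps ``n_in`` rows onto ``n_out`` buckets given per-row bucket ids;
    the forward scatter and its transpose are CSR matrices so that
    repeated segment sums (and gather backwards) become sparse matmuls.
    """

    def __init__(self, idx: np.ndarray, n_out: int):
        import scipy.sparse as sp

        n_in = len(idx)
        self.idx = idx
        self.n_out = n_out
        ones = np.ones(n_in, dtype=np.float32)
        self.m = sp.csr_matrix((ones, (idx, np.arange(n_in))), shape=(n_out, n_in))
        self.mt = self.m.T.tocsr()

    def scatter(self, x: np.ndarray) -> np.ndarray:
        flat = x.reshape(x.shape[0], -1)
        out = self.m @ flat
        return np.ascontiguousarray(out).reshape((self.n_out,) + x.shape[1:])

    def gather_grad(self, g: np.ndarray) -> np.ndarray:
        # Transpose action: distribute bucket gradients back to rows.
        flat = g.reshape(g.shape[0], -1)
        out = self.mt @ flat
        return np.ascontiguousarray(out).reshape((self.mt.shape[0],) + g.shape[1:])


def gather_rows(t: Tensor, idx: np.ndarray, plan: "ScatterPlan | None" = None) -> Tensor:
    """Select rows ``t[idx]`` along axis 0, with scatter-add backward.

    ``plan`` (a :class:`ScatterPlan` built from ``idx`` with
    ``n_out == t.shape[0]``) accelerates the backward scatter.
    """
    out_data = t.data[idx]

    def backward(out=None):
        if t.requires_grad:
            if plan is not None:
                t._accum(plan.scatter(out.grad))
            else:
                g = np.zeros_like(t.data)
                np.add.at(g, idx, out.grad)
                t._accum(g)

    out = Tensor._make(out_data, (t,), None)
    out._backward = lambda: backward(out)
    return out


def segment_sum(
    t: Tensor, idx: np.ndarray, n_segments: int, plan: "ScatterPlan | None" = None
) -> Tensor:
    """Sum rows of `t` into `n_segments` buckets given per-row bucket ids.

    Rows whose bucket never occurs yield zero rows (the empty-sum
    convention used for isolated graph nodes).
    """
    if plan is not None:
        out_data = plan.scatter(t.data)
    else:
        out_data = np.zeros((n_segments,) + t.data.shape[1:], dtype=t.data.dtype)
        np.add.at(out_data, idx, t.data)

    def backward(out=None):
        if t.requires_grad:
            t._accum(out.grad[idx])

    out = Tensor._make(out_data, (t,), None)
    out._backward = lambda: backward(out)
    return out


def segment_softmax(
    scores: Tensor,
    idx: np.ndarray,
    n_segments: int,
    sorted_starts: np.ndarray | None = None,
) -> Tensor:
    """Column-wise softmax of `scores` [N, H] within row-segments.

    Each column is normalized independently so that rows sharing a segment
    id sum to one; used for attention over variable-size atom sets. When
    ``idx`` is non-decreasing, pass ``sorted_starts`` (first row of every
    segment) to use the much faster ``reduceat`` path; every segment must
    then be non-empty.
    """
    x = scores.data
    if sorted_starts is not None:
        mx = np.maximum.reduceat(x, sorted_starts, axis=0)
        e = np.exp(x - mx[idx])
        denom = np.add.reduceat(e, sorted_starts, axis=0)
        s = e / denom[idx]
    else:
        mx = np.full((n_segments,) + x.shape[1:], -np.inf, dtype=x.dtype)
        np.maximum.at(mx, idx, x)
        e = np.exp(x - mx[idx])
        denom = np.zeros((n_segments,) + x.shape[1:], dtype=x.dtype)
        np.add.at(denom, idx, e)
        s = e / denom[idx]

    def backward(out=None):
        if scores.requires_grad:
            g = out.grad
            if sorted_starts is not None:
                dot = np.add.reduceat(g * s, sorted_starts, axis=0)
            else:
                dot = np.zeros((n_segments,) + x.shape[1:], dtype=x.dtype)
                np.add.at(dot, idx, g * s)
            scores._accum(s * (g - dot[idx]))

    out = Tensor._make(s, (scores,), None)
    out._backward = lambda: backward(out)
    return out


# -- layers ------------------------------------------------------------------


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.w = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def parameters(self) -> list[Tensor]:
        return [self.w, self.b]


class MLP:
    """Linear stack with SiLU between layers (none after the last)."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator,
                 final_activation: bool = False):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.final_activation = final_activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1 or self.final_activation:
                x = x.silu()
        return x

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]


class Adam:
    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class EMA:
    """Exponential moving average of parameter values.

    ``factor`` is the retention weight of the running average; the shadow
    weights are used for validation and test evaluation.
    """

    def __init__(self, params: Sequence[Tensor], factor: float = 0.9):
        self.params = list(params)
        self.factor = factor
        self.shadow = [p.data.copy() for p in self.params]

    def update(self) -> None:
        for s, p in zip(self.shadow, self.params):
            s *= self.factor
            s += (1.0 - self.factor) * p.data

    def swap_in(self) -> list[np.ndarray]:
        live = [p.data.copy() for p in self.params]
        for p, s in zip(self.params, self.shadow):
            p.data = s.copy()
        return live

    def swap_out(self, live: list[np.ndarray]) -> None:
        for p, d in zip(self.params, live):
            p.data = d
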