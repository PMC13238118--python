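"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the package's neural models need: dense and
sparse matrix products, elementwise arithmetic with broadcasting, the usual
nonlinearities, reductions, reshaping, and per-segment softmax for graph
attention. Everything is float64 and deterministic.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "Adam", "spmm", "segment_softmax", "log_softmax",
           "no_grad"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (evaluation passes)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_children", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._children: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for c in t._children:
                visit(c)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
        # break the closure reference cycles so arrays free immediately
        for t in topo:
            t._children = ()
            t._backward = None

    def _needs(self, *others) -> bool:
        return self.requires_grad or any(
            isinstance(o, Tensor) and o.requires_grad for o in others
        )

    @staticmethod
    def _make(data, children, backward, requires_grad):
        requires_grad = requires_grad and _GRAD_ENABLED[-1]
        out = Tensor(data, requires_grad=requires_grad)
        if requires_grad:
            out._children = tuple(c for c in children if isinstance(c, Tensor))
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        rg = self._needs(other)
        out_data = self.data + other.data

        def bwd():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out = self._make(out_data, (self, other), bwd, rg)
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        rg = self._needs(other)
        out_data = self.data * other.data

        def bwd():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out = self._make(out_data, (self, other), bwd, rg)
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        rg = self.requires_grad
        out_data = np.power(self.data, p)

        def bwd():
            if self.requires_grad:
                self._accum(out.grad * p * np.power(self.data, p - 1.0))

        out = self._make(out_data, (self,), bwd, rg)
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        rg = self._needs(other)
        out_data = self.data @ other.data

        def bwd():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out = self._make(out_data, (self, other), bwd, rg)
        return out

    # -- elementwise functions ---------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd():
            if self.requires_grad:
                self._accum(out.grad * out_data)

        out = self._make(out_data, (self,), bwd, self.requires_grad)
        return out

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def bwd():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out = self._make(out_data, (self,), bwd, self.requires_grad)
        return out

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad * out_data * (1.0 - out_data))

        out = self._make(out_data, (self,), bwd, self.requires_grad)
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = np.where(self.data > 0, 1.0, slope)
        out_data = self.data * mask

        def bwd():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out = self._make(out_data, (self,), bwd, self.requires_grad)
        return out

    # -- reductions / shape -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out = self._make(out_data, (self,), bwd, self.requires_grad)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        out_data = self.data.reshape(*shape)

        def bwd():
            if self.requires_grad:
                self._accum(out.grad.reshape(orig))

        out = self._make(out_data, (self,), bwd, self.requires_grad)
        return out


def spmm(S: sp.spmatrix, t: Tensor) -> Tensor:
    """Sparse (constant) @ dense (tensor). Used for gather/scatter on graphs."""
    S = S.tocsr()
    out_data = S @ t.data

    def bwd():
        if t.requires_grad:
            t._accum(S.T @ out.grad)

    out = Tensor._make(out_data, (t,), bwd, t.requires_grad)
    return out


class SegmentIndex:
    """Precomputed grouping of E items into n segments (e.g. edges by target node).

    Provides O(E) segment max/sum via a sorted permutation + reduceat, and
    sparse matrices for differentiable gather/scatter.
    """

    def __init__(self, seg_ids: np.ndarray, n_segments: int):
        seg_ids = np.asarray(seg_ids)
        self.seg_ids = seg_ids
        self.n_segments = n_segments
        self.perm = np.argsort(seg_ids, kind="stable")
        sorted_ids = seg_ids[self.perm]
        # segments present, with their start offsets in the sorted order
        self.present, self.starts = np.unique(sorted_ids, return_index=True)
        E = len(seg_ids)
        ones = np.ones(E)
        # scatter: (n_segments, E); scatter @ values sums per segment
        self.scatter = sp.csr_matrix(
            (ones, (seg_ids, np.arange(E))), shape=(n_segments, E)
        )
        self.gather = self.scatter.T.tocsr()  # (E, n_segments)

    def seg_max(self, values: np.ndarray) -> np.ndarray:
        """Per-segment max (constant w.r.t. autodiff), shape (n_segments, ...)."""
        out = np.full((self.n_segments,) + values.shape[1:], -np.inf)
        out[self.present] = np.maximum.reduceat(values[self.perm], self.starts, axis=0)
        return out


def segment_softmax(scores: Tensor, index: SegmentIndex) -> Tensor:
    """Softmax of `scores` (E, ...) within segments defined by `index`.

    Numerically stabilised with a per-segment max shift (treated as constant).
    """
    shift = index.seg_max(scores.data)[index.seg_ids]
    ex = (scores - Tensor(shift)).exp()
    if ex.data.ndim == 1:
        denom = spmm(index.scatter, ex.reshape(-1, 1))
        return ex / spmm(index.gather, denom).reshape(-1)
    denom = spmm(index.scatter, ex)
    return ex / spmm(index.gather, denom)


def log_softmax(logits: Tensor) -> Tensor:
    """Row-wise log-softmax for an (n, C) tensor."""
    shift = logits.data.max(axis=1, keepdims=True)
    z = logits - Tensor(shift)
    return z - z.exp().sum(axis=1, keepdims=True).log()


class Adam:
    """Adam optimiser over a list of Tensors."""

    def __init__(self, params, lr: float = 1e-3, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
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
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
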