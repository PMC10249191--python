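"""A minimal reverse-mode automatic-differentiation engine over numpy arrays.

Just enough machinery to train the sequential-attention tabular network in
:mod:`tabfusion.tabnet`: dense arithmetic with broadcasting, matmul, the
gated/rectified nonlinearities the architecture needs, a row-wise sparsemax
primitive with its exact Jacobian-vector product, a width-1 categorical
embedding gather, and a numerically stable binary cross-entropy head.

Gradients are accumulated by a topological backward sweep from a scalar
loss. Everything is float64 and deterministic; correctness is pinned by
finite-difference checks in the test suite.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

__all__ = ["Tensor", "sparsemax_np", "capped_sparsemax_np", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g.reshape(shape)


class Tensor:
    """A numpy array node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents: tuple = (),
                 backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list = []
        seen = set()

        def visit(node: "Tensor") -> None:
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor.as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    __matmul__ = matmul

    def square(self) -> "Tensor":
        return self * self

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, float(g)))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bwd)

    def mean(self) -> "Tensor":
        return self.sum() * (1.0 / self.data.size)

    # -- nonlinearities ---------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * s * (1 - s))

        return Tensor(s, parents=(self,), backward=bwd)

    # -- structural ops ---------------------------------------------------
    def slice_cols(self, start: int, stop: int) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[:, start:stop] = g
                self._accum(full)

        return Tensor(self.data[:, start:stop], parents=(self,), backward=bwd)

    @staticmethod
    def concat_cols(parts: Iterable["Tensor"]) -> "Tensor":
        parts = [Tensor.as_tensor(p) for p in parts]
        widths = [p.data.shape[1] for p in parts]
        edges = np.concatenate([[0], np.cumsum(widths)])

        def bwd(g):
            for p, lo, hi in zip(parts, edges[:-1], edges[1:]):
                if p.requires_grad:
                    p._accum(g[:, lo:hi])

        return Tensor(np.concatenate([p.data for p in parts], axis=1),
                      parents=tuple(parts), backward=bwd)

    def sparsemax_rows(self) -> "Tensor":
        p = sparsemax_np(self.data)
        support = p > 0

        def bwd(g):
            if not self.requires_grad:
                return
            k = support.sum(axis=1, keepdims=True)
            v = (g * support).sum(axis=1, keepdims=True) / np.maximum(k, 1)
            self._accum(support * (g - v))

        return Tensor(p, parents=(self,), backward=bwd)

    def capped_sparsemax_rows(self, cap: np.ndarray) -> "Tensor":
        """Row-wise projection onto the capped simplex
        ``{m : 0 <= m <= cap, sum m = 1}``. The cap is treated as a
        constant (no gradient flows through it); for free coordinates the
        Jacobian-vector product matches sparsemax restricted to the free
        set."""
        p = capped_sparsemax_np(self.data, cap)
        free = (p > 0) & (p < cap - 1e-12)

        def bwd(g):
            if not self.requires_grad:
                return
            k = free.sum(axis=1, keepdims=True)
            v = (g * free).sum(axis=1, keepdims=True) / np.maximum(k, 1)
            self._accum(free * (g - v))

        return Tensor(p, parents=(self,), backward=bwd)

    def permute_cols(self, perm: np.ndarray) -> "Tensor":
        perm = np.asarray(perm)
        inv = np.argsort(perm)

        def bwd(g):
            if self.requires_grad:
                self._accum(g[:, inv])

        return Tensor(self.data[:, perm], parents=(self,), backward=bwd)

    def embed_lookup(self, indices: np.ndarray) -> "Tensor":
        """Gather entries of a flat parameter vector; ``indices`` is any
        integer array; output has the indices' shape."""

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, indices.ravel(), g.ravel())
                self._accum(full)

        return Tensor(self.data[indices], parents=(self,), backward=bwd)

    def bce_with_logits(self, targets: np.ndarray) -> "Tensor":
        """Mean binary cross-entropy of logits against 0/1 targets."""
        z = self.data.ravel()
        t = np.asarray(targets, dtype=np.float64).ravel()
        loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
        s = 1.0 / (1.0 + np.exp(-z))

        def bwd(g):
            if self.requires_grad:
                self._accum((float(g) * (s - t) / z.size).reshape(self.data.shape))

        return Tensor(loss, parents=(self,), backward=bwd)


def sparsemax_np(z: np.ndarray) -> np.ndarray:
    """Row-wise Euclidean projection onto the probability simplex.

    Sorted-threshold algorithm: with ``z_(1) >= ... >= z_(D)``, the support
    size is the largest k with ``1 + k z_(k) > sum_{j<=k} z_(j)`` and the
    threshold is ``tau = (sum_{j<=k} z_(j) - 1)/k``; the projection is
    ``max(z - tau, 0)``.
    """
    z = np.asarray(z, dtype=np.float64)
    if z.size == 0:
        raise ValueError("sparsemax of an empty vector is undefined")
    one_d = z.ndim == 1
    if one_d:
        z = z[None, :]
    if not np.isfinite(z).all():
        raise ValueError("sparsemax requires finite inputs")
    d = z.shape[1]
    zs = -np.sort(-z, axis=1)
    cs = np.cumsum(zs, axis=1)
    ks = np.arange(1, d + 1)
    cond = 1 + ks * zs > cs
    k = cond.sum(axis=1)
    tau = (cs[np.arange(z.shape[0]), k - 1] - 1) / k
    p = np.maximum(z - tau[:, None], 0.0)
    return p[0] if one_d else p


def capped_sparsemax_np(z: np.ndarray, cap: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of ``z`` onto
    ``{m : 0 <= m <= cap, sum m = 1}``.

    The solution is ``m = clip(z - tau, 0, cap)`` with the threshold ``tau``
    chosen so each row sums to one; ``tau`` is found by bisection (the row
    sum is monotone in ``tau``). Requires ``sum(cap) >= 1`` per row.
    """
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    cap = np.broadcast_to(np.asarray(cap, dtype=np.float64), z.shape)
    if (cap < -1e-12).any():
        raise ValueError("caps must be non-negative")
    cap = np.maximum(cap, 0.0)
    short = cap.sum(axis=1) < 1 - 1e-9
    if short.any():
        raise ValueError(
            f"capped simplex infeasible: cap rows {np.flatnonzero(short).tolist()} sum to < 1"
        )
    plain = sparsemax_np(z)
    if (plain <= cap + 1e-12).all():  # caps slack: identical to sparsemax
        return np.minimum(plain, cap)
    lo = (z - cap).min(axis=1)
    hi = z.max(axis=1)
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        s = np.clip(z - mid[:, None], 0.0, cap).sum(axis=1)
        too_big = s > 1.0
        lo = np.where(too_big, mid, lo)
        hi = np.where(too_big, hi, mid)
    tau = 0.5 * (lo + hi)
    return np.clip(z - tau[:, None], 0.0, cap)


class Adam:
    """Adaptive-moment optimizer with optional decoupled L2 weight decay."""

    def __init__(self, params: dict, lr: float = 0.02, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params  # name -> Tensor
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for name, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1**self.t)
            vhat = self.v[name] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
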