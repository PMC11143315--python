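"""Minimal reverse-mode autograd on numpy arrays.

Only the operations the graph layers need: dense/sparse matmul, broadcast
add/mul, ReLU/LeakyReLU, exp, division, row gather/scatter, segment max,
concat, dropout and a fused masked cross-entropy.  Gradients are float64
throughout; `backward()` topologically sorts the tape.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
from scipy import sparse

__all__ = ["Tensor", "Parameter"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- ops ---------------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        out_data = a.data + b.data

        def bw(g: np.ndarray) -> None:
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor(out_data, parents=(a, b), backward=bw)

    def __sub__(self, other: "Tensor") -> "Tensor":
        return self + (other * (-1.0))

    def __mul__(self, other) -> "Tensor":
        if not isinstance(other, Tensor):
            a, c = self, float(other)
            return Tensor(
                a.data * c,
                parents=(a,),
                backward=lambda g: a._accum(g * c) if a.requires_grad else None,
            )
        a, b = self, other

        def bw(g: np.ndarray) -> None:
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor(a.data * b.data, parents=(a, b), backward=bw)

    def __truediv__(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def bw(g: np.ndarray) -> None:
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data**2), b.data.shape))

        return Tensor(a.data / b.data, parents=(a, b), backward=bw)

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def bw(g: np.ndarray) -> None:
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor(a.data @ b.data, parents=(a, b), backward=bw)

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0
        return Tensor(
            a.data * mask,
            parents=(a,),
            backward=lambda g: a._accum(g * mask) if a.requires_grad else None,
        )

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        a = self
        factor = np.where(a.data > 0, 1.0, slope)
        return Tensor(
            a.data * factor,
            parents=(a,),
            backward=lambda g: a._accum(g * factor) if a.requires_grad else None,
        )

    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)
        return Tensor(
            out_data,
            parents=(a,),
            backward=lambda g: a._accum(g * out_data) if a.requires_grad else None,
        )

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def bw(g: np.ndarray) -> None:
            if not a.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,), backward=bw)

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        """out[k] = self[idx[k]]."""
        a = self
        idx = np.asarray(idx, dtype=np.int64)

        def bw(g: np.ndarray) -> None:
            if a.requires_grad:
                acc = np.zeros_like(a.data)
                np.add.at(acc, idx, g)
                a._accum(acc)

        return Tensor(a.data[idx], parents=(a,), backward=bw)

    def scatter_add_rows(self, idx: np.ndarray, n: int) -> "Tensor":
        """out[i] = sum over k with idx[k]==i of self[k]; out has n rows."""
        a = self
        idx = np.asarray(idx, dtype=np.int64)
        if a.data.size > 2_000_000 and a.data.ndim == 2:
            # CSR matmul beats ufunc.at at full-graph scale
            E = a.data.shape[0]
            S = sparse.csr_matrix(
                (np.ones(E), (idx, np.arange(E))), shape=(n, E)
            )
            out_data = S @ a.data
        else:
            out_data = np.zeros((n,) + a.data.shape[1:])
            np.add.at(out_data, idx, a.data)

        def bw(g: np.ndarray) -> None:
            if a.requires_grad:
                a._accum(g[idx])

        return Tensor(out_data, parents=(a,), backward=bw)

    def segment_max(self, idx: np.ndarray, n: int) -> "Tensor":
        """Per-group elementwise max; empty groups yield 0.

        The subgradient flows to the first element attaining each group
        max, so ties (e.g. duplicated rows) are not double-counted.
        """
        a = self
        idx = np.asarray(idx, dtype=np.int64)
        out_data = np.full((n,) + a.data.shape[1:], -np.inf)
        np.maximum.at(out_data, idx, a.data)
        empty = ~np.isfinite(out_data)
        out_data[empty] = 0.0

        def bw(g: np.ndarray) -> None:
            if not a.requires_grad:
                return
            E = a.data.shape[0]
            winner = a.data == out_data[idx]
            eids = np.arange(E, dtype=np.int64)[:, None]
            claims = np.where(winner, eids, E)
            first = np.full(out_data.shape, E, dtype=np.int64)
            np.minimum.at(first, idx, claims)
            mask = winner & (eids == first[idx])
            a._accum(g[idx] * mask)

        return Tensor(out_data, parents=(a,), backward=bw)

    def concat(self, others: Sequence["Tensor"], axis: int = 1) -> "Tensor":
        parts = [self, *others]
        sizes = [p.data.shape[axis] for p in parts]
        bounds = np.cumsum([0] + sizes)

        def bw(g: np.ndarray) -> None:
            for p, lo, hi in zip(parts, bounds[:-1], bounds[1:]):
                if p.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    p._accum(g[tuple(sl)])

        return Tensor(
            np.concatenate([p.data for p in parts], axis=axis),
            parents=tuple(parts),
            backward=bw,
        )

    def dropout(self, rate: float, rng: np.random.Generator) -> "Tensor":
        """Inverted dropout; call only in training mode."""
        a = self
        keep = rng.random(a.data.shape) >= rate
        scale = keep / (1.0 - rate)
        return Tensor(
            a.data * scale,
            parents=(a,),
            backward=lambda g: a._accum(g * scale) if a.requires_grad else None,
        )

    def spmm(self, A: sparse.spmatrix) -> "Tensor":
        """out = A @ self for a constant sparse matrix A."""
        a = self
        AT = A.T.tocsr()
        return Tensor(
            A @ a.data,
            parents=(a,),
            backward=lambda g: a._accum(AT @ g) if a.requires_grad else None,
        )

    def cross_entropy(self, labels: np.ndarray, idx: Optional[np.ndarray] = None) -> "Tensor":
        """Mean softmax cross-entropy over rows ``idx`` (default: all)."""
        a = self
        labels = np.asarray(labels, dtype=np.int64)
        if idx is None:
            idx = np.arange(a.data.shape[0])
        idx = np.asarray(idx, dtype=np.int64)
        logits = a.data[idx]
        z = logits - logits.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        m = len(idx)
        loss = -logp[np.arange(m), labels].mean()

        def bw(g: np.ndarray) -> None:
            if not a.requires_grad:
                return
            p = np.exp(logp)
            p[np.arange(m), labels] -= 1.0
            acc = np.zeros_like(a.data)
            np.add.at(acc, idx, p * (float(g) / m))
            a._accum(acc)

        return Tensor(np.array(loss), parents=(a,), backward=bw)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over broadcast dimensions back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data: np.ndarray):
        super().__init__(data, requires_grad=True)
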