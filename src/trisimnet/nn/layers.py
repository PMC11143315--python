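"""Message-passing layers: GCNConv, GATv2Conv, SAGEConv.

All layers consume a :class:`GraphTopology` — the directed edge index of an
undirected graph (both directions present, no self-loops) — and a node
feature :class:`~trisimnet.nn.autograd.Tensor`.

Conventions (matching the usual graph-learning formulations):

* GCNConv uses the renormalization trick: ``X' = D^-1/2 (A + I) D^-1/2 X W + b``.
* GATv2Conv scores edge (j -> i) per head as
  ``e_ij = a^T LeakyReLU(W_l x_j + W_r x_i)``, softmax-normalized over i's
  in-neighborhood (self-loop included), and aggregates ``alpha_ij W_l x_j``;
  head outputs are concatenated.
* SAGEConv computes ``W_r x_i + W_l agg({x_j})`` where ``agg`` is either the
  neighborhood mean or max-pooling (elementwise max of ``ReLU(W_p x_j + b_p)``);
  an empty neighborhood aggregates to zero.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import sparse

from .autograd import Parameter, Tensor

__all__ = ["GraphTopology", "Module", "Linear", "GCNConv", "GATv2Conv", "SAGEConv"]


class GraphTopology:
    """Directed edge index over n nodes, with cached derived structures."""

    def __init__(self, n: int, src: np.ndarray, dst: np.ndarray):
        self.n = int(n)
        self.src = np.asarray(src, dtype=np.int64)
        self.dst = np.asarray(dst, dtype=np.int64)
        self._gcn_adj: Optional[sparse.csr_matrix] = None
        self._loop_src: Optional[np.ndarray] = None
        self._loop_dst: Optional[np.ndarray] = None

    @property
    def gcn_adj(self) -> sparse.csr_matrix:
        """D^-1/2 (A + I) D^-1/2 as a CSR matrix."""
        if self._gcn_adj is None:
            loops = np.arange(self.n)
            rows = np.concatenate([self.dst, loops])
            cols = np.concatenate([self.src, loops])
            data = np.ones(len(rows))
            A = sparse.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))
            deg = np.asarray(A.sum(axis=1)).ravel()
            dinv = 1.0 / np.sqrt(deg)
            D = sparse.diags(dinv)
            self._gcn_adj = (D @ A @ D).tocsr()
        return self._gcn_adj

    def with_self_loops(self) -> tuple[np.ndarray, np.ndarray]:
        if self._loop_src is None:
            loops = np.arange(self.n)
            self._loop_src = np.concatenate([self.src, loops])
            self._loop_dst = np.concatenate([self.dst, loops])
        return self._loop_src, self._loop_dst


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        self.in_dim, self.out_dim = in_dim, out_dim
        self.weight = Parameter(_glorot(rng, in_dim, out_dim))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x.matmul(self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class GCNConv(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.in_dim, self.out_dim = in_dim, out_dim
        self.lin = Linear(in_dim, out_dim, rng, bias=True)

    def __call__(self, x: Tensor, topo: GraphTopology) -> Tensor:
        h = x.matmul(self.lin.weight)
        return h.spmm(topo.gcn_adj) + self.lin.bias


class GATv2Conv(Module):
    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        heads: int,
        rng: np.random.Generator,
        negative_slope: float = 0.2,
        concat: bool = True,
    ):
        self.in_dim, self.out_dim, self.heads = in_dim, out_dim, heads
        self.negative_slope = negative_slope
        self.concat = concat
        self.lin_l = [Linear(in_dim, out_dim, rng, bias=True) for _ in range(heads)]
        self.lin_r = [Linear(in_dim, out_dim, rng, bias=False) for _ in range(heads)]
        self.att = [Parameter(_glorot(rng, out_dim, 1, (out_dim, 1))) for _ in range(heads)]
        self.bias = Parameter(np.zeros(out_dim * heads if concat else out_dim))

    def __call__(self, x: Tensor, topo: GraphTopology) -> Tensor:
        src, dst = topo.with_self_loops()
        n = topo.n
        head_outs: list[Tensor] = []
        for h in range(self.heads):
            gl = self.lin_l[h](x)  # messages from source
            gr = self.lin_r[h](x)  # destination query
            s = gl.gather_rows(src) + gr.gather_rows(dst)
            e = s.leaky_relu(self.negative_slope).matmul(self.att[h])  # E x 1
            # segment softmax over each destination's in-neighborhood;
            # the per-group max shift is detached (softmax is shift-invariant)
            emax = np.full(n, -np.inf)
            np.maximum.at(emax, dst, e.data.ravel())
            emax[~np.isfinite(emax)] = 0.0
            z = (e + Tensor(-emax[dst][:, None])).exp()
            denom = z.scatter_add_rows(dst, n).gather_rows(dst)
            alpha = z / denom
            msg = gl.gather_rows(src) * alpha
            head_outs.append(msg.scatter_add_rows(dst, n))
        if self.concat:
            out = head_outs[0].concat(head_outs[1:], axis=1) if self.heads > 1 else head_outs[0]
        else:
            out = head_outs[0]
            for ho in head_outs[1:]:
                out = out + ho
            out = out * (1.0 / self.heads)
        return out + self.bias


class SAGEConv(Module):
    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        rng: np.random.Generator,
        aggregator: str = "max-pool",
    ):
        if aggregator not in ("max-pool", "mean"):
            raise ValueError(f"unknown aggregator {aggregator!r}")
        self.in_dim, self.out_dim = in_dim, out_dim
        self.aggregator = aggregator
        self.lin_r = Linear(in_dim, out_dim, rng, bias=True)   # root
        self.lin_l = Linear(in_dim, out_dim, rng, bias=False)  # aggregated
        self.pool = Linear(in_dim, in_dim, rng, bias=True) if aggregator == "max-pool" else None

    def __call__(self, x: Tensor, topo: GraphTopology) -> Tensor:
        src, dst = topo.src, topo.dst
        n = topo.n
        if self.aggregator == "mean":
            summed = x.gather_rows(src).scatter_add_rows(dst, n)
            deg = np.zeros(n)
            np.add.at(deg, dst, 1.0)
            agg = summed * Tensor(1.0 / np.maximum(deg, 1.0)[:, None])
        else:
            pooled = self.pool(x).relu()
            agg = pooled.gather_rows(src).segment_max(dst, n)
        return self.lin_r(x) + self.lin_l(agg)
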