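"""Neighbor-sampled mini-batches for scalable GraphSAGE training.

Training nodes are shuffled and partitioned into ceil(n_train / B) seed
sets.  For each seed set an L-hop subgraph is grown: at every hop, each
frontier node keeps all of its neighbors when it has at most ``fanout`` of
them, and otherwise draws ``fanout`` of them (with replacement, which keeps
the draw vectorizable; a node therefore never aggregates more than
``fanout`` sampled in-edges).  Sampled edges point *into* the frontier
node — the direction message passing needs — and nodes are de-duplicated,
so a subgraph never exceeds the full graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import GraphTopology

__all__ = ["GraphBatch", "sample_neighborhoods", "full_batch"]


@dataclass
class GraphBatch:
    """One subgraph: global node ids, local directed edges, seed prefix.

    The first ``seed_count`` entries of ``node_ids`` are the seed (loss)
    nodes.  ``topology`` indexes nodes locally (0..len(node_ids)-1).
    """

    node_ids: np.ndarray
    seed_count: int
    topology: GraphTopology

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def seed_ids(self) -> np.ndarray:
        return self.node_ids[: self.seed_count]

    def max_in_degree(self) -> int:
        """Largest sampled in-neighborhood (fanout audit)."""
        if len(self.topology.dst) == 0:
            return 0
        return int(np.bincount(self.topology.dst, minlength=self.n_nodes).max())


def full_batch(g) -> GraphBatch:
    """The whole graph as a single batch (full-graph training).

    The topology is cached on the graph, so repeated calls (one per
    training epoch) reuse the derived sparse structures.
    """
    topo = getattr(g, "_full_topology", None)
    if topo is None:
        src, dst = g.directed_edges()
        topo = GraphTopology(g.n_nodes, src, dst)
        try:
            g._full_topology = topo
        except AttributeError:
            pass
    return GraphBatch(
        node_ids=np.arange(g.n_nodes),
        seed_count=g.n_nodes,
        topology=topo,
    )


def _flat_adjacency(g) -> tuple[np.ndarray, np.ndarray]:
    """CSR-style (flat neighbor array, offsets), cached on the graph."""
    cached = getattr(g, "_flat_adj", None)
    if cached is not None:
        return cached
    src, dst = g.directed_edges()
    order = np.argsort(dst, kind="stable")
    flat = src[order]
    offsets = np.searchsorted(dst[order], np.arange(g.n_nodes + 1))
    try:
        g._flat_adj = (flat, offsets)
    except AttributeError:
        pass
    return flat, offsets


def _ragged_take(flat, offsets, nodes, counts):
    """All neighbors of ``nodes`` whose degrees are ``counts``, flattened."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(counts)])
    pos = (
        np.arange(total)
        - np.repeat(cum[:-1], counts)
        + np.repeat(offsets[nodes], counts)
    )
    return flat[pos]


def sample_neighborhoods(
    g,
    train_nodes: np.ndarray,
    batch_size: int,
    fanout: int,
    hops: int,
    seed: int = 0,
) -> list[GraphBatch]:
    """Partition ``train_nodes`` into seed sets and grow L-hop subgraphs.

    Every training node is a seed in exactly one batch; per hop, a node
    receives at most ``fanout`` sampled in-edges.  Deterministic under
    ``seed``.
    """
    train_nodes = np.asarray(train_nodes, dtype=np.int64)
    if batch_size < 1 or fanout < 1 or hops < 1:
        raise ValueError("batch_size, fanout and hops must be >= 1")
    if batch_size > g.n_nodes:
        batch_size = g.n_nodes
    rng = np.random.default_rng(seed)
    shuffled = train_nodes[rng.permutation(len(train_nodes))]
    flat, offsets = _flat_adjacency(g)
    n = g.n_nodes
    batches = []
    for start in range(0, len(shuffled), batch_size):
        seeds = shuffled[start:start + batch_size]
        local = np.full(n, -1, dtype=np.int64)
        local[seeds] = np.arange(len(seeds))
        node_parts = [seeds]
        count = len(seeds)
        src_parts: list[np.ndarray] = []
        dst_parts: list[np.ndarray] = []
        frontier = seeds
        for _ in range(hops):
            deg = offsets[frontier + 1] - offsets[frontier]
            has = deg > 0
            fr, dg = frontier[has], deg[has]
            if fr.size == 0:
                break
            small = dg <= fanout
            nbr_small = _ragged_take(flat, offsets, fr[small], dg[small])
            dst_small = np.repeat(fr[small], dg[small])
            big_fr, big_dg = fr[~small], dg[~small]
            if big_fr.size:
                draws = (rng.random((big_fr.size, fanout)) * big_dg[:, None]).astype(np.int64)
                nbr_big = flat[offsets[big_fr][:, None] + draws].ravel()
                dst_big = np.repeat(big_fr, fanout)
            else:
                nbr_big = np.empty(0, dtype=np.int64)
                dst_big = np.empty(0, dtype=np.int64)
            src_g = np.concatenate([nbr_small, nbr_big])
            dst_g = np.concatenate([dst_small, dst_big])
            new_nodes = np.unique(src_g[local[src_g] == -1])
            local[new_nodes] = count + np.arange(len(new_nodes))
            count += len(new_nodes)
            node_parts.append(new_nodes)
            src_parts.append(local[src_g])
            dst_parts.append(local[dst_g])
            frontier = new_nodes
        cat = lambda parts: (
            np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        )
        batches.append(
            GraphBatch(
                node_ids=cat(node_parts),
                seed_count=len(seeds),
                topology=GraphTopology(count, cat(src_parts), cat(dst_parts)),
            )
        )
    return batches
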