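"""Patient-similarity networks: thresholded graphs over a prepared cohort.

Each patient is a node carrying its feature vector and severity label.  An
edge connects two patients when the chosen pairwise measure passes a strict
threshold: similarity measures (cosine) connect when the value *exceeds*
the threshold, distance measures (euclidean, manhattan, minkowski) when the
value is *lower than* it.  Loosening the threshold therefore only ever adds
edges (nestedness), which is what the threshold sweeps exploit.

Edge weights store the raw cosine similarity, or ``1 / (1 + d)`` for
distance measures; message passing downstream is unweighted by default.

Pairwise values are computed in row blocks against the full matrix, with
edges emitted from the upper triangle only, keeping memory at
O(block_size x n) rather than O(n^2).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "MetricSpec",
    "MetricError",
    "PatientGraph",
    "NetworkStats",
    "pairwise_values",
    "build_graph",
    "network_stats",
    "threshold_sweep",
    "write_edgelist",
    "write_graphml",
    "write_node_table",
    "stats_table",
    "to_networkx",
]

SIMILARITY_METRICS = ("cosine",)
DISTANCE_METRICS = ("euclidean", "manhattan", "minkowski")

#: row-block size for the blocked pairwise pass
BLOCK = 512


class MetricError(ValueError):
    """Invalid metric configuration or input (e.g. zero-norm row)."""


@dataclass(frozen=True)
class MetricSpec:
    """A pairwise measure plus its edge threshold.

    ``direction`` is derived: cosine connects on ``value > threshold``,
    distances on ``value < threshold``.  ``p`` is required (and only
    allowed) for the Minkowski distance, ``(sum |x_k - y_k|^p)^(1/p)``.
    """

    name: str
    threshold: float
    p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.name not in SIMILARITY_METRICS + DISTANCE_METRICS:
            raise MetricError(f"unknown metric {self.name!r}")
        if self.name == "minkowski":
            if self.p is None or self.p < 1:
                raise MetricError("minkowski requires p >= 1")
        elif self.p is not None:
            raise MetricError(f"p is only meaningful for minkowski, not {self.name}")
        if self.name == "cosine":
            if not -1.0 <= self.threshold <= 1.0:
                raise MetricError("cosine threshold must be in [-1, 1]")
        elif self.threshold < 0:
            raise MetricError("distance threshold must be >= 0")

    @property
    def is_similarity(self) -> bool:
        return self.name in SIMILARITY_METRICS

    def connects(self, values: np.ndarray) -> np.ndarray:
        """Strict threshold predicate, elementwise."""
        if self.is_similarity:
            return values > self.threshold
        return values < self.threshold

    def weight(self, values: np.ndarray) -> np.ndarray:
        """Edge weight from the raw pairwise value."""
        if self.is_similarity:
            return values
        return 1.0 / (1.0 + values)


def _block_values(block: np.ndarray, X: np.ndarray, spec: MetricSpec) -> np.ndarray:
    if spec.name == "cosine":
        return 1.0 - cdist(block, X, metric="cosine")
    if spec.name == "euclidean":
        return cdist(block, X, metric="euclidean")
    if spec.name == "manhattan":
        return cdist(block, X, metric="cityblock")
    return cdist(block, X, metric="minkowski", p=spec.p)


def _check_rows(X: np.ndarray, spec: MetricSpec) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise MetricError("X must be a 2-D matrix")
    if np.isnan(X).any():
        raise MetricError("X contains missing values")
    if spec.name == "cosine":
        norms = np.linalg.norm(X, axis=1)
        bad = np.flatnonzero(norms == 0.0)
        if bad.size:
            raise MetricError(f"zero-norm row {bad[0]} under cosine similarity")
    return X


def pairwise_values(X: np.ndarray, metric: MetricSpec) -> np.ndarray:
    """Full symmetric n x n matrix of pairwise metric values.

    The diagonal is the self-value: 1 for cosine, 0 for distances.  For
    large n prefer :func:`build_graph`/:func:`threshold_sweep`, which work
    in row blocks and never materialize the full matrix.
    """
    X = _check_rows(X, metric)
    V = _block_values(X, X, metric)
    np.fill_diagonal(V, 1.0 if metric.is_similarity else 0.0)
    return V


@dataclass
class PatientGraph:
    """Undirected weighted patient-similarity network.

    Edges are stored once as (src, dst) index arrays with ``src < dst``;
    no self-loops, no duplicate pairs.  ``edge_weights[k]`` is the weight
    of edge ``(edge_src[k], edge_dst[k])``.
    """

    node_features: np.ndarray
    node_labels: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_weights: np.ndarray
    metric: Optional[MetricSpec] = None
    class_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.node_features = np.asarray(self.node_features, dtype=float)
        self.node_labels = np.asarray(self.node_labels, dtype=int)
        self.edge_src = np.asarray(self.edge_src, dtype=np.int64)
        self.edge_dst = np.asarray(self.edge_dst, dtype=np.int64)
        self.edge_weights = np.asarray(self.edge_weights, dtype=float)
        if (self.edge_src >= self.edge_dst).any():
            raise ValueError("edges must satisfy src < dst (no self-loops)")
        pairs = self.edge_src * self.n_nodes + self.edge_dst
        if len(np.unique(pairs)) != len(pairs):
            raise ValueError("duplicate edges")
        self._adj: Optional[list[np.ndarray]] = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_features)

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)

    @property
    def n_features(self) -> int:
        return self.node_features.shape[1]

    @property
    def n_classes(self) -> int:
        if self.class_names:
            return len(self.class_names)
        return int(self.node_labels.max()) + 1 if len(self.node_labels) else 0

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edge_src, 1)
        np.add.at(deg, self.edge_dst, 1)
        return deg

    def edge_set(self) -> set[tuple[int, int]]:
        return set(zip(self.edge_src.tolist(), self.edge_dst.tolist()))

    def directed_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Both directions of every undirected edge (no self-loops)."""
        src = np.concatenate([self.edge_src, self.edge_dst])
        dst = np.concatenate([self.edge_dst, self.edge_src])
        return src, dst

    def neighbors(self) -> list[np.ndarray]:
        """Adjacency lists, cached."""
        if self._adj is None:
            src, dst = self.directed_edges()
            order = np.argsort(dst, kind="stable")
            src_sorted, dst_sorted = src[order], dst[order]
            splits = np.searchsorted(dst_sorted, np.arange(self.n_nodes + 1))
            self._adj = [
                src_sorted[splits[i]:splits[i + 1]] for i in range(self.n_nodes)
            ]
        return self._adj

    def add_nodes(
        self, features: np.ndarray, labels: np.ndarray
    ) -> "PatientGraph":
        """Return a new graph with extra nodes wired in under this graph's
        metric — the inductive path for triaging novel patients."""
        if self.metric is None:
            raise ValueError("graph has no metric; cannot attach new nodes")
        features = np.atleast_2d(np.asarray(features, dtype=float))
        labels = np.atleast_1d(np.asarray(labels, dtype=int))
        n_old = self.n_nodes
        all_feats = np.vstack([self.node_features, features])
        new_src, new_dst, new_w = [], [], []
        vals = _block_values(features, all_feats, self.metric)
        for r in range(len(features)):
            gi = n_old + r
            row = vals[r].copy()
            row[gi] = np.inf if not self.metric.is_similarity else -np.inf
            hits = np.flatnonzero(self.metric.connects(row[: gi]))
            new_src.extend(hits.tolist())
            new_dst.extend([gi] * len(hits))
            new_w.extend(self.metric.weight(row[hits]).tolist())
        return PatientGraph(
            node_features=all_feats,
            node_labels=np.concatenate([self.node_labels, labels]),
            edge_src=np.concatenate([self.edge_src, np.array(new_src, dtype=np.int64)]),
            edge_dst=np.concatenate([self.edge_dst, np.array(new_dst, dtype=np.int64)]),
            edge_weights=np.concatenate([self.edge_weights, np.array(new_w)]),
            metric=self.metric,
            class_names=self.class_names,
        )


@dataclass(frozen=True)
class NetworkStats:
    """The per-network summary reported in threshold sweeps."""

    n_nodes: int
    n_edges: int
    n_isolated: int
    threshold: float
    metric: str
    p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_isolated > self.n_nodes:
            raise ValueError("more isolated nodes than nodes")
        if self.n_edges > self.n_nodes * (self.n_nodes - 1) // 2:
            raise ValueError("edge count exceeds complete graph")


def _iter_blocks(X: np.ndarray, spec: MetricSpec) -> Iterator[tuple[int, np.ndarray]]:
    for start in range(0, len(X), BLOCK):
        yield start, _block_values(X[start:start + BLOCK], X, spec)


def build_graph(pc, metric: MetricSpec) -> PatientGraph:
    """Threshold the pairwise measure over a prepared cohort into a graph.

    ``pc`` is a :class:`~trisimnet.cohort.PreparedCohort` or any object with
    ``X``/``y`` (and optionally ``class_names``) attributes.  Node order is
    preserved from the cohort.
    """
    X = _check_rows(pc.X, metric)
    y = np.asarray(pc.y, dtype=int)
    srcs, dsts, ws = [], [], []
    for start, vals in _iter_blocks(X, metric):
        for r in range(vals.shape[0]):
            i = start + r
            row = vals[r, i + 1:]  # upper triangle only
            hits = np.flatnonzero(metric.connects(row)) + i + 1
            if hits.size:
                srcs.append(np.full(hits.size, i, dtype=np.int64))
                dsts.append(hits.astype(np.int64))
                ws.append(metric.weight(vals[r, hits]))
    cat = lambda parts, dt: (
        np.concatenate(parts) if parts else np.empty(0, dtype=dt)
    )
    return PatientGraph(
        node_features=X,
        node_labels=y,
        edge_src=cat(srcs, np.int64),
        edge_dst=cat(dsts, np.int64),
        edge_weights=cat(ws, float),
        metric=metric,
        class_names=getattr(pc, "class_names", None),
    )


def network_stats(g: PatientGraph) -> NetworkStats:
    """Exact edge and isolated-node (degree-0) counts."""
    return NetworkStats(
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
        n_isolated=int((g.degrees() == 0).sum()),
        threshold=g.metric.threshold if g.metric else float("nan"),
        metric=g.metric.name if g.metric else "unknown",
        p=g.metric.p if g.metric else None,
    )


def threshold_sweep(
    pc,
    metric_name: str,
    thresholds: Sequence[float],
    p: Optional[float] = None,
) -> list[NetworkStats]:
    """Network statistics for several thresholds from one pairwise pass.

    The pairwise values are computed once per row block and every threshold
    is applied on the fly, which is how sweeps over 5-point grids stay
    affordable at cohort scale.
    """
    if not len(thresholds):
        raise ValueError("thresholds must be non-empty")
    specs = [MetricSpec(metric_name, th, p) for th in thresholds]
    X = _check_rows(pc.X, specs[0])
    n = len(X)
    n_edges = np.zeros(len(specs), dtype=np.int64)
    degrees = np.zeros((len(specs), n), dtype=np.int64)
    for start, vals in _iter_blocks(X, specs[0]):
        for r in range(vals.shape[0]):
            i = start + r
            row = vals[r, i + 1:]
            for s, spec in enumerate(specs):
                hits = np.flatnonzero(spec.connects(row)) + i + 1
                n_edges[s] += hits.size
                degrees[s, hits] += 1
                degrees[s, i] += hits.size
    return [
        NetworkStats(
            n_nodes=n,
            n_edges=int(n_edges[s]),
            n_isolated=int((degrees[s] == 0).sum()),
            threshold=spec.threshold,
            metric=spec.name,
            p=spec.p,
        )
        for s, spec in enumerate(specs)
    ]


# ---------------------------------------------------------------------------
# writers

def to_networkx(g: PatientGraph) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(
        (i, {"label": int(g.node_labels[i])}) for i in range(g.n_nodes)
    )
    G.add_weighted_edges_from(
        zip(g.edge_src.tolist(), g.edge_dst.tolist(), g.edge_weights.tolist())
    )
    return G


def write_edgelist(g: PatientGraph, path: str | Path) -> None:
    """Tab-separated ``src  dst  weight`` lines."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["src", "dst", "weight"])
        for i, j, wt in zip(g.edge_src, g.edge_dst, g.edge_weights):
            w.writerow([int(i), int(j), f"{wt:.10g}"])


def write_graphml(g: PatientGraph, path: str | Path) -> None:
    nx.write_graphml(to_networkx(g), str(path))


def write_node_table(g: PatientGraph, path: str | Path) -> None:
    """CSV of node id, label and features."""
    df = pd.DataFrame(
        g.node_features,
        columns=[f"f{k}" for k in range(g.n_features)],
    )
    df.insert(0, "label", g.node_labels)
    df.insert(0, "node", np.arange(g.n_nodes))
    df.to_csv(path, index=False)


def stats_table(stats: Sequence[NetworkStats]) -> pd.DataFrame:
    """Sweep results as a table (threshold, isolated_nodes, edges)."""
    return pd.DataFrame(
        {
            "metric": [s.metric for s in stats],
            "p": [s.p for s in stats],
            "threshold": [s.threshold for s in stats],
            "isolated_nodes": [s.n_isolated for s in stats],
            "edges": [s.n_edges for s in stats],
        }
    )
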