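"""The four triage GNN architectures and the ablation re-chaining rules.

Families
--------
``gcn5``
    Five GCNConv layers (F,64),(64,64),(64,64),(64,64),(64,C); ReLU after
    each non-final layer, 20% dropout after hidden layers 2-4.
``gcn4``
    Four GCNConv layers with hidden width 32: (F,32),(32,32),(32,32),(32,C);
    same dropout rate, placed after hidden layers 2-3.
``gatv2``
    Two GATv2Conv layers: (F, 8) with 4 attention heads (concatenated ->
    width 32), then (32, C); one 20% dropout before each attention layer.
``sage5``
    Five SAGEConv layers tapering (F,64),(64,32),(32,16),(16,8),(8,C);
    max-pool aggregation everywhere except the mean-aggregating third
    layer; ReLU after each non-final layer and a single 20% dropout after
    layer 4.

Ablation variants derive from ``sage5`` by removing layers 2-4 in the
stated patterns and re-chaining the remaining hidden widths as a geometric
taper starting from ``hidden_width`` (8 or 64), floored at C.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .autograd import Tensor
from .layers import GATv2Conv, GCNConv, GraphTopology, Module, SAGEConv

__all__ = ["ArchitectureSpec", "ArchitectureError", "GNNClassifier", "make_model", "ablation_spec"]

FAMILIES = ("gcn5", "gcn4", "gatv2", "sage5")


class ArchitectureError(ValueError):
    """Unknown family or inconsistent layer chaining."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of one GNN variant.

    ``layer_dims`` chains (in, out) per layer; for attention layers the next
    input equals ``out * heads``.  ``dropout_after`` uses 1-based layer
    indices, with 0 meaning dropout on the input features.
    """

    family: str
    layer_dims: tuple[tuple[int, int], ...]
    conv: str  # "gcn" | "gatv2" | "sage"
    heads: int = 1
    aggregators: Optional[tuple[str, ...]] = None
    dropout_rate: float = 0.2
    dropout_after: frozenset[int] = frozenset()
    activation: str = "relu"

    def __post_init__(self) -> None:
        if not self.layer_dims:
            raise ArchitectureError("at least one layer required")
        for k in range(len(self.layer_dims) - 1):
            out_dim = self.layer_dims[k][1]
            if self.conv == "gatv2" and k == 0:
                out_dim *= self.heads
            if out_dim != self.layer_dims[k + 1][0]:
                raise ArchitectureError(
                    f"layer {k + 1} out dim {out_dim} does not chain into "
                    f"layer {k + 2} in dim {self.layer_dims[k + 1][0]}"
                )
        if self.aggregators is not None and len(self.aggregators) != len(self.layer_dims):
            raise ArchitectureError("one aggregator per layer required")

    @property
    def n_layers(self) -> int:
        return len(self.layer_dims)

    @property
    def in_dim(self) -> int:
        return self.layer_dims[0][0]

    @property
    def out_dim(self) -> int:
        return self.layer_dims[-1][1]

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "layer_dims": [list(d) for d in self.layer_dims],
            "conv": self.conv,
            "heads": self.heads,
            "aggregators": list(self.aggregators) if self.aggregators else None,
            "dropout_rate": self.dropout_rate,
            "dropout_after": sorted(self.dropout_after),
            "activation": self.activation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(
            family=d["family"],
            layer_dims=tuple(tuple(x) for x in d["layer_dims"]),
            conv=d["conv"],
            heads=d["heads"],
            aggregators=tuple(d["aggregators"]) if d.get("aggregators") else None,
            dropout_rate=d["dropout_rate"],
            dropout_after=frozenset(d["dropout_after"]),
            activation=d.get("activation", "relu"),
        )


def architecture_spec(family: str, F: int, C: int) -> ArchitectureSpec:
    """The declarative spec for one named family at feature width F, C classes."""
    if family == "gcn5":
        return ArchitectureSpec(
            family="gcn5",
            layer_dims=((F, 64), (64, 64), (64, 64), (64, 64), (64, C)),
            conv="gcn",
            dropout_after=frozenset({2, 3, 4}),
        )
    if family == "gcn4":
        return ArchitectureSpec(
            family="gcn4",
            layer_dims=((F, 32), (32, 32), (32, 32), (32, C)),
            conv="gcn",
            dropout_after=frozenset({2, 3}),
        )
    if family == "gatv2":
        return ArchitectureSpec(
            family="gatv2",
            layer_dims=((F, 8), (32, C)),
            conv="gatv2",
            heads=4,
            dropout_after=frozenset({0, 1}),
        )
    if family == "sage5":
        return ArchitectureSpec(
            family="sage5",
            layer_dims=((F, 64), (64, 32), (32, 16), (16, 8), (8, C)),
            conv="sage",
            aggregators=("max-pool", "max-pool", "mean", "max-pool", "max-pool"),
            dropout_after=frozenset({4}),
        )
    raise ArchitectureError(f"unknown family {family!r}; known: {FAMILIES}")


def ablation_spec(
    removed_layers: Sequence[int], hidden_width: int, F: int, C: int
) -> ArchitectureSpec:
    """A sage5 ablation variant.

    ``removed_layers`` is a subset of {2, 3, 4} (1-based positions in the
    5-layer base).  Remaining hidden layers are re-chained with widths
    ``hidden_width, hidden_width/2, ...`` (floored at C) so every variant
    stays smaller than the base model.
    """
    removed = set(removed_layers)
    if not removed <= {2, 3, 4}:
        raise ArchitectureError("only layers 2-4 of sage5 can be removed")
    kept = [k for k in range(1, 6) if k not in removed]
    n_hidden = len(kept) - 1
    widths = [max(C, hidden_width >> i) for i in range(n_hidden)]
    dims = []
    prev = F
    for w in widths:
        dims.append((prev, w))
        prev = w
    dims.append((prev, C))
    # mirror the base design: mean aggregation at the third layer when the
    # variant is deep enough, max-pool elsewhere
    aggs = tuple(
        "mean" if (k == 2 and len(dims) >= 3) else "max-pool"
        for k in range(len(dims))
    )
    dropout_after = frozenset({len(dims) - 1}) if len(dims) >= 3 else frozenset()
    return ArchitectureSpec(
        family=f"sage5-ablate-{''.join(map(str, sorted(removed))) or 'none'}-w{hidden_width}",
        layer_dims=tuple(dims),
        conv="sage",
        aggregators=aggs,
        dropout_after=dropout_after,
    )


class GNNClassifier(Module):
    """A stack of convolution layers built from an :class:`ArchitectureSpec`."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.layers: list[Module] = []
        for k, (din, dout) in enumerate(spec.layer_dims):
            if spec.conv == "gcn":
                self.layers.append(GCNConv(din, dout, rng))
            elif spec.conv == "gatv2":
                last = k == spec.n_layers - 1
                self.layers.append(
                    GATv2Conv(din, dout, spec.heads if not last else 1, rng)
                )
            else:
                agg = spec.aggregators[k] if spec.aggregators else "mean"
                self.layers.append(SAGEConv(din, dout, rng, aggregator=agg))

    def forward(
        self,
        x: np.ndarray | Tensor,
        topo: GraphTopology,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        """Logits for every node.  Dropout fires only with ``training=True``."""
        h = x if isinstance(x, Tensor) else Tensor(x)
        if h.data.shape[1] != self.spec.in_dim:
            raise ArchitectureError(
                f"feature width {h.data.shape[1]} != model input {self.spec.in_dim}"
            )
        spec = self.spec
        if training and 0 in spec.dropout_after:
            h = h.dropout(spec.dropout_rate, rng)
        for k, layer in enumerate(self.layers):
            h = layer(h, topo)
            if k < spec.n_layers - 1 and spec.activation == "relu":
                h = h.relu()
            if training and (k + 1) in spec.dropout_after and k < spec.n_layers - 1:
                h = h.dropout(spec.dropout_rate, rng)
        return h

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ArchitectureError("state does not match parameter count")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ArchitectureError("state shape mismatch")
            p.data = s.copy()


def make_model(family: str, F: int, C: int, seed: int = 0) -> tuple[ArchitectureSpec, GNNClassifier]:
    """Build a named architecture with seeded Glorot initialization."""
    spec = architecture_spec(family, F, C)
    return spec, GNNClassifier(spec, seed=seed)
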