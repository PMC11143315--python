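"""Model/Results interface for triage node classification.

:class:`TriageGNN` binds a patient-similarity graph, an architecture and
split masks; :meth:`TriageGNN.fit` trains the network and returns a
:class:`TriageGNNResults` carrying the learned parameters, the training
history, per-split accuracies, the test confusion matrix and per-class
precision/recall, with a printable :meth:`~TriageGNNResults.summary`.

Example
-------
>>> from trisimnet import synthetic, cohort, graph
>>> from trisimnet.model import TriageGNN
>>> raw, _ = synthetic.generate_cohort(synthetic.CohortSpec(n=600, separation=6, seed=1))
>>> pc = cohort.preprocess(raw)
>>> g = graph.build_graph(pc, graph.MetricSpec("cosine", 0.9))
>>> res = TriageGNN(g, arch="sage5").fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Union

import numpy as np

from .evaluation import (
    ExperimentReport,
    SplitMasks,
    _per_class,
    _report_from_predictions,
    accuracy,
    confusion,
    make_split,
)
from .graph import PatientGraph, network_stats
from .nn import GNNClassifier, TrainConfig, TrainedClassifier
from .nn.architectures import ArchitectureSpec, architecture_spec
from .nn.training import default_config, forward_logits, predict, train

__all__ = ["TriageGNN", "TriageGNNResults"]


class TriageGNN:
    """A GNN node classifier bound to one patient-similarity graph.

    Parameters
    ----------
    graph : PatientGraph
        The thresholded similarity network (nodes = patients).
    arch : str or ArchitectureSpec
        A family name (``gcn5``, ``gcn4``, ``gatv2``, ``sage5``) or an
        explicit spec (e.g. an ablation variant).
    masks : SplitMasks, optional
        Train/validation/test node masks; a stratified default split is
        drawn with ``split_seed`` when omitted.
    """

    def __init__(
        self,
        graph: PatientGraph,
        arch: Union[str, ArchitectureSpec] = "sage5",
        masks: Optional[SplitMasks] = None,
        split_seed: int = 0,
        init_seed: int = 0,
    ):
        self.graph = graph
        F, C = graph.n_features, graph.n_classes
        if isinstance(arch, str):
            self.spec = architecture_spec(arch, F, C)
        else:
            self.spec = arch
            if self.spec.in_dim != F or self.spec.out_dim != C:
                raise ValueError(
                    f"spec expects ({self.spec.in_dim} -> {self.spec.out_dim}) "
                    f"but the graph has F={F}, C={C}"
                )
        self.masks = masks if masks is not None else make_split(
            graph.node_labels, seed=split_seed
        )
        self.init_seed = init_seed

    @classmethod
    def from_cohort(
        cls,
        prepared,
        metric,
        arch: Union[str, ArchitectureSpec] = "sage5",
        split_seed: int = 0,
        **kwargs,
    ) -> "TriageGNN":
        """Build the graph from a prepared cohort, then the model."""
        from .graph import build_graph

        g = build_graph(prepared, metric)
        return cls(g, arch=arch, split_seed=split_seed, **kwargs)

    def fit(self, cfg: Optional[TrainConfig] = None, **overrides) -> "TriageGNNResults":
        """Train and return results.  ``overrides`` adjust the family's
        default config (e.g. ``epochs=50``, ``seed=3``)."""
        if cfg is None:
            cfg = default_config(self.spec.family, **overrides)
        elif overrides:
            cfg = replace(cfg, **overrides)
        model = GNNClassifier(self.spec, seed=self.init_seed + cfg.seed)
        tc = train(model, self.graph, self.masks, cfg)
        return TriageGNNResults(self, tc)


class TriageGNNResults:
    """Fitted-model results: estimates, diagnostics and predictions."""

    def __init__(self, model: TriageGNN, trained: TrainedClassifier):
        self.model = model
        self.trained = trained
        self.graph = model.graph
        self.masks = model.masks
        self._logits = forward_logits(trained.model, self.graph)
        self.predictions = self._logits.argmax(axis=1)
        y = self.graph.node_labels
        self.accuracies = {
            f"{name}_accuracy": accuracy(self.predictions[m], y[m])
            for name, m in (
                ("train", self.masks.train),
                ("validation", self.masks.validation),
                ("test", self.masks.test),
            )
            if m.any()
        }
        self.confusion_matrix = confusion(
            self.predictions[self.masks.test], y[self.masks.test], self.graph.n_classes
        )
        self.class_precision, self.class_recall, self.macro_f1 = _per_class(
            self.confusion_matrix
        )

    @property
    def history(self) -> list[dict]:
        return self.trained.history

    @property
    def test_accuracy(self) -> float:
        return self.accuracies.get("test_accuracy", float("nan"))

    def predict(self, node_ids: Optional[np.ndarray] = None) -> np.ndarray:
        """Severity prediction for the given nodes (default: all)."""
        return predict(self.trained, self.graph, node_ids)

    def predict_new(self, features: np.ndarray, labels=None) -> np.ndarray:
        """Inductive prediction for unseen patients: attach them to the
        graph under its metric and run a forward pass, no retraining."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        k = len(features)
        dummy = np.zeros(k, dtype=int) if labels is None else np.asarray(labels)
        extended = self.graph.add_nodes(features, dummy)
        logits = forward_logits(self.trained.model, extended)
        return logits[-k:].argmax(axis=1)

    def report(self, split_seed: Optional[int] = None) -> ExperimentReport:
        """Serialize this fit as an :class:`ExperimentReport`."""
        cfg = self.trained.config
        config = {
            "model": self.trained.spec.family,
            "layer_dims": [list(d) for d in self.trained.spec.layer_dims],
            "learning_rate": cfg.learning_rate,
            "weight_decay": cfg.weight_decay,
            "epochs": cfg.epochs,
        }
        return _report_from_predictions(
            config=config,
            stats=network_stats(self.graph),
            y=self.graph.node_labels,
            pred=self.predictions,
            masks=self.masks,
            n_classes=self.graph.n_classes,
            seeds={"train": cfg.seed, "split": split_seed if split_seed is not None else self.masks.seed},
            history=self.history,
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        g, spec = self.graph, self.trained.spec
        stats = network_stats(g)
        lines = [
            "Triage similarity-network classifier",
            "=" * 52,
            f"architecture:      {spec.family}",
            f"layers:            {' -> '.join(str(d) for d in spec.layer_dims)}",
            f"parameters:        {self.trained.model.n_parameters()}",
            f"nodes / edges:     {g.n_nodes} / {g.n_edges}",
            f"isolated nodes:    {stats.n_isolated}",
            f"metric:            {stats.metric} (threshold {stats.threshold:g}"
            + (f", p={stats.p:g})" if stats.p else ")"),
            f"epochs run:        {len(self.history)}",
            "-" * 52,
        ]
        for k, v in self.accuracies.items():
            lines.append(f"{k + ':':<19}{v:.4f}")
        lines.append(f"{'macro F1:':<19}{self.macro_f1:.4f}")
        lines.append("-" * 52)
        names = self.graph.class_names or [
            str(c) for c in range(self.graph.n_classes)
        ]
        lines.append(f"{'class':<20}{'precision':>10}{'recall':>10}{'n_test':>8}")
        for c, name in enumerate(names):
            n_test = int(self.confusion_matrix[c].sum())
            lines.append(
                f"{name:<20}{self.class_precision[c]:>10.3f}"
                f"{self.class_recall[c]:>10.3f}{n_test:>8d}"
            )
        return "\n".join(lines)
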