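"""Experiment orchestration: splits, metrics, sweeps, ablations, baselines.

The split protocol is stratified 70/30 train/test, after which 30% of the
test nodes are re-assigned to a validation set (so at n=1000: 700 train,
90 validation, 210 test; masks are pairwise disjoint and cover all rows).

`run_experiment` executes the full pipeline — preprocess, build the
similarity graph, split, train a GNN, evaluate — and emits an
:class:`ExperimentReport`.  `sensitivity_analysis` repeats it over a
threshold grid per metric, `ablation_study` over reduced GraphSAGE
variants, and `tabular_baselines` trains SVM (RBF) and k-NN on the same
prepared features and split.

Rebalancing the whole cohort before splitting mirrors the preprocessing
workflow but lets synthetic minority samples leak across splits; a
leakage-safe mode (``split_before_balance=True``) splits first and SMOTEs
the training rows only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .cohort import BalanceConfig, PreparedCohort, PreprocessConfig, balance_classes, preprocess
from .graph import MetricSpec, NetworkStats, PatientGraph, build_graph
from .nn import ArchitectureSpec, TrainConfig, ablation_spec

__all__ = [
    "SplitMasks",
    "SplitError",
    "AblationVariant",
    "ExperimentReport",
    "make_split",
    "accuracy",
    "confusion",
    "run_experiment",
    "sensitivity_analysis",
    "ablation_study",
    "tabular_baselines",
]


class SplitError(ValueError):
    """A class is too small to stratify across the requested masks."""


@dataclass
class SplitMasks:
    """Disjoint boolean masks over the n cohort rows."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float] = (0.7, 0.3, 0.3)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        t, v, s = (np.asarray(m, dtype=bool) for m in (self.train, self.validation, self.test))
        self.train, self.validation, self.test = t, v, s
        if (t & v).any() or (t & s).any() or (v & s).any():
            raise SplitError("masks must be pairwise disjoint")
        if not (t | v | s).all():
            raise SplitError("masks must cover every row")

    @property
    def n(self) -> int:
        return len(self.train)


def make_split(
    y: np.ndarray,
    fractions: tuple[float, float, float] = (0.7, 0.3, 0.3),
    stratified: bool = True,
    seed: int = 0,
) -> SplitMasks:
    """Stratified train/test split with a validation set carved from test.

    ``fractions`` = (train share, test share, validation-share-of-test).
    Deterministic under ``seed``; raises :class:`SplitError` when a class
    is too small to appear in every mask.
    """
    y = np.asarray(y)
    n = len(y)
    f_train, f_test, f_val = fractions
    if abs(f_train + f_test - 1.0) > 1e-9 or not 0 < f_val < 1:
        raise SplitError(f"invalid fractions {fractions}")
    idx = np.arange(n)
    strat = y if stratified else None
    try:
        train_idx, test_all = train_test_split(
            idx, test_size=f_test, random_state=seed, stratify=strat
        )
        test_idx, val_idx = train_test_split(
            test_all,
            test_size=f_val,
            random_state=seed,
            stratify=y[test_all] if stratified else None,
        )
    except ValueError as exc:
        raise SplitError(f"stratified split failed: {exc}") from exc
    masks = SplitMasks(
        train=np.isin(idx, train_idx),
        validation=np.isin(idx, val_idx),
        test=np.isin(idx, test_idx),
        fractions=fractions,
        stratified=stratified,
        seed=seed,
    )
    return masks


def accuracy(pred: np.ndarray, true: np.ndarray) -> float:
    pred, true = np.asarray(pred), np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError("prediction/label length mismatch")
    return float((pred == true).mean())


def confusion(pred: np.ndarray, true: np.ndarray, n_classes: int) -> np.ndarray:
    """C x C counts; rows index the true class, columns the prediction."""
    pred, true = np.asarray(pred, dtype=int), np.asarray(true, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("prediction/label length mismatch")
    M = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(M, (true, pred), 1)
    return M


def _per_class(M: np.ndarray) -> tuple[list[float], list[float], float]:
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.diag(M) / M.sum(axis=1)
        precision = np.diag(M) / M.sum(axis=0)
        f1 = 2 * precision * recall / (precision + recall)
    recall = np.nan_to_num(recall)
    precision = np.nan_to_num(precision)
    f1 = np.nan_to_num(f1)
    return precision.tolist(), recall.tolist(), float(f1.mean())


@dataclass(frozen=True)
class AblationVariant:
    """One reduced GraphSAGE configuration for the ablation study."""

    removed_layers: frozenset[int] = frozenset()
    hidden_width: int = 8
    base: str = "sage5"

    def __post_init__(self) -> None:
        if self.base != "sage5":
            raise ValueError("ablation variants derive from sage5")
        if not set(self.removed_layers) <= {2, 3, 4}:
            raise ValueError("only layers 2-4 can be removed")

    @property
    def name(self) -> str:
        rm = "".join(map(str, sorted(self.removed_layers))) or "none"
        return f"-L{rm}/w{self.hidden_width}"


DEFAULT_ABLATION_GRID: tuple[AblationVariant, ...] = tuple(
    AblationVariant(frozenset(rm), w)
    for rm in ({2}, {3}, {4}, {2, 3, 4})
    for w in (8, 64)
)


@dataclass
class ExperimentReport:
    """Everything one configuration produced, serializable to JSON."""

    config: dict
    stats: Optional[NetworkStats]
    accuracies: dict[str, float]
    confusion_matrix: list[list[int]]
    class_precision: list[float]
    class_recall: list[float]
    macro_f1: float
    seeds: dict[str, int]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.provenance:
            blob = json.dumps({"config": self.config, "seeds": self.seeds}, sort_keys=True)
            self.provenance = hashlib.sha256(blob.encode()).hexdigest()[:16]

    @property
    def test_accuracy(self) -> float:
        return self.accuracies.get("test_accuracy", float("nan"))

    def to_dict(self) -> dict:
        d = {
            "config": self.config,
            "accuracies": self.accuracies,
            "confusion_matrix": self.confusion_matrix,
            "class_precision": self.class_precision,
            "class_recall": self.class_recall,
            "macro_f1": self.macro_f1,
            "seeds": self.seeds,
            "provenance": self.provenance,
        }
        if self.stats is not None:
            d["network"] = {
                "n_nodes": self.stats.n_nodes,
                "n_edges": self.stats.n_edges,
                "n_isolated": self.stats.n_isolated,
                "threshold": self.stats.threshold,
                "metric": self.stats.metric,
                "p": self.stats.p,
            }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _report_from_predictions(
    config: dict,
    stats: Optional[NetworkStats],
    y: np.ndarray,
    pred: np.ndarray,
    masks: SplitMasks,
    n_classes: int,
    seeds: dict[str, int],
    history: Optional[list[dict]] = None,
) -> ExperimentReport:
    accs = {}
    for name in ("train", "validation", "test"):
        mask = getattr(masks, name)
        if mask.any():
            accs[f"{name}_accuracy"] = accuracy(pred[mask], y[mask])
    M = confusion(pred[masks.test], y[masks.test], n_classes)
    precision, recall, macro_f1 = _per_class(M)
    if history:
        config = {**config, "epochs_run": len(history)}
    return ExperimentReport(
        config=config,
        stats=stats,
        accuracies=accs,
        confusion_matrix=M.tolist(),
        class_precision=precision,
        class_recall=recall,
        macro_f1=macro_f1,
        seeds=seeds,
    )


def _prepare(cohort, preprocess_cfg: Optional[PreprocessConfig]) -> PreparedCohort:
    if isinstance(cohort, PreparedCohort):
        return cohort
    return preprocess(cohort, preprocess_cfg or PreprocessConfig())


def run_experiment(
    cohort,
    metric: MetricSpec,
    arch: str | ArchitectureSpec = "sage5",
    train_cfg: Optional[TrainConfig] = None,
    split_seed: int = 0,
    preprocess_cfg: Optional[PreprocessConfig] = None,
    split_before_balance: bool = False,
) -> ExperimentReport:
    """Preprocess -> build graph -> split -> train -> evaluate.

    ``cohort`` may be a RawCohort or an already-prepared cohort.  With
    ``split_before_balance`` the cohort is split first and only training
    rows are SMOTEd (synthetic rows join the training mask), avoiding
    leakage of interpolated minority samples into the held-out sets.
    """
    from .model import TriageGNN  # local import to avoid a cycle

    if split_before_balance:
        base_cfg = preprocess_cfg or PreprocessConfig()
        balance = base_cfg.balance
        pc = _prepare(cohort, replace(base_cfg, balance=BalanceConfig(method="none")))
        masks = make_split(pc.y, seed=split_seed)
        pc, masks = _balance_train_only(pc, masks, balance)
    else:
        pc = _prepare(cohort, preprocess_cfg)
        masks = make_split(pc.y, seed=split_seed)
    g = build_graph(pc, metric)
    model = TriageGNN(g, arch=arch, masks=masks)
    res = model.fit(train_cfg)
    return res.report(split_seed=split_seed)


def _balance_train_only(
    pc: PreparedCohort, masks: SplitMasks, balance: BalanceConfig
) -> tuple[PreparedCohort, SplitMasks]:
    if balance.method == "none":
        return pc, masks
    Xb, yb = balance_classes(pc.X[masks.train], pc.y[masks.train], balance)
    n_new = len(Xb) - int(masks.train.sum())
    X_all = np.vstack([pc.X, Xb[-n_new:]]) if n_new else pc.X
    y_all = np.concatenate([pc.y, yb[-n_new:]]) if n_new else pc.y
    pc2 = PreparedCohort(
        X=np.clip(X_all, 0.0, 1.0),
        y=y_all,
        feature_names=pc.feature_names,
        class_names=pc.class_names,
        encoders=pc.encoders,
        log=pc.log + [{"action": "balance_train_only", "rows_added": n_new}],
    )
    pad = np.zeros(n_new, dtype=bool)
    masks2 = SplitMasks(
        train=np.concatenate([masks.train, ~pad]),
        validation=np.concatenate([masks.validation, pad]),
        test=np.concatenate([masks.test, pad]),
        fractions=masks.fractions,
        stratified=masks.stratified,
        seed=masks.seed,
    )
    return pc2, masks2


def sensitivity_analysis(
    cohort,
    grids: dict[str, Sequence[float]],
    archs: Sequence[str] = ("gcn5", "gatv2", "sage5"),
    p_values: Optional[dict[str, float]] = None,
    train_cfg: Optional[TrainConfig] = None,
    split_seed: int = 0,
    preprocess_cfg: Optional[PreprocessConfig] = None,
    include_baselines: bool = True,
) -> tuple[list[ExperimentReport], pd.DataFrame]:
    """One experiment per (metric, threshold, architecture).

    ``grids`` maps metric name to its threshold grid; ``p_values`` supplies
    p for minkowski entries (keys like ``"minkowski"``).  Returns all
    reports plus an accuracy-vs-threshold table with the tabular baselines
    (SVM, k-NN) as comparison rows when requested.
    """
    if not grids or any(not len(v) for v in grids.values()):
        raise ValueError("grids must be non-empty")
    pc = _prepare(cohort, preprocess_cfg)
    reports: list[ExperimentReport] = []
    rows = []
    for metric_name, thresholds in grids.items():
        p = (p_values or {}).get(metric_name)
        for th in thresholds:
            spec = MetricSpec(metric_name, th, p)
            for arch in archs:
                rep = run_experiment(
                    pc, spec, arch=arch, train_cfg=train_cfg, split_seed=split_seed
                )
                reports.append(rep)
                rows.append(
                    {
                        "metric": metric_name,
                        "p": p,
                        "threshold": th,
                        "model": arch,
                        "test_accuracy": rep.test_accuracy,
                    }
                )
    if include_baselines:
        for rep in tabular_baselines(pc, split_seed=split_seed):
            rows.append(
                {
                    "metric": "tabular",
                    "p": None,
                    "threshold": np.nan,
                    "model": rep.config["model"],
                    "test_accuracy": rep.test_accuracy,
                }
            )
            reports.append(rep)
    return reports, pd.DataFrame(rows)


def ablation_study(
    graph: PatientGraph,
    variants: Sequence[AblationVariant] = DEFAULT_ABLATION_GRID,
    train_cfg: Optional[TrainConfig] = None,
    masks: Optional[SplitMasks] = None,
    split_seed: int = 0,
    include_base: bool = True,
) -> list[ExperimentReport]:
    """Train the base GraphSAGE plus each reduced variant on one graph.

    The study design: remove layer 2, 3, 4, or all three, at hidden widths
    8 and 64 (8 variants), on the cosine-0.95 graph by default — the graph
    is supplied by the caller so any network can be ablated.
    """
    from .model import TriageGNN

    masks = masks or make_split(graph.node_labels, seed=split_seed)
    F, C = graph.n_features, graph.n_classes
    specs: list[tuple[str, ArchitectureSpec]] = []
    if include_base:
        from .nn.architectures import architecture_spec

        specs.append(("sage5", architecture_spec("sage5", F, C)))
    for v in variants:
        specs.append((v.name, ablation_spec(sorted(v.removed_layers), v.hidden_width, F, C)))
    reports = []
    for name, spec in specs:
        model = TriageGNN(graph, arch=spec, masks=masks)
        res = model.fit(train_cfg)
        rep = res.report(split_seed=split_seed)
        rep.config["variant"] = name
        reports.append(rep)
    return reports


def tabular_baselines(
    pc: PreparedCohort,
    split_seed: int = 0,
    svm_c: float = 1.0,
    knn_k: int = 5,
) -> list[ExperimentReport]:
    """SVM (RBF kernel) and k-NN on the prepared features, same split
    protocol and seed as the graph experiments."""
    masks = make_split(pc.y, seed=split_seed)
    X, y = pc.X, pc.y
    reports = []
    for name, clf in (
        ("svm_rbf", SVC(kernel="rbf", C=svm_c, random_state=split_seed)),
        ("knn", KNeighborsClassifier(n_neighbors=knn_k)),
    ):
        clf.fit(X[masks.train], y[masks.train])
        pred = clf.predict(X)
        reports.append(
            _report_from_predictions(
                config={"model": name, "kind": "tabular"},
                stats=None,
                y=y,
                pred=pred,
                masks=masks,
                n_classes=pc.n_classes,
                seeds={"split": split_seed},
            )
        )
    return reports
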