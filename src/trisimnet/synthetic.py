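"""Synthetic patient cohorts with controllable class structure.

The generator emits schema-conformant admission tables so that every
downstream stage (cleaning, imputation, encoding, SMOTE, graph building,
GNN training) can be exercised and audited without external data.

Generative model
----------------
Numeric features are drawn per class from isotropic Gaussian clusters whose
centroids sit at pairwise distance ``separation`` (an orthogonal-simplex
construction), with per-feature standard deviation ``noise_sd``; with
``separation=0`` the features carry no class signal at all.  Categorical
features are drawn from per-class multinomials: each class tilts probability
mass ``cat_strength`` onto one preferred category, so categoricals remain
label-informative after integer encoding.  After the clean table is built,
exact duplicate rows, missing feature cells and missing labels are injected
at the configured rates, and the injection counts are returned as ground
truth so cleaning logs can be checked exactly.

The generator makes no attempt to match any real cohort's marginal
distributions; its contract is schema conformance plus controllable
separability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import RawCohort
from .schemas import get_schema

__all__ = ["CohortSpec", "GroundTruth", "SpecError", "generate_cohort",
           "kaggle16_profile", "mimic14_profile"]


class SpecError(ValueError):
    """A cohort spec is internally inconsistent."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort draw.

    ``class_proportions`` is a simplex vector over the 4 severity classes
    (most to least severe, matching the schema's declared class order);
    the defaults mimic an imbalanced triage mix.  ``separation`` is the
    pairwise distance between class centroids in numeric-feature space and
    ``noise_sd`` the within-class standard deviation, so
    ``separation / noise_sd`` controls Bayes separability directly.
    """

    n: int = 6962
    schema_id: str = "kaggle16"
    class_proportions: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40)
    separation: float = 4.0
    noise_sd: float = 1.0
    cat_strength: float = 0.5
    missing_rate: float = 0.01
    missing_label_rate: float = 0.059
    duplicate_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SpecError("n must be positive")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise SpecError("class proportions must sum to 1")
        for name in ("missing_rate", "missing_label_rate", "duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise SpecError(f"{name} must be in [0, 1)")
        if self.separation < 0 or self.noise_sd < 0:
            raise SpecError("separation and noise_sd must be non-negative")
        if not 0.0 <= self.cat_strength <= 1.0:
            raise SpecError("cat_strength must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Bookkeeping of what the generator injected."""

    injected_duplicates: int
    injected_missing_cells: int
    injected_missing_labels: int
    class_centroids: np.ndarray  # C x F_numeric

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "injected_duplicates": self.injected_duplicates,
                    "injected_missing_cells": self.injected_missing_cells,
                    "injected_missing_labels": self.injected_missing_labels,
                    "class_centroids": self.class_centroids.tolist(),
                },
                indent=2,
            )
        )


def _simplex_centroids(
    n_classes: int, n_features: int, separation: float, rng: np.random.Generator
) -> np.ndarray:
    """C centroids at pairwise distance ``separation`` in F-dim space.

    Uses scaled rows of a random orthonormal basis: distinct orthonormal
    vectors e_i satisfy |e_i - e_j| = sqrt(2).
    """
    if n_features < n_classes:
        raise SpecError("need at least as many numeric features as classes")
    A = rng.standard_normal((n_features, n_classes))
    Q, _ = np.linalg.qr(A)
    return (separation / np.sqrt(2.0)) * Q.T  # C x F


def generate_cohort(spec: CohortSpec) -> tuple[RawCohort, GroundTruth]:
    """Draw one cohort; deterministic under ``spec.seed``."""
    schema = get_schema(spec.schema_id)
    rng = np.random.default_rng(spec.seed)
    classes = list(schema.label_classes)
    C = len(classes)
    if len(spec.class_proportions) != C:
        raise SpecError(
            f"{C} classes in schema {spec.schema_id!r} but "
            f"{len(spec.class_proportions)} proportions"
        )

    n_dup = int(round(spec.duplicate_rate * spec.n))
    n_clean = spec.n - n_dup
    if n_clean < C:
        raise SpecError("n too small for the requested duplicate rate")

    y_idx = rng.choice(C, size=n_clean, p=np.asarray(spec.class_proportions))
    if len(np.unique(y_idx)) < C:
        raise SpecError("some class drew no members; increase n or proportions")

    numeric_cols = [c for c in schema.columns if c.kind == "numeric"]
    cat_cols = [c for c in schema.columns if c.kind == "categorical"]
    centroids = _simplex_centroids(C, len(numeric_cols), spec.separation, rng)
    X_num = centroids[y_idx] + spec.noise_sd * rng.standard_normal(
        (n_clean, len(numeric_cols))
    )

    data: dict[str, object] = {}
    for j, col in enumerate(numeric_cols):
        data[col.name] = X_num[:, j]
    for col in cat_cols:
        cats = list(col.categories)
        K = len(cats)
        base = np.full(K, (1.0 - spec.cat_strength) / K)
        cells = np.empty(n_clean, dtype=object)
        for cls in range(C):
            probs = base.copy()
            probs[cls % K] += spec.cat_strength
            probs /= probs.sum()
            mask = y_idx == cls
            cells[mask] = rng.choice(cats, size=int(mask.sum()), p=probs)
        data[col.name] = cells
    data[schema.label_column] = np.asarray(classes, dtype=object)[y_idx]

    df = pd.DataFrame(data, columns=list(schema.feature_names) + [schema.label_column])

    # Missing labels and cells go on rows NOT involved in duplication so the
    # cleaning log can be compared with the injected counts exactly.
    n_protect = min(n_dup, n_clean)  # rows that will be copied
    free_rows = np.arange(n_protect, n_clean)

    n_miss_label = int(round(spec.missing_label_rate * spec.n))
    n_miss_label = min(n_miss_label, len(free_rows))
    label_rows = rng.choice(free_rows, size=n_miss_label, replace=False)
    df.loc[label_rows, schema.label_column] = np.nan

    optional_cols = [
        c.name for c in schema.columns if not c.mandatory
    ]
    n_miss_cells = int(round(spec.missing_rate * spec.n * len(optional_cols)))
    n_miss_cells = min(n_miss_cells, len(free_rows) * len(optional_cols))
    if n_miss_cells:
        flat = rng.choice(
            len(free_rows) * len(optional_cols), size=n_miss_cells, replace=False
        )
        for f in flat:
            r = free_rows[f // len(optional_cols)]
            col = optional_cols[f % len(optional_cols)]
            df.loc[r, col] = np.nan

    if n_dup:
        copies = df.iloc[:n_protect].copy()
        df = pd.concat([df, copies], ignore_index=True)

    perm = rng.permutation(len(df))
    df = df.iloc[perm].reset_index(drop=True)

    cohort = RawCohort(df, schema)
    cohort.log.append({"action": "synthesize", "rows": len(df), "seed": spec.seed})
    truth = GroundTruth(
        injected_duplicates=n_dup,
        injected_missing_cells=n_miss_cells,
        injected_missing_labels=n_miss_label,
        class_centroids=centroids,
    )
    return cohort, truth


def kaggle16_profile(**overrides) -> CohortSpec:
    """Default spec for the 16-feature admission-table layout."""
    return replace(CohortSpec(schema_id="kaggle16", n=6962), **overrides) if overrides else CohortSpec(
        schema_id="kaggle16", n=6962
    )


def mimic14_profile(**overrides) -> CohortSpec:
    """Default spec for the 14-feature ED-triage layout; the combined
    over/under-sampling path is the natural balance choice downstream."""
    base = CohortSpec(schema_id="mimic14", n=1500)
    return replace(base, **overrides) if overrides else base
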