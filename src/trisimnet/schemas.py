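"""Cohort schemas: which columns a patient table has and how to treat them.

A :class:`CohortSchema` declares, for one tabular cohort layout, the ordered
feature columns, which of them are categorical (and their closed vocabulary,
if known), which are mandatory (a row missing a mandatory value is dropped
during cleaning rather than imputed), and the label column with its severity
classes.

Two layouts ship with the package:

``kaggle16``
    A 16-feature emergency-admission table (vitals, biochemistry, comorbidity
    flags) with a 4-level triage code target.  Categorical features are
    residence type and smoking status; gender is mandatory.

``mimic14``
    A 14-feature ED-triage layout (vital signs, pain score, demographics,
    transport/disposition, medication text fields, length of stay in minutes)
    with a 4-level acuity target (1 = most severe).

Custom layouts can be loaded from a YAML or JSON file via :func:`load_schema`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "ColumnSpec",
    "CohortSchema",
    "SchemaError",
    "get_schema",
    "load_schema",
    "KAGGLE16",
    "MIMIC14",
]


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


@dataclass(frozen=True)
class ColumnSpec:
    """One feature column: its name, kind and (for categoricals) vocabulary."""

    name: str
    kind: str = "numeric"  # "numeric" | "categorical"
    categories: Optional[tuple[str, ...]] = None
    mandatory: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise SchemaError(f"unknown column kind {self.kind!r} for {self.name!r}")


@dataclass(frozen=True)
class CohortSchema:
    schema_id: str
    columns: tuple[ColumnSpec, ...]
    label_column: Optional[str] = None
    label_classes: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate column names in schema")
        if self.label_column is not None and self.label_column in names:
            raise SchemaError("label column must not also be a feature column")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)

    @property
    def categorical_columns(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns if c.kind == "categorical")

    @property
    def mandatory_columns(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns if c.mandatory)

    def column(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)


def _num(name: str, mandatory: bool = False) -> ColumnSpec:
    return ColumnSpec(name, "numeric", None, mandatory)


def _cat(name: str, categories: tuple[str, ...], mandatory: bool = False) -> ColumnSpec:
    return ColumnSpec(name, "categorical", categories, mandatory)


# 16-feature admission table with a 4-level triage code.  Gender is numeric
# (0/1-coded in the source table) but mandatory: a row missing it is dropped.
KAGGLE16 = CohortSchema(
    schema_id="kaggle16",
    columns=(
        _num("age"),
        _num("gender", mandatory=True),
        _num("chest_pain_type"),
        _num("blood_pressure"),
        _num("cholesterol"),
        _num("max_heart_rate"),
        _num("exercise_angina"),
        _num("plasma_glucose"),
        _num("skin_thickness"),
        _num("insulin"),
        _num("bmi"),
        _num("diabetes_pedigree"),
        _num("hypertension"),
        _num("heart_disease"),
        _cat("residence_type", ("Urban", "Rural")),
        _cat("smoking_status", ("never smoked", "smoke", "previously smoked", "Unknown")),
    ),
    label_column="triage",
    label_classes=("Red", "Orange", "Yellow", "Green"),
)

# 14 ED-triage features with a 4-level acuity target (1 = most severe).
MIMIC14 = CohortSchema(
    schema_id="mimic14",
    columns=(
        _num("temperature"),
        _num("heartrate"),
        _num("resprate"),
        _num("o2sat"),
        _num("sbp"),
        _num("dbp"),
        _num("pain"),
        _cat("gender", ("F", "M")),
        _cat("race", ("ASIAN", "BLACK", "HISPANIC", "OTHER", "WHITE")),
        _cat("arrival_transport", ("AMBULANCE", "HELICOPTER", "OTHER", "WALK IN")),
        _cat("disposition", ("ADMITTED", "ELOPED", "HOME", "OTHER", "TRANSFER")),
        _cat("name", ("acetaminophen", "albuterol", "aspirin", "ibuprofen", "morphine", "ondansetron")),
        _cat("etcdescription", ("analgesic", "antiemetic", "bronchodilator", "cardiovascular", "other")),
        _num("times_minutes"),
    ),
    label_column="acuity",
    label_classes=("1", "2", "3", "4"),
)

_BUILTIN = {"kaggle16": KAGGLE16, "mimic14": MIMIC14}


def get_schema(schema_id: str) -> CohortSchema:
    """Return a built-in schema by id."""
    try:
        return _BUILTIN[schema_id]
    except KeyError:
        raise SchemaError(
            f"unknown schema {schema_id!r}; built-ins are {sorted(_BUILTIN)}"
        ) from None


def load_schema(path: str | Path) -> CohortSchema:
    """Load a custom schema from a YAML or JSON file.

    Expected structure::

        schema_id: my_cohort
        label_column: severity
        label_classes: [low, medium, high, critical]   # optional
        columns:
          - {name: age, kind: numeric}
          - {name: sex, kind: categorical, categories: [F, M], mandatory: true}
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict) or "columns" not in raw:
        raise SchemaError(f"{path}: schema file must define 'columns'")
    cols = []
    for entry in raw["columns"]:
        cats = entry.get("categories")
        cols.append(
            ColumnSpec(
                name=str(entry["name"]),
                kind=entry.get("kind", "numeric"),
                categories=tuple(map(str, cats)) if cats else None,
                mandatory=bool(entry.get("mandatory", False)),
            )
        )
    classes = raw.get("label_classes")
    return CohortSchema(
        schema_id=str(raw.get("schema_id", path.stem)),
        columns=tuple(cols),
        label_column=raw.get("label_column"),
        label_classes=tuple(map(str, classes)) if classes else None,
    )
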