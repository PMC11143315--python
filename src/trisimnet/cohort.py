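"""Loading tabular patient cohorts and the preprocessing workflow.

The workflow turns a raw admission table into a model-ready cohort in five
steps, applied in this fixed order:

1. drop exact duplicate rows, rows with a missing label, and rows missing a
   mandatory demographic field (e.g. gender);
2. impute remaining missing cells with the column mode (ties broken toward
   the smallest value under the column's natural ordering);
3. label-encode categorical features and the target, mapping each distinct
   value to an integer by lexicographic order;
4. optionally rebalance classes (SMOTE, or combined over/under-sampling);
5. min-max scale every feature column into [0, 1] (constant columns map
   to 0).

Every step appends to a provenance log with row counts, so that cleaning
bookkeeping can be audited against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from .resampling import BalanceError, smote, smote_undersample
from .schemas import CohortSchema, SchemaError, get_schema, load_schema

__all__ = [
    "RawCohort",
    "PreparedCohort",
    "PreprocessConfig",
    "BalanceConfig",
    "CohortError",
    "ImputationError",
    "EncodingError",
    "load_cohort",
    "drop_duplicates_and_nulls",
    "impute_mode",
    "encode_categoricals",
    "balance_classes",
    "minmax_scale",
    "preprocess",
]

#: tokens treated as missing on load (plus genuinely empty cells)
MISSING_TOKENS = ["", "NA", "NaN", "nan"]


class CohortError(ValueError):
    """Generic cohort-processing failure."""


class ImputationError(CohortError):
    """A column cannot be imputed (all values missing)."""


class EncodingError(CohortError):
    """A categorical value was not seen when the encoder was built."""


@dataclass
class RawCohort:
    """An untyped patient table: rows are admissions, columns are features.

    ``df`` holds the feature columns in schema order plus, if present, the
    label column.  Values are kept as loaded; missing cells are ``NaN``.
    """

    df: pd.DataFrame
    schema: CohortSchema
    log: list[dict] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def has_label(self) -> bool:
        return (
            self.schema.label_column is not None
            and self.schema.label_column in self.df.columns
        )

    def copy(self) -> "RawCohort":
        return RawCohort(self.df.copy(), self.schema, list(self.log))


@dataclass
class PreparedCohort:
    """Model-ready cohort: features scaled into [0, 1], integer labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    class_names: list[str]
    encoders: dict[str, dict[str, int]]
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.y) != len(self.X):
            raise CohortError("X must be n x F with one label per row")
        if np.isnan(self.X).any():
            raise CohortError("prepared features contain missing values")
        if len(self.X) and (self.X.min() < -1e-12 or self.X.max() > 1 + 1e-12):
            raise CohortError("prepared features must lie in [0, 1]")

    @property
    def n_rows(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def save(self, outdir: str | Path) -> None:
        """Write features CSV, labels CSV and the JSON provenance log."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.X, columns=self.feature_names).to_csv(
            outdir / "features.csv", index=False
        )
        pd.DataFrame({"label": self.y}).to_csv(outdir / "labels.csv", index=False)
        meta = {
            "feature_names": self.feature_names,
            "class_names": self.class_names,
            "encoders": self.encoders,
            "log": self.log,
        }
        (outdir / "log.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, outdir: str | Path) -> "PreparedCohort":
        outdir = Path(outdir)
        X = pd.read_csv(outdir / "features.csv")
        y = pd.read_csv(outdir / "labels.csv")["label"].to_numpy()
        meta = json.loads((outdir / "log.json").read_text())
        return cls(
            X=X.to_numpy(dtype=float),
            y=y,
            feature_names=meta["feature_names"],
            class_names=meta["class_names"],
            encoders={k: dict(v) for k, v in meta["encoders"].items()},
            log=meta["log"],
        )


@dataclass(frozen=True)
class BalanceConfig:
    """How to rebalance classes before scaling.

    ``method`` is one of ``none`` (leave counts alone), ``smote``
    (oversample minorities to ``ratio`` x majority) or ``smote_undersample``
    (SMOTE up to the median class size, undersample down to it).
    """

    method: str = "smote"
    k_neighbors: int = 5
    ratio: float = 1.0  # 1.0 = equalize to the majority count
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("none", "smote", "smote_undersample"):
            raise CohortError(f"unknown balance method {self.method!r}")
        if self.k_neighbors < 1:
            raise CohortError("k_neighbors must be >= 1")
        if not 0.0 < self.ratio <= 1.0:
            raise CohortError("ratio must be in (0, 1]")


@dataclass(frozen=True)
class PreprocessConfig:
    drop_duplicate_rows: bool = True
    drop_rows_missing_label: bool = True
    impute_strategy: str = "column-mode"
    balance: BalanceConfig = field(default_factory=BalanceConfig)
    scale: str = "min-max"

    def __post_init__(self) -> None:
        if self.impute_strategy != "column-mode":
            raise CohortError(f"unknown impute strategy {self.impute_strategy!r}")
        if self.scale != "min-max":
            raise CohortError(f"unknown scaling {self.scale!r}")


def load_cohort(path: str | Path, schema_id: str = "kaggle16") -> RawCohort:
    """Load a delimited patient table under a named or custom schema.

    ``schema_id`` is a built-in id (``kaggle16``, ``mimic14``) or the path
    of a YAML/JSON schema file.  Column order follows the schema; extra
    columns in the file are ignored, missing feature columns are a schema
    error, and a missing label column is an error when the schema declares
    one.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cohort file not found: {path}")
    schema = (
        get_schema(schema_id)
        if schema_id in ("kaggle16", "mimic14")
        else (load_schema(schema_id) if Path(str(schema_id)).exists() else get_schema(schema_id))
    )
    # Detect duplicated header names before pandas mangles them.
    with open(path) as fh:
        header_line = fh.readline().strip()
    if not header_line:
        raise SchemaError(f"{path}: empty file")
    header = [h.strip() for h in header_line.split(",")]
    if len(set(header)) != len(header):
        raise SchemaError(f"{path}: duplicated column name in header")
    try:
        df = pd.read_csv(
            path, na_values=MISSING_TOKENS, keep_default_na=False, skipinitialspace=True
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise IOError(f"could not parse {path}: {exc}") from exc
    missing_cols = [c for c in schema.feature_names if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing feature columns {missing_cols}")
    cols = list(schema.feature_names)
    if schema.label_column is not None:
        if schema.label_column not in df.columns:
            raise SchemaError(f"{path}: missing label column {schema.label_column!r}")
        cols.append(schema.label_column)
    cohort = RawCohort(df[cols].copy(), schema)
    cohort.log.append({"action": "load", "rows": len(df), "source": str(path)})
    return cohort


def drop_duplicates_and_nulls(
    c: RawCohort, cfg: PreprocessConfig | None = None
) -> RawCohort:
    """Cleaning step: duplicates, missing labels, missing mandatory fields.

    Exact duplicate rows keep their first occurrence.  The provenance log
    records how many rows each rule removed, so
    ``rows_in == rows_out + duplicates + missing_label + missing_mandatory``.
    """
    cfg = cfg or PreprocessConfig()
    df = c.df
    n_in = len(df)
    n_dup = n_label = n_mand = 0
    if cfg.drop_duplicate_rows:
        dup_mask = df.duplicated(keep="first")
        n_dup = int(dup_mask.sum())
        df = df[~dup_mask]
    if cfg.drop_rows_missing_label and c.has_label:
        lbl_missing = df[c.schema.label_column].isna()
        n_label = int(lbl_missing.sum())
        df = df[~lbl_missing]
    for col in c.schema.mandatory_columns:
        miss = df[col].isna()
        n_mand += int(miss.sum())
        df = df[~miss]
    out = RawCohort(df.reset_index(drop=True), c.schema, list(c.log))
    out.log.append(
        {
            "action": "drop_duplicates_and_nulls",
            "rows_in": n_in,
            "duplicates_removed": n_dup,
            "missing_label_removed": n_label,
            "missing_mandatory_removed": n_mand,
            "rows_out": len(df),
        }
    )
    return out


def _column_mode(series: pd.Series):
    """Most frequent non-missing value; ties -> smallest under natural order."""
    counts = series.dropna().value_counts()
    if counts.empty:
        raise ImputationError(f"column {series.name!r} has no observed values")
    top = counts.max()
    candidates = counts[counts == top].index.tolist()
    return sorted(candidates)[0]


def impute_mode(c: RawCohort) -> RawCohort:
    """Replace every missing feature cell with its column mode."""
    df = c.df.copy()
    n_filled = 0
    for col in c.schema.feature_names:
        miss = df[col].isna()
        k = int(miss.sum())
        if k:
            df.loc[miss, col] = _column_mode(df[col])
            n_filled += k
    out = RawCohort(df, c.schema, list(c.log))
    out.log.append({"action": "impute_mode", "cells_filled": n_filled})
    return out


def _build_encoder(series: pd.Series) -> dict[str, int]:
    values = sorted({str(v) for v in series.dropna()})
    return {v: i for i, v in enumerate(values)}


def _apply_encoder(series: pd.Series, encoder: dict[str, int]) -> pd.Series:
    def enc(v):
        if pd.isna(v):
            return np.nan
        key = str(v)
        if key not in encoder:
            raise EncodingError(
                f"unseen category {key!r} in column {series.name!r}"
            )
        return encoder[key]

    return series.map(enc)


def encode_categoricals(
    c: RawCohort, encoders: Optional[dict[str, dict[str, int]]] = None
) -> tuple[RawCohort, dict[str, dict[str, int]]]:
    """Map categorical features (and the label) to integers.

    Each distinct value maps to its rank in lexicographic order, making the
    encoding invertible and reproducible.  Passing pre-built ``encoders``
    re-applies an existing mapping; an unseen value then raises
    :class:`EncodingError`.
    """
    df = c.df.copy()
    cols = list(c.schema.categorical_columns)
    if c.has_label:
        cols.append(c.schema.label_column)
    built: dict[str, dict[str, int]] = {}
    for col in cols:
        enc = (encoders or {}).get(col) or _build_encoder(df[col])
        df[col] = _apply_encoder(df[col], enc)
        built[col] = enc
    out = RawCohort(df, c.schema, list(c.log))
    out.log.append({"action": "encode_categoricals", "columns": cols})
    return out, built


def balance_classes(
    X: np.ndarray, y: np.ndarray, cfg: BalanceConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Rebalance class counts according to ``cfg`` (see :mod:`.resampling`)."""
    if cfg.method == "none":
        return np.asarray(X, dtype=float), np.asarray(y)
    if cfg.method == "smote":
        return smote(X, y, cfg.k_neighbors, cfg.ratio, cfg.seed)
    return smote_undersample(X, y, cfg.k_neighbors, cfg.seed)


def minmax_scale(X: np.ndarray) -> np.ndarray:
    """Per-column (x - min) / (max - min); constant columns map to 0."""
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        return X
    return MinMaxScaler().fit_transform(X)


def preprocess(c: RawCohort, cfg: PreprocessConfig | None = None) -> PreparedCohort:
    """Run the five-step workflow and return a :class:`PreparedCohort`.

    Order: clean -> impute -> encode -> balance -> scale.  The log carries
    the action sequence with row counts after each step.
    """
    cfg = cfg or PreprocessConfig()
    if not c.has_label:
        raise SchemaError("preprocess requires a label column")
    cleaned = drop_duplicates_and_nulls(c, cfg)
    imputed = impute_mode(cleaned)
    encoded, encoders = encode_categoricals(imputed)
    label_col = c.schema.label_column
    X = encoded.df[list(c.schema.feature_names)].to_numpy(dtype=float)
    y = encoded.df[label_col].to_numpy(dtype=int)
    log = list(encoded.log)
    try:
        Xb, yb = balance_classes(X, y, cfg.balance)
    except BalanceError:
        raise
    log.append(
        {
            "action": f"balance:{cfg.balance.method}",
            "rows_in": len(X),
            "rows_out": len(Xb),
        }
    )
    Xs = minmax_scale(Xb)
    log.append({"action": "minmax_scale", "rows": len(Xs)})
    label_encoder = encoders[label_col]
    class_names = [v for v, _ in sorted(label_encoder.items(), key=lambda kv: kv[1])]
    return PreparedCohort(
        X=Xs,
        y=yb,
        feature_names=list(c.schema.feature_names),
        class_names=class_names,
        encoders=encoders,
        log=log,
    )
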