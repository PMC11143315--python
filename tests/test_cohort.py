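"""Preprocessing workflow: cleaning, imputation, encoding, scaling."""

import numpy as np
import pandas as pd
import pytest

import trisimnet as tsn
from trisimnet.cohort import (
    BalanceConfig,
    ImputationError,
    PreprocessConfig,
    drop_duplicates_and_nulls,
    encode_categoricals,
    impute_mode,
    load_cohort,
    minmax_scale,
    preprocess,
)
from trisimnet.schemas import KAGGLE16, SchemaError


def _write_cohort_csv(tmp_path, df):
    path = tmp_path / "cohort.csv"
    df.to_csv(path, index=False)
    return path


def _tiny_df(n=3):
    raw, _ = tsn.generate_cohort(tsn.CohortSpec(n=50, seed=0, duplicate_rate=0,
                                                missing_rate=0, missing_label_rate=0))
    return raw.df.head(n).reset_index(drop=True)


class TestLoadCohort:
    def test_identity_load(self, tmp_path):
        df = _tiny_df(3)
        path = _write_cohort_csv(tmp_path, df)
        raw = load_cohort(path, "kaggle16")
        assert raw.n_rows == 3
        assert list(raw.df.columns) == list(KAGGLE16.feature_names) + ["triage"]

    def test_empty_file_is_schema_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(SchemaError):
            load_cohort(path, "kaggle16")

    def test_duplicate_header_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("a,b,a\n1,2,3\n")
        with pytest.raises(SchemaError):
            load_cohort(path, "kaggle16")

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(IOError):
            load_cohort(tmp_path / "nope.csv", "kaggle16")

    def test_missing_label_column_rejected(self, tmp_path):
        df = _tiny_df(3).drop(columns=["triage"])
        path = _write_cohort_csv(tmp_path, df)
        with pytest.raises(SchemaError):
            load_cohort(path, "kaggle16")

    def test_missing_tokens_become_nan(self, tmp_path):
        df = _tiny_df(3).astype(object)
        df.loc[0, "age"] = "NA"
        df.loc[1, "bmi"] = "NaN"
        df.loc[2, "insulin"] = ""
        path = _write_cohort_csv(tmp_path, df)
        raw = load_cohort(path, "kaggle16")
        assert raw.df["age"].isna()[0]
        assert raw.df["bmi"].isna()[1]
        assert raw.df["insulin"].isna()[2]


class TestCleaning:
    def test_duplicates_keep_first(self):
        df = _tiny_df(2)
        stacked = pd.concat([df.iloc[[0]], df.iloc[[0]], df.iloc[[1]]], ignore_index=True)
        raw = tsn.RawCohort(stacked, KAGGLE16)
        out = drop_duplicates_and_nulls(raw)
        assert out.n_rows == 2
        assert out.log[-1]["duplicates_removed"] == 1

    def test_missing_labels_dropped(self):
        df = _tiny_df(3).copy()
        df.loc[1, "triage"] = np.nan
        out = drop_duplicates_and_nulls(tsn.RawCohort(df, KAGGLE16))
        assert out.n_rows == 2
        assert out.log[-1]["missing_label_removed"] == 1

    def test_missing_mandatory_gender_dropped(self):
        df = _tiny_df(3).copy()
        df.loc[0, "gender"] = np.nan
        out = drop_duplicates_and_nulls(tsn.RawCohort(df, KAGGLE16))
        assert out.n_rows == 2
        assert out.log[-1]["missing_mandatory_removed"] == 1

    def test_count_conservation_brute_force(self):
        # 10 rows, 2 duplicates + 1 missing label -> 7 remain
        df = _tiny_df(8).copy()
        df = pd.concat([df, df.iloc[[0, 1]]], ignore_index=True)
        df.loc[4, "triage"] = np.nan
        out = drop_duplicates_and_nulls(tsn.RawCohort(df, KAGGLE16))
        rec = out.log[-1]
        assert out.n_rows == 7
        assert rec["rows_in"] == rec["rows_out"] + rec["duplicates_removed"] + \
            rec["missing_label_removed"] + rec["missing_mandatory_removed"]


class TestImputation:
    def test_unique_mode(self):
        df = _tiny_df(4).copy()
        df["residence_type"] = ["Urban", "Urban", "Rural", np.nan]
        out = impute_mode(tsn.RawCohort(df, KAGGLE16))
        assert out.df["residence_type"].iloc[3] == "Urban"

    def test_tie_breaks_to_smallest(self):
        df = _tiny_df(3).copy()
        df["age"] = [1.0, 2.0, np.nan]
        out = impute_mode(tsn.RawCohort(df, KAGGLE16))
        assert out.df["age"].iloc[2] == 1.0

    def test_matches_frequency_oracle(self, rng):
        df = _tiny_df(5).copy()
        df["age"] = [3.0, 3.0, 7.0, np.nan, np.nan]
        df["bmi"] = [np.nan, 2.0, 2.0, 2.0, 9.0]
        out = impute_mode(tsn.RawCohort(df, KAGGLE16))
        # independent per-column frequency count
        for col in ("age", "bmi"):
            observed = df[col].dropna().tolist()
            mode = sorted(
                {v: observed.count(v) for v in observed}.items(),
                key=lambda kv: (-kv[1], kv[0]),
            )[0][0]
            filled = out.df.loc[df[col].isna(), col]
            assert (filled == mode).all()
        assert not out.df[list(KAGGLE16.feature_names)].isna().any().any()

    def test_all_missing_column_errors(self):
        df = _tiny_df(3).copy()
        df["age"] = np.nan
        with pytest.raises(ImputationError, match="age"):
            impute_mode(tsn.RawCohort(df, KAGGLE16))


class TestEncoding:
    def test_lexicographic_order(self):
        df = _tiny_df(4).copy()
        df["residence_type"] = ["Urban", "Rural", "Urban", "Rural"]
        out, enc = encode_categoricals(tsn.RawCohort(df, KAGGLE16))
        assert enc["residence_type"] == {"Rural": 0, "Urban": 1}

    def test_round_trip_identity(self):
        df = _tiny_df(6).copy()
        df["smoking_status"] = ["smoke", "never smoked", "Unknown",
                                "previously smoked", "smoke", "Unknown"]
        out, enc = encode_categoricals(tsn.RawCohort(df, KAGGLE16))
        inverse = {v: k for k, v in enc["smoking_status"].items()}
        decoded = out.df["smoking_status"].map(inverse)
        assert (decoded == df["smoking_status"]).all()

    def test_four_categories_bijective(self):
        df = _tiny_df(4).copy()
        cats = ["never smoked", "smoke", "previously smoked", "Unknown"]
        df["smoking_status"] = cats
        _, enc = encode_categoricals(tsn.RawCohort(df, KAGGLE16))
        assert sorted(enc["smoking_status"].values()) == [0, 1, 2, 3]

    def test_unseen_category_errors(self):
        df = _tiny_df(2).copy()
        df["residence_type"] = ["Urban", "Rural"]
        _, enc = encode_categoricals(tsn.RawCohort(df, KAGGLE16))
        df2 = df.copy()
        df2["residence_type"] = ["Urban", "Suburban"]
        from trisimnet.cohort import EncodingError
        with pytest.raises(EncodingError):
            encode_categoricals(tsn.RawCohort(df2, KAGGLE16), encoders=enc)


class TestScaling:
    def test_linear_map(self):
        out = minmax_scale(np.array([[2.0], [4.0], [6.0]]))
        assert np.allclose(out.ravel(), [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        out = minmax_scale(np.array([[5.0], [5.0]]))
        assert np.allclose(out, 0.0)

    def test_extrema_recovered(self, rng):
        X = rng.uniform(-3, 9, size=(10, 4))
        out = minmax_scale(X)
        assert np.allclose(out.min(axis=0), 0.0)
        assert np.allclose(out.max(axis=0), 1.0)


class TestPreprocess:
    def test_clean_cohort_passthrough(self):
        raw, _ = tsn.generate_cohort(
            tsn.CohortSpec(n=100, seed=3, duplicate_rate=0, missing_rate=0,
                           missing_label_rate=0)
        )
        cfg = PreprocessConfig(balance=BalanceConfig(method="none"))
        pc = preprocess(raw, cfg)
        assert pc.n_rows == 100
        assert pc.X.shape == (100, 16)
        assert set(np.unique(pc.y)) <= {0, 1, 2, 3}

    def test_log_matches_generator_bookkeeping(self):
        raw, truth = tsn.generate_cohort(
            tsn.CohortSpec(n=200, seed=5, duplicate_rate=0.05,
                           missing_label_rate=0.05)
        )
        cfg = PreprocessConfig(balance=BalanceConfig(method="none"))
        pc = preprocess(raw, cfg)
        rec = next(e for e in pc.log if e["action"] == "drop_duplicates_and_nulls")
        assert rec["duplicates_removed"] == truth.injected_duplicates
        assert rec["missing_label_removed"] == truth.injected_missing_labels

    def test_scaling_bounds_invariant(self, prepared):
        assert prepared.X.min() >= 0.0
        assert prepared.X.max() <= 1.0
        assert not np.isnan(prepared.X).any()

    def test_determinism(self):
        spec = tsn.CohortSpec(n=150, seed=7)
        raw1, _ = tsn.generate_cohort(spec)
        raw2, _ = tsn.generate_cohort(spec)
        pc1, pc2 = tsn.preprocess(raw1), tsn.preprocess(raw2)
        assert np.array_equal(pc1.X, pc2.X)
        assert np.array_equal(pc1.y, pc2.y)

    def test_idempotence_on_prepared_data(self, prepared):
        """Re-running the workflow on already-prepared data changes nothing."""
        from trisimnet.schemas import CohortSchema, ColumnSpec

        cols = tuple(ColumnSpec(f, "numeric") for f in prepared.feature_names)
        schema = CohortSchema("prepared", cols, label_column="label")
        df = pd.DataFrame(prepared.X, columns=prepared.feature_names)
        df["label"] = prepared.y.astype(str)
        raw = tsn.RawCohort(df, schema)
        cfg = PreprocessConfig(balance=BalanceConfig(method="none"))
        pc2 = preprocess(raw, cfg)
        assert np.allclose(pc2.X, prepared.X, atol=1e-12)
        assert np.array_equal(pc2.y, prepared.y)

    def test_save_load_round_trip(self, prepared, tmp_path):
        prepared.save(tmp_path / "prep")
        back = tsn.PreparedCohort.load(tmp_path / "prep")
        assert np.allclose(back.X, prepared.X)
        assert np.array_equal(back.y, prepared.y)
        assert back.class_names == prepared.class_names
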