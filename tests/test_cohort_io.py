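import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from intense.cohort_io import (
    Factor,
    FactorSchema,
    encode_factors,
    load_cohort,
    make_cohort,
    normalize_cohort,
    zscore,
)
from intense.exceptions import CohortValidationError, DegenerateDataError, SchemaError

TOY = FactorSchema(
    (
        Factor("age", "continuous", units="years"),
        Factor("flag", "binary", ("absent", "present")),
        Factor("grade", "ordinal3", ("low", "mid", "high")),
    )
)


def _toy_csv(tmp_path, rows, name="cohort.csv", header="age,flag,grade"):
    path = tmp_path / name
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestSchema:
    def test_default_schema_has_25_uniquely_named_factors(self, schema):
        assert len(schema) == 25
        assert len(set(schema.names)) == 25
        kinds = {f.kind for f in schema.factors}
        assert kinds == {"continuous", "binary", "ordinal3"}
        assert schema["endometriosis"].level_order == ("absent", "suspected", "confirmed")

    def test_level_count_enforced(self):
        with pytest.raises(SchemaError):
            Factor("bad", "binary", ("only",))
        with pytest.raises(SchemaError):
            Factor("bad", "ordinal3", ("a", "b"))

    def test_duplicate_names_rejected(self):
        with pytest.raises(SchemaError):
            FactorSchema((Factor("x", "continuous"), Factor("x", "continuous")))

    def test_schema_json_round_trip(self, schema, tmp_path):
        path = tmp_path / "schema.json"
        schema.to_json(path)
        again = FactorSchema.from_json(path)
        assert again == schema


class TestLoadCohort:
    def test_valid_load_shape_and_column_order(self, tmp_path):
        path = _toy_csv(
            tmp_path,
            ["31.5,present,low", "28.0,absent,high", "40.2,present,mid"],
            header="flag,age,grade".replace("flag,age", "age,flag"),
        )
        table = load_cohort(path, TOY)
        assert (table.n_subjects, table.n_factors) == (3, 3)
        assert list(table.values.columns) == ["age", "flag", "grade"]

    def test_file_column_order_irrelevant(self, tmp_path):
        path = _toy_csv(
            tmp_path, ["present,31.5,low", "absent,28.0,high"], header="flag,age,grade"
        )
        table = load_cohort(path, TOY)
        assert list(table.values.columns) == ["age", "flag", "grade"]
        assert float(table.values.loc[0, "age"]) == 31.5

    def test_missing_column_named(self, tmp_path):
        path = _toy_csv(tmp_path, ["31.5,present", "28.0,absent"], header="age,flag")
        with pytest.raises(CohortValidationError, match="grade"):
            load_cohort(path, TOY)

    def test_unknown_level_names_row_and_column(self, tmp_path):
        path = _toy_csv(tmp_path, ["31.5,present,low", "28.0,maybe,high"])
        with pytest.raises(CohortValidationError, match=r"flag.*row 1|row 1.*flag"):
            load_cohort(path, TOY)

    def test_non_numeric_continuous_rejected(self, tmp_path):
        path = _toy_csv(tmp_path, ["31.5,present,low", "old,absent,high"])
        with pytest.raises(CohortValidationError, match="age"):
            load_cohort(path, TOY)

    def test_single_subject_rejected(self, tmp_path):
        path = _toy_csv(tmp_path, ["31.5,present,low"])
        with pytest.raises(CohortValidationError, match="at least 2"):
            load_cohort(path, TOY)

    def test_generated_cohort_round_trips_through_csv(self, tmp_path, cohort_seed1, schema):
        path = tmp_path / "cohort.csv"
        cohort_seed1.to_csv(path)
        again = load_cohort(path, schema)
        enc_a = encode_factors(cohort_seed1).to_numpy()
        enc_b = encode_factors(again).to_numpy()
        assert np.allclose(enc_a, enc_b)


class TestEncode:
    def test_positional_level_coding(self):
        frame = pd.DataFrame(
            {
                "age": [25.3, 30.0],
                "flag": ["present", "absent"],
                "grade": ["high", "mid"],
            }
        )
        enc = encode_factors(make_cohort(frame, TOY))
        assert enc["flag"].tolist() == [1.0, 0.0]
        assert enc["grade"].tolist() == [2.0, 1.0]
        assert enc["age"].tolist() == [25.3, 30.0]


class TestZscore:
    def test_simple_column(self):
        nm = zscore(np.array([[0.0], [1.0], [2.0]]))
        assert np.allclose(nm.values[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_column_is_degenerate(self):
        with pytest.raises(DegenerateDataError, match="f1"):
            zscore(np.array([[0.0, 5.0], [1.0, 5.0], [2.0, 5.0]]))

    def test_matches_two_pass_oracle(self, rng):
        x = rng.normal(size=(5, 1))
        nm = zscore(x)
        mean = sum(x[:, 0]) / 5
        sd = np.sqrt(sum((v - mean) ** 2 for v in x[:, 0]) / 4)
        assert np.allclose(nm.values[:, 0], (x[:, 0] - mean) / sd, atol=1e-12)

    def test_columns_standardized_exactly(self, normalized_seed1):
        Z = normalized_seed1.values
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        assert np.abs(Z.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_idempotent(self, rng):
        x = rng.normal(size=(20, 3))
        once = zscore(x).values
        twice = zscore(once).values
        assert np.allclose(once, twice, atol=1e-10)

    @settings(derandomize=True, max_examples=30)
    @given(
        a=st.floats(min_value=-50, max_value=50).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(min_value=-100, max_value=100),
    )
    def test_affine_invariance(self, a, b):
        x = np.arange(7.0).reshape(-1, 1) ** 2
        base = zscore(x).values
        transformed = zscore(a * x + b).values
        assert np.allclose(transformed, np.sign(a) * base, atol=1e-8)

    def test_binary_column_two_values_zero_weighted_mean(self):
        col = np.array([0.0, 0.0, 0.0, 1.0, 1.0]).reshape(-1, 1)
        z = zscore(col).values[:, 0]
        assert len(np.unique(z)) == 2
        assert abs(z.mean()) < 1e-12

    def test_missing_cells_error_by_default_and_imputable(self):
        x = np.array([[1.0, 2.0], [np.nan, 3.0], [3.0, 4.0]])
        with pytest.raises(CohortValidationError, match="row 1"):
            zscore(x)
        nm = zscore(x, impute_missing=True)
        assert np.isfinite(nm.values).all()

    def test_audit_csv_round_trip(self, tmp_path, normalized_seed1):
        path = tmp_path / "normalized.csv"
        normalized_seed1.to_csv(path)
        back = pd.read_csv(path)
        assert np.allclose(back.to_numpy(), normalized_seed1.values)
        assert list(back.columns) == normalized_seed1.factor_names


def test_normalize_cohort_shape(cohort_seed1):
    nm = normalize_cohort(cohort_seed1)
    assert nm.values.shape == (656, 25)
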