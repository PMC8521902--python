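"""Cohort table input, categorical encoding, and Z-score normalization.

A cohort is a subjects x factors table described by a :class:`FactorSchema`.
Every factor is one of three kinds:

``continuous``
    a real-valued measurement (age in years, a questionnaire score, ...);
``binary``
    two declared levels, encoded ``{0, 1}`` in ``level_order``;
``ordinal3``
    three ordered levels, encoded ``{0, 1, 2}`` in ``level_order``.

All downstream analyses consume the :class:`NormalizedMatrix` produced by
:func:`zscore`: each encoded column has the mean subtracted and is divided by
the sample standard deviation (``N - 1`` denominator), so the three clustering
views all see the factors on a common, unit-variance scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import CohortValidationError, DegenerateDataError, SchemaError

logger = logging.getLogger(__name__)

FACTOR_KINDS = ("continuous", "binary", "ordinal3")

_LEVEL_COUNT = {"binary": 2, "ordinal3": 3}


@dataclass(frozen=True)
class Factor:
    """A single column description.

    ``level_order`` fixes the numeric coding of categorical factors: the i-th
    level is encoded as the integer ``i``. Continuous factors have no levels.
    """

    name: str
    kind: str
    level_order: tuple[str, ...] = ()
    units: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FACTOR_KINDS:
            raise SchemaError(f"factor {self.name!r}: unknown kind {self.kind!r}")
        want = _LEVEL_COUNT.get(self.kind)
        if want is not None and len(self.level_order) != want:
            raise SchemaError(
                f"factor {self.name!r}: kind {self.kind!r} requires exactly "
                f"{want} levels, got {len(self.level_order)}"
            )
        if self.kind == "continuous" and self.level_order:
            raise SchemaError(f"factor {self.name!r}: continuous factors take no levels")
        if len(set(self.level_order)) != len(self.level_order):
            raise SchemaError(f"factor {self.name!r}: duplicate levels")

    @property
    def is_categorical(self) -> bool:
        return self.kind != "continuous"


@dataclass(frozen=True)
class FactorSchema:
    """An ordered collection of :class:`Factor` with unique names."""

    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate factor names: {dupes}")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    def __len__(self) -> int:
        return len(self.factors)

    def __getitem__(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.factors)

    def subset(self, names: Iterable[str]) -> "FactorSchema":
        return FactorSchema(tuple(self[n] for n in names))

    @classmethod
    def from_dict(cls, payload: dict) -> "FactorSchema":
        factors = []
        for entry in payload["factors"]:
            factors.append(
                Factor(
                    name=entry["name"],
                    kind=entry["kind"],
                    level_order=tuple(entry.get("level_order", ())),
                    units=entry.get("units", ""),
                    label=entry.get("label", ""),
                )
            )
        return cls(tuple(factors))

    @classmethod
    def from_json(cls, path: str | Path) -> "FactorSchema":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "factors": [
                {
                    "name": f.name,
                    "kind": f.kind,
                    **({"level_order": list(f.level_order)} if f.level_order else {}),
                    **({"units": f.units} if f.units else {}),
                    **({"label": f.label} if f.label else {}),
                }
                for f in self.factors
            ]
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")


def default_schema() -> FactorSchema:
    """The packaged 25-factor chronic-pelvic-pain schema.

    Covers demographics (age, parity, ethnicity, BMI), diagnoses
    (endometriosis, IBS, painful bladder syndrome), examination findings
    (pelvic floor tenderness, abdominal wall pain), psychological instruments
    (PHQ-9 depression, GAD-7 anxiety, Pain Catastrophizing Scale), history
    items, lifestyle factors, pain ratings, and the EHP-30 quality-of-life
    score.
    """
    payload = resources.files("intense.data").joinpath("default_schema.json")
    return FactorSchema.from_dict(json.loads(payload.read_text(encoding="utf-8")))


@dataclass
class CohortTable:
    """Raw cohort values (labels for categorical factors) plus their schema."""

    values: pd.DataFrame
    schema: FactorSchema

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    @property
    def n_factors(self) -> int:
        return len(self.schema)

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index=False)


def _validate_column(col: pd.Series, factor: Factor) -> None:
    if factor.is_categorical:
        allowed = set(factor.level_order)
        bad = col[~col.isna() & ~col.astype(str).isin(allowed)]
        if len(bad):
            row = int(bad.index[0])
            raise CohortValidationError(
                f"column {factor.name!r}, row {row}: level {bad.iloc[0]!r} is not "
                f"one of {sorted(allowed)}"
            )
    else:
        numeric = pd.to_numeric(col, errors="coerce")
        bad = col[numeric.isna() & ~col.isna()]
        if len(bad):
            row = int(bad.index[0])
            raise CohortValidationError(
                f"column {factor.name!r}, row {row}: non-numeric value {bad.iloc[0]!r} "
                "in a continuous column"
            )


def make_cohort(values: pd.DataFrame, schema: FactorSchema) -> CohortTable:
    """Validate a raw data frame against a schema and wrap it.

    Columns are reordered to schema order; extra columns are ignored.
    """
    missing = [n for n in schema.names if n not in values.columns]
    if missing:
        raise CohortValidationError(f"missing column(s): {missing}")
    if len(values) < 2:
        raise CohortValidationError(
            f"cohort has {len(values)} subject(s); at least 2 are required"
        )
    frame = values.loc[:, schema.names].reset_index(drop=True)
    for factor in schema.factors:
        _validate_column(frame[factor.name], factor)
    # continuous columns become floats once validated
    for factor in schema.factors:
        if not factor.is_categorical:
            frame[factor.name] = pd.to_numeric(frame[factor.name])
    return CohortTable(values=frame, schema=schema)


def load_cohort(path: str | Path, schema: FactorSchema | None = None) -> CohortTable:
    """Read a cohort CSV (header row, one row per subject, comma-separated).

    ``schema`` defaults to the packaged 25-factor schema. Column order in the
    file is irrelevant; the returned table follows schema order.
    """
    schema = schema if schema is not None else default_schema()
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    # continuous parsing happens in make_cohort after validation
    return make_cohort(frame, schema)


def encode_factors(table: CohortTable) -> pd.DataFrame:
    """Numeric encoding of a cohort: binary -> {0,1}, ordinal3 -> {0,1,2}
    positionally by ``level_order``; continuous values pass through.

    Missing cells become NaN and are handled (or rejected) by :func:`zscore`.
    """
    out = {}
    for factor in table.schema.factors:
        col = table.values[factor.name]
        if factor.is_categorical:
            mapping = {level: float(i) for i, level in enumerate(factor.level_order)}
            out[factor.name] = col.map(mapping)
        else:
            out[factor.name] = pd.to_numeric(col).astype(float)
    return pd.DataFrame(out, columns=table.schema.names)


@dataclass
class NormalizedMatrix:
    """Column-standardized data: each factor has mean 0 and sample sd 1.

    Stores the per-factor mean and sd actually used so the transform is
    auditable and invertible.
    """

    values: np.ndarray
    factor_names: list[str]
    means: np.ndarray = field(repr=False, default=None)
    sds: np.ndarray = field(repr=False, default=None)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_factors(self) -> int:
        return self.values.shape[1]

    def subset(self, names: Iterable[str]) -> "NormalizedMatrix":
        names = list(names)
        idx = [self.factor_names.index(n) for n in names]
        return NormalizedMatrix(
            values=self.values[:, idx],
            factor_names=names,
            means=None if self.means is None else self.means[idx],
            sds=None if self.sds is None else self.sds[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.factor_names)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def zscore(matrix: pd.DataFrame | np.ndarray, *, impute_missing: bool = False) -> NormalizedMatrix:
    """Z-score each column: ``(X - mean) / sd`` with the N-1 (sample) sd.

    Parameters
    ----------
    matrix
        Numeric N x F matrix (data frame from :func:`encode_factors` or a
        plain array).
    impute_missing
        If True, NaN cells are replaced by their column mean before
        standardizing (each imputed cell is logged); if False (default), any
        NaN raises :class:`CohortValidationError`.
    """
    if isinstance(matrix, pd.DataFrame):
        names = [str(c) for c in matrix.columns]
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        if X.ndim != 2:
            raise CohortValidationError("zscore expects a 2-D matrix")
        names = [f"f{i}" for i in range(X.shape[1])]
    if X.shape[0] < 2:
        raise CohortValidationError("zscore requires at least 2 rows")

    X = X.copy()
    nan_rows, nan_cols = np.nonzero(np.isnan(X))
    if nan_rows.size:
        if not impute_missing:
            r, c = int(nan_rows[0]), int(nan_cols[0])
            raise CohortValidationError(
                f"missing value at row {r}, column {names[c]!r} "
                "(pass impute_missing=True to mean-impute)"
            )
        for r, c in zip(nan_rows, nan_cols):
            fill = np.nanmean(X[:, c])
            logger.info("imputing row %d, column %r with column mean %.6g", r, names[c], fill)
            X[r, c] = fill

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    degenerate = np.nonzero(sds == 0)[0]
    if degenerate.size:
        raise DegenerateDataError(
            f"constant column(s) cannot be Z-scored: {[names[i] for i in degenerate]}"
        )
    Z = (X - means) / sds
    return NormalizedMatrix(values=Z, factor_names=names, means=means, sds=sds)


def normalize_cohort(table: CohortTable, *, impute_missing: bool = False) -> NormalizedMatrix:
    """Convenience: encode then Z-score a cohort table."""
    return zscore(encode_factors(table), impute_missing=impute_missing)
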