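"""Preprocessing: complete-case filtering, encoding, scaling, splitting.

Mirrors the study protocol: records with any missing value are excluded;
binary features are coded 1 = event present; sex, surgical specialty and
other nominal features are one-hot encoded with *no* reference level
dropped (the downstream symbolic-regression engine performs its own
feature selection, so collinearity among indicators is harmless);
continuous features are min-max scaled to [0, 1] with parameters fitted
on the training set only; and the cohort is split 80/20 stratified on
the outcome.

The stratified allocation is exact and deterministic: each class
contributes floor(fraction * class size) training rows, and the seats
still needed to reach round(fraction * n) go to the largest class first.
On a 1190-patient cohort with 66 events this reproduces a 952/238 split
carrying 52/14 events.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._rng import substream
from .cohort import ID_COLUMN, OUTCOME_COLUMN, CohortSchema
from .evaluation import stratified_allocation

__all__ = [
    "FeatureMatrix",
    "SplitSpec",
    "complete_case_filter",
    "encode",
    "scale_fit",
    "scale_apply",
    "stratified_split",
    "CohortPreprocessor",
    "write_matrix",
    "read_matrix",
    "infer_schema",
]


def sanitize(name: str) -> str:
    """Column names must fit the formula grammar: identifier characters only."""
    out = re.sub(r"[^0-9A-Za-z_]", "_", str(name))
    if not out or not re.match(r"[A-Za-z_]", out[0]):
        out = "f_" + out
    return out


@dataclass
class FeatureMatrix:
    """Fully numeric design matrix with provenance and scaling metadata.

    ``provenance`` maps every encoded column to its source feature, the
    one-hot level (or None) and the feature kind; ``scaling`` records the
    fitted per-column (min, max) once scaling has been applied.
    """

    X: pd.DataFrame
    y: pd.Series
    row_ids: pd.Series
    provenance: dict[str, dict] = field(default_factory=dict)
    scaling: dict[str, tuple[float, float]] | None = None

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    @property
    def continuous_columns(self) -> list[str]:
        return [c for c, p in self.provenance.items() if p["kind"] == "continuous"]

    def source_features(self) -> list[str]:
        """Original feature list recovered from column provenance."""
        seen: list[str] = []
        for p in self.provenance.values():
            if p["source"] not in seen:
                seen.append(p["source"])
        return seen

    def take(self, indices) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X.iloc[indices].reset_index(drop=True),
            y=self.y.iloc[indices].reset_index(drop=True),
            row_ids=self.row_ids.iloc[indices].reset_index(drop=True),
            provenance=self.provenance,
            scaling=self.scaling,
        )


@dataclass
class SplitSpec:
    fraction: float = 0.8
    outcome: str = OUTCOME_COLUMN
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fraction < 1:
            raise ValueError("train fraction must be in (0, 1)")


def complete_case_filter(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop every row with at least one missing cell.

    Raises if the outcome column itself carries missing values (that is a
    schema violation, not a missing-data pattern) or if no complete row
    remains.
    """
    if OUTCOME_COLUMN in table.columns and table[OUTCOME_COLUMN].isna().any():
        raise ValueError("outcome column contains missing values; "
                         "the cohort schema forbids a missing outcome")
    kept = table.dropna(axis=0, how="any")
    if len(kept) == 0:
        raise ValueError("empty cohort after complete-case filtering")
    return kept.reset_index(drop=True), len(table) - len(kept)


def infer_schema(table: pd.DataFrame) -> CohortSchema:
    """Fallback schema for tables arriving without one: object columns are
    categorical (levels = observed values), {0,1} integer columns binary,
    the rest continuous."""
    cont, binary, cat = [], [], {}
    for col in table.columns:
        if col in (ID_COLUMN, OUTCOME_COLUMN):
            continue
        s = table[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            cat[col] = tuple(sorted(s.dropna().astype(str).unique()))
        elif s.dropna().isin((0, 1)).all() and s.dtype.kind in "iub":
            binary.append(col)
        else:
            cont.append(col)
    return CohortSchema(tuple(cont), tuple(binary), cat)


def encode(table: pd.DataFrame, schema: CohortSchema | None = None) -> FeatureMatrix:
    """Complete-case table -> numeric matrix.

    Binary features pass through as {0,1}; each categorical feature
    expands into one indicator column per declared level (no reference
    level dropped), so indicators of a group sum to exactly 1 per row;
    continuous features pass through unscaled.  An observed category
    outside the declared level set is an error naming the value.
    """
    if schema is None:
        schema = infer_schema(table)
    if table[schema.feature_columns].isna().any().any():
        raise ValueError("encode requires a complete-case table")
    cols: dict[str, np.ndarray] = {}
    provenance: dict[str, dict] = {}
    for col in schema.continuous:
        name = sanitize(col)
        cols[name] = table[col].to_numpy(dtype=float)
        provenance[name] = {"source": col, "level": None, "kind": "continuous"}
    for col in schema.binary:
        vals = table[col]
        if not vals.isin((0, 1)).all():
            bad = vals[~vals.isin((0, 1))].iloc[0]
            raise ValueError(f"binary column {col!r} carries non-binary value {bad!r}")
        name = sanitize(col)
        cols[name] = vals.to_numpy(dtype=float)
        provenance[name] = {"source": col, "level": None, "kind": "binary"}
    for col, levels in schema.categorical.items():
        observed = table[col].astype(str)
        unknown = set(observed) - set(levels)
        if unknown:
            raise ValueError(
                f"unseen category {sorted(unknown)[0]!r} in column {col!r} "
                f"(declared levels: {list(levels)})")
        for level in levels:
            name = sanitize(f"{col}__{level}")
            cols[name] = (observed == level).to_numpy(dtype=float)
            provenance[name] = {"source": col, "level": level, "kind": "onehot"}
    X = pd.DataFrame(cols)
    y = (table[OUTCOME_COLUMN].astype(int).reset_index(drop=True)
         if OUTCOME_COLUMN in table.columns
         else pd.Series(np.zeros(len(table), dtype=int)))
    ids = (table[ID_COLUMN].reset_index(drop=True)
           if ID_COLUMN in table.columns
           else pd.Series([str(i) for i in range(len(table))]))
    return FeatureMatrix(X=X, y=y, row_ids=ids, provenance=provenance)


def scale_fit(matrix: FeatureMatrix,
              columns: Sequence[str] | None = None) -> dict[str, tuple[float, float]]:
    """Observed (min, max) per continuous column on the fitting set."""
    if columns is None:
        columns = matrix.continuous_columns
    params = {}
    for col in columns:
        if col not in matrix.X.columns:
            raise KeyError(f"column {col!r} not in matrix")
        v = matrix.X[col].to_numpy(dtype=float)
        params[col] = (float(v.min()), float(v.max()))
    return params


def scale_apply(matrix: FeatureMatrix,
                params: Mapping[str, tuple[float, float]]) -> FeatureMatrix:
    """Map x -> (x - min) / (max - min) per fitted column.

    A constant fitted column maps to 0.  Values outside the fitted range
    (test data under training parameters) are *not* clipped, preserving
    their ordering.
    """
    X = matrix.X.copy()
    for col, (lo, hi) in params.items():
        if col not in X.columns:
            raise KeyError(f"scaling parameters reference absent column {col!r}")
        if hi > lo:
            X[col] = (X[col] - lo) / (hi - lo)
        else:
            X[col] = 0.0
    return FeatureMatrix(X=X, y=matrix.y, row_ids=matrix.row_ids,
                         provenance=matrix.provenance, scaling=dict(params))


def stratified_split(table: pd.DataFrame,
                     spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outcome-stratified train/test partition with exact allocation."""
    y = table[spec.outcome].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present to stratify")
    if counts.min() < 2:
        raise ValueError("cannot stratify: a class has fewer than 2 members")
    alloc = stratified_allocation(dict(zip(classes.tolist(), counts.tolist())),
                                  spec.fraction)
    rng = substream(spec.seed, "split")
    train_idx = []
    for c in classes.tolist():
        members = np.flatnonzero(y == c)
        train_idx.append(rng.permutation(members)[: alloc[c]])
    train_idx = np.sort(np.concatenate(train_idx))
    mask = np.zeros(len(table), dtype=bool)
    mask[train_idx] = True
    return (table.iloc[mask].reset_index(drop=True),
            table.iloc[~mask].reset_index(drop=True))


class CohortPreprocessor(BaseEstimator, TransformerMixin):
    """Transformer view of the preprocessing chain.

    ``fit`` freezes the encoding schema and the min-max scaling
    parameters on the training cohort; ``transform`` encodes any cohort
    against that frozen schema (unseen categories are an error) and
    applies the training scaling without clipping.
    """

    def __init__(self, schema: CohortSchema | None = None):
        self.schema = schema

    def fit(self, table: pd.DataFrame, y=None):
        self.schema_ = self.schema if self.schema is not None else infer_schema(table)
        fitted = encode(table, self.schema_)
        self.scaling_ = scale_fit(fitted)
        self.provenance_ = fitted.provenance
        self.feature_names_out_ = fitted.columns
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "schema_"):
            raise RuntimeError("CohortPreprocessor is not fitted")
        return self.transform_matrix(table).X

    def transform_matrix(self, table: pd.DataFrame) -> FeatureMatrix:
        return scale_apply(encode(table, self.schema_), self.scaling_)


# ---------------------------------------------------------------------------
# on-disk artifacts: matrix CSV + JSON sidecar

def write_matrix(matrix: FeatureMatrix, path, sidecar_path=None) -> None:
    df = matrix.X.copy()
    df.insert(0, ID_COLUMN, matrix.row_ids)
    df[OUTCOME_COLUMN] = matrix.y
    df.to_csv(path, index=False, encoding="utf-8")
    if sidecar_path is not None:
        with open(sidecar_path, "w", encoding="utf-8") as fh:
            json.dump({"provenance": matrix.provenance,
                       "scaling": matrix.scaling}, fh, indent=1)


def read_matrix(path, sidecar_path=None) -> FeatureMatrix:
    df = pd.read_csv(path, encoding="utf-8")
    ids = df.pop(ID_COLUMN)
    y = df.pop(OUTCOME_COLUMN).astype(int)
    provenance, scaling = {}, None
    if sidecar_path is not None:
        with open(sidecar_path, encoding="utf-8") as fh:
            meta = json.load(fh)
        provenance = meta.get("provenance", {})
        scaling = meta.get("scaling")
        if scaling is not None:
            scaling = {k: tuple(v) for k, v in scaling.items()}
    return FeatureMatrix(X=df, y=y, row_ids=ids,
                         provenance=provenance, scaling=scaling)
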