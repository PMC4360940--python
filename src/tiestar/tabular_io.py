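"""Subject-level tabular datasets: schemas, CSV round-trip, imputation, discretization.

A :class:`Dataset` is the universal input of the pipeline: an ``n x p`` feature
table of mixed continuous / ordinal / binary columns, a per-feature
:class:`FeatureSchema`, and a binary outcome vector (1 = case, e.g. membership
in a non-remitting symptom trajectory).  Missing predictor values are carried
as NaN until :func:`impute_missing` resolves them; contingency-based
independence tests require discrete columns, which :func:`discretize`
produces from continuous ones by equal-frequency binning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("tiestar")

KINDS = ("continuous", "ordinal", "binary")


@dataclass(frozen=True)
class FeatureSchema:
    """Metadata for one predictor column.

    Parameters
    ----------
    name : str
        Unique column identifier.
    kind : {"continuous", "ordinal", "binary"}
        Statistical type; drives discretization and test selection.
    levels : tuple, optional
        Ordered category values for ordinal/binary columns.
    """

    name: str
    kind: str
    levels: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == "binary":
            if self.levels is not None and len(self.levels) != 2:
                raise ValueError(f"binary feature {self.name!r} must have exactly 2 levels")
        if self.kind == "ordinal":
            if self.levels is not None and len(self.levels) < 2:
                raise ValueError(f"ordinal feature {self.name!r} needs >= 2 levels")
        if self.kind == "continuous" and self.levels is not None:
            raise ValueError(f"continuous feature {self.name!r} cannot carry levels")


@dataclass
class Dataset:
    """Feature matrix + schema + binary outcome.

    ``features`` is a DataFrame (one column per schema entry, NaN = missing);
    ``outcome`` is an integer 0/1 vector of length ``n``.
    """

    features: pd.DataFrame
    schema: list[FeatureSchema]
    outcome: np.ndarray
    id: str = "dataset"

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=int)
        if self.features.shape[0] != self.outcome.shape[0]:
            raise ValueError("feature matrix and outcome length differ")
        if self.features.shape[0] < 1 or self.features.shape[1] < 1:
            raise ValueError("dataset needs n >= 1 rows and p >= 1 features")
        names = [s.name for s in self.schema]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in schema")
        if list(self.features.columns) != names:
            raise ValueError("schema order does not match feature columns")
        bad = set(np.unique(self.outcome)) - {0, 1}
        if bad:
            raise ValueError(f"outcome must be 0/1, found {sorted(bad)}")

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def schema_of(self, name: str) -> FeatureSchema:
        for s in self.schema:
            if s.name == name:
                return s
        raise KeyError(name)

    def subset_rows(self, index: np.ndarray) -> "Dataset":
        """Row subset (boolean mask or integer positions); schema shared."""
        feats = self.features.iloc[np.asarray(index)].reset_index(drop=True)
        return Dataset(feats, self.schema, self.outcome[np.asarray(index)], id=self.id)

    def has_both_classes(self) -> bool:
        return len(np.unique(self.outcome)) == 2

    def column_codes(self, name: str) -> np.ndarray:
        """Integer level codes (0..L-1, ascending by value) for a column."""
        col = self.features[name].to_numpy()
        if np.any(pd.isna(col)):
            raise ValueError(f"column {name!r} has missing values; impute first")
        _, codes = np.unique(col, return_inverse=True)
        return codes.astype(np.int64)


# -- CSV + schema round trip ---------------------------------------------


def _schema_from_mapping(mapping: dict) -> list[FeatureSchema]:
    out = []
    for name, spec in mapping.items():
        if isinstance(spec, str):
            spec = {"kind": spec}
        levels = spec.get("levels")
        out.append(
            FeatureSchema(str(name), spec["kind"], tuple(levels) if levels is not None else None)
        )
    return out


def read_schema(path) -> list[FeatureSchema]:
    with open(path, "r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh)
    if not mapping:
        raise ValueError(f"empty schema file {path}")
    return _schema_from_mapping(mapping)


def write_schema(schema: Sequence[FeatureSchema], path) -> None:
    mapping = {}
    for s in schema:
        entry: dict = {"kind": s.kind}
        if s.levels is not None:
            entry["levels"] = [lv.item() if hasattr(lv, "item") else lv for lv in s.levels]
        mapping[s.name] = entry
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(mapping, fh, sort_keys=False)


def read_dataset(path, schema_path, outcome_name: str) -> Dataset:
    """Load a validated Dataset from a CSV file and its sidecar schema.

    Rows with a missing outcome are dropped (count logged).  The outcome
    column must contain exactly two distinct values; the larger value maps
    to 1 (case).
    """
    frame = pd.read_csv(path)
    if frame.shape[0] == 0:
        raise ValueError(f"empty data file {path}")
    schema = read_schema(schema_path)
    if outcome_name not in frame.columns:
        raise ValueError(f"outcome column {outcome_name!r} not in {path}")
    names = [s.name for s in schema]
    unknown = set(names) - set(frame.columns)
    if unknown:
        raise ValueError(f"schema names missing from data: {sorted(unknown)}")
    uncovered = set(frame.columns) - set(names) - {outcome_name}
    if uncovered:
        raise ValueError(f"data columns not covered by schema: {sorted(uncovered)}")

    missing_outcome = frame[outcome_name].isna()
    if missing_outcome.any():
        logger.info("dropped %d rows with missing outcome", int(missing_outcome.sum()))
        frame = frame.loc[~missing_outcome].reset_index(drop=True)
    values = np.unique(frame[outcome_name].to_numpy())
    if len(values) != 2:
        raise ValueError(
            f"outcome {outcome_name!r} must be binary, found {len(values)} distinct values"
        )
    outcome = (frame[outcome_name].to_numpy() == values[1]).astype(int)
    return Dataset(frame[names].copy(), schema, outcome, id=str(path))


def write_dataset(dataset: Dataset, path, schema_path=None, outcome_name: str = "outcome") -> None:
    frame = dataset.features.copy()
    frame[outcome_name] = dataset.outcome
    frame.to_csv(path, index=False)
    if schema_path is not None:
        write_schema(dataset.schema, schema_path)


# -- cleaning ------------------------------------------------------------


def impute_missing(dataset: Dataset) -> Dataset:
    """Deterministic per-column imputation: median (continuous), mode (discrete).

    Mode ties break toward the smaller value.  Imputation counts are logged
    per column; a dataset without missing values is returned unchanged.
    """
    feats = dataset.features
    if not feats.isna().any().any():
        return dataset
    feats = feats.copy()
    for s in dataset.schema:
        col = feats[s.name]
        n_missing = int(col.isna().sum())
        if n_missing == 0:
            continue
        if col.isna().all():
            raise ValueError(f"column {s.name!r} is entirely missing")
        if s.kind == "continuous":
            fill = float(col.median())
        else:
            counts = col.value_counts()
            top = counts[counts == counts.max()]
            fill = sorted(top.index)[0]
        feats[s.name] = col.fillna(fill)
        logger.info("imputed %d values in %s with %r", n_missing, s.name, fill)
    return Dataset(feats, dataset.schema, dataset.outcome, id=dataset.id)


def discretize(dataset: Dataset, bins: int = 3, strategy: str = "equal_frequency") -> Dataset:
    """Equal-frequency binning of continuous columns into ordinal codes.

    Each continuous column becomes an ordinal column with at most ``bins``
    levels (0..bins-1), larger raw value mapping to the same-or-larger level.
    Ordinal and binary columns pass through unchanged.  A column with fewer
    distinct values than requested bins collapses to its distinct-value
    count with a warning.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if strategy != "equal_frequency":
        raise ValueError(f"unknown discretization strategy {strategy!r}")
    feats = dataset.features.copy()
    schema: list[FeatureSchema] = []
    for s in dataset.schema:
        if s.kind != "continuous":
            schema.append(s)
            continue
        col = feats[s.name]
        distinct = col.nunique(dropna=True)
        if distinct < bins:
            warnings.warn(
                f"column {s.name!r} has {distinct} distinct values < {bins} bins; collapsing",
                stacklevel=2,
            )
        if distinct == 1:
            codes = pd.Series(np.zeros(len(col)), index=col.index)
        else:
            codes = pd.qcut(col, q=min(bins, distinct), labels=False, duplicates="drop")
        codes = codes.where(col.notna())
        feats[s.name] = codes
        n_levels = int(codes.dropna().nunique())
        levels = tuple(range(n_levels)) if n_levels >= 2 else None
        schema.append(FeatureSchema(s.name, "ordinal", levels))
    return Dataset(feats, schema, dataset.outcome, id=dataset.id)
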