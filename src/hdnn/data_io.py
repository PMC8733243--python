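"""Labeled feature tables: reading, writing, validation and stratified splitting.

The universal currency of the pipeline is the :class:`FeatureTable` — an
``n_samples x n_features`` numeric matrix with binary labels (1 = positive
pre-miRNA hairpin, 0 = pseudo-hairpin), feature names and sample ids.
Tables are exchanged as delimited text (CSV/TSV) with a header row; a
serial-number/id column, if present, is dropped by explicit name, never by
position heuristics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .errors import (
    DomainError,
    FormatError,
    LabelError,
    ParseError,
    StratificationError,
)

__all__ = [
    "FeatureTable",
    "DatasetManifest",
    "read_feature_table",
    "write_feature_table",
    "stratified_split",
]


@dataclass
class FeatureTable:
    """An immutable-by-convention table of numeric features with binary labels.

    Invariants (checked at construction):

    * ``features`` is 2-D, finite, with one row per label and per sample id;
    * ``labels`` contain only 0 and 1;
    * ``feature_names`` has one entry per feature column.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2:
            raise DomainError("features must be a 2-D matrix")
        n, p = self.features.shape
        if self.labels.shape != (n,):
            raise DomainError(
                f"labels length {self.labels.shape} does not match {n} rows"
            )
        if len(self.sample_ids) != n:
            raise DomainError(f"sample_ids length {len(self.sample_ids)} != {n} rows")
        if len(self.feature_names) != p:
            raise DomainError(
                f"feature_names length {len(self.feature_names)} != {p} columns"
            )
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise LabelError(f"labels outside {{0, 1}}: {sorted(bad)}")
        if not np.isfinite(self.features).all():
            i, j = np.argwhere(~np.isfinite(self.features))[0]
            raise DomainError(
                f"non-finite feature value at row {i}, column {self.feature_names[j]!r}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == 0).sum())

    def take(self, indices: Sequence[int] | np.ndarray) -> "FeatureTable":
        """Row-subset the table, preserving the given index order."""
        idx = np.asarray(indices, dtype=np.intp)
        return FeatureTable(
            features=self.features[idx],
            labels=self.labels[idx],
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def to_frame(self, label_column: str = "label", id_column: str = "id") -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df.insert(0, id_column, self.sample_ids)
        df[label_column] = self.labels
        return df


@dataclass(frozen=True)
class DatasetManifest:
    """Name plus class counts of a genome-scale dataset (not the data itself)."""

    name: str
    n_positive: int
    n_negative: int

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise DomainError("manifest counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_positive + self.n_negative

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "name": self.name,
                    "n_positive": self.n_positive,
                    "n_negative": self.n_negative,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "DatasetManifest":
        with open(path) as fh:
            doc = json.load(fh)
        try:
            return cls(doc["name"], int(doc["n_positive"]), int(doc["n_negative"]))
        except KeyError as exc:
            raise FormatError(f"manifest missing field {exc}") from exc


def read_feature_table(
    path,
    label_column: str = "label",
    id_column: str | None = None,
    delimiter: str = ",",
    label_map: Mapping[object, int] | None = None,
) -> FeatureTable:
    """Read a delimited feature table with a header row.

    All columns other than ``label_column`` and the optional ``id_column``
    (a serial-number attribute, dropped from the feature matrix) must be
    numeric. ``label_map`` optionally maps string labels such as
    ``positive``/``negative`` onto 1/0 before validation.
    """
    # round_trip parsing: exact inverse of the %.17g text written on save
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    if label_column not in df.columns:
        raise FormatError(f"label column {label_column!r} not found in {path}")
    if id_column is not None and id_column not in df.columns:
        raise FormatError(f"id column {id_column!r} not found in {path}")

    labels_raw = df[label_column]
    if label_map is not None:
        labels_raw = labels_raw.map(lambda v: label_map.get(v, v))
    labels = pd.to_numeric(labels_raw, errors="coerce")
    if labels.isna().any() or not set(labels.unique()) <= {0, 1}:
        bad = labels_raw[~labels.isin([0, 1])].iloc[0]
        raise LabelError(f"label value {bad!r} is not in {{0, 1}}")

    if id_column is not None:
        sample_ids = df[id_column].astype(str).tolist()
    else:
        sample_ids = [str(i) for i in range(len(df))]

    drop = [label_column] + ([id_column] if id_column is not None else [])
    feat_df = df.drop(columns=drop)
    for col in feat_df.columns:
        coerced = pd.to_numeric(feat_df[col], errors="coerce")
        if coerced.isna().any() and not feat_df[col].isna().any():
            row = int(coerced.index[coerced.isna()][0])
            raise ParseError(
                f"non-numeric value {feat_df[col][row]!r} at row {row}, column {col!r}"
            )
        feat_df[col] = coerced
    if feat_df.isna().any().any():
        col = feat_df.columns[feat_df.isna().any()][0]
        row = int(feat_df.index[feat_df[col].isna()][0])
        raise ParseError(f"missing value at row {row}, column {col!r}")

    return FeatureTable(
        features=feat_df.to_numpy(dtype=np.float64),
        labels=labels.to_numpy(dtype=np.int64),
        feature_names=list(feat_df.columns),
        sample_ids=sample_ids,
    )


def write_feature_table(
    table: FeatureTable,
    path,
    delimiter: str = ",",
    label_column: str = "label",
    id_column: str = "id",
):
    """Write a table as delimited text; round-trips bit-exactly through
    :func:`read_feature_table` (floats are printed with ``repr`` precision)."""
    df = table.to_frame(label_column=label_column, id_column=id_column)
    try:
        # %.17g always round-trips an IEEE double through text
        df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")
    except OSError as exc:
        raise HdnnIOError(f"cannot write {path}: {exc}") from exc
    return path


class HdnnIOError(FormatError):
    """Unwritable or unreadable path."""


def stratified_split(
    table: FeatureTable,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable]:
    """Split into train/test preserving class proportions.

    At imbalance ratios of 1:5000 an unstratified split can easily leave the
    test set with zero positives, so stratification is mandatory here.
    Deterministic for a fixed seed; every sample lands in exactly one side.
    """
    if not 0.0 < test_fraction < 1.0:
        raise DomainError("test_fraction must lie in (0, 1)")
    if table.n_positive == 0 or table.n_negative == 0:
        raise StratificationError(
            "stratified split requires at least one sample of each class"
        )
    idx = np.arange(table.n_samples)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        random_state=seed,
        stratify=table.labels,
        shuffle=True,
    )
    return table.take(np.sort(train_idx)), table.take(np.sort(test_idx))
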