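"""Tabular two-class datasets: I/O, cleanliness rules, imbalance descriptors, CV splits.

The container is deliberately minimal: a dense float feature matrix, a 0/1
label vector (1 = positive = minority/case class by convention), and the
column names.  Rows with missing attribute values are dropped at read time
and the drop count is recorded — downstream stages may assume a complete
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TabularDataset",
    "FoldAssignment",
    "DatasetError",
    "read_csv",
    "write_csv",
    "imbalance_ratio",
    "stratified_kfold",
    "scale_minmax",
    "MISSING_SENTINELS",
]

#: Tokens treated as missing values in CSV cells (UCI files use "?").
MISSING_SENTINELS = ("", "NA", "?", "NaN")


class DatasetError(ValueError):
    """Raised on contract violations of dataset I/O and splitting."""


@dataclass
class TabularDataset:
    """A two-class tabular dataset.

    Parameters
    ----------
    features : (n, d) float array of attribute values, no missing entries.
    labels : (n,) int array in {0, 1}; 1 is the positive (minority/case)
        class, 0 the negative (majority/control) class.
    feature_names : d column names.
    label_column : name of the label column for round-tripping.
    positive_label, negative_label : the original label values, kept so a
        written CSV reads back with the same class encoding.
    n_dropped : rows discarded at read time because of missing values.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    label_column: str = "class"
    positive_label: object = 1
    negative_label: object = 0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise DatasetError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise DatasetError(
                f"{self.features.shape[0]} feature rows vs {self.labels.shape[0]} labels"
            )
        if not np.isfinite(self.features).all():
            raise DatasetError("features contain non-finite values")
        distinct = set(np.unique(self.labels))
        if not distinct <= {0, 1}:
            raise DatasetError(f"labels must be 0/1, got {sorted(distinct)}")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.features.shape[1])]
        if len(self.feature_names) != self.features.shape[1]:
            raise DatasetError("feature_names length does not match feature columns")

    # -- descriptors ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_positive(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == 0).sum())

    @property
    def is_degenerate(self) -> bool:
        """True when only one class is present."""
        return self.n_positive == 0 or self.n_negative == 0

    # -- manipulation --------------------------------------------------
    def take(self, indices: Sequence[int]) -> "TabularDataset":
        """Row subset preserving metadata (drop count not inherited)."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            features=self.features[idx],
            labels=self.labels[idx],
            n_dropped=0,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        raw = np.where(self.labels == 1, self.positive_label, self.negative_label)
        df[self.label_column] = raw
        return df


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified k-fold assignment: per-row fold index in [0, k_folds)."""

    fold_index: np.ndarray
    k_folds: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def read_csv(
    path: str | Path,
    label_column: str,
    positive_label: object | None = None,
) -> TabularDataset:
    """Read a two-class CSV, dropping rows with missing attribute values.

    Empty cells, ``NA``, ``?`` and ``NaN`` all count as missing.  If
    ``positive_label`` is omitted, the minority class is taken as positive.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    df = pd.read_csv(path, na_values=["?"], skipinitialspace=True)
    if label_column not in df.columns:
        raise DatasetError(f"label column {label_column!r} not in header {list(df.columns)}")
    n_before = len(df)
    df = df.dropna(axis=0, how="any")
    n_dropped = n_before - len(df)
    if len(df) == 0:
        raise DatasetError("zero rows remain after missing-value filtering")

    raw_labels = df[label_column]
    values = sorted(raw_labels.unique(), key=str)
    if len(values) > 2:
        raise DatasetError(f"more than two classes in {label_column!r}: {values}")

    feats = df.drop(columns=[label_column])
    try:
        X = feats.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DatasetError(f"non-numeric feature column: {exc}") from exc

    if positive_label is None:
        # minority class is positive by default
        counts = raw_labels.value_counts()
        positive_label = counts.index[-1] if len(counts) > 1 else values[0]
    else:
        matches = [v for v in values if str(v) == str(positive_label) or v == positive_label]
        if not matches:
            raise DatasetError(f"positive label {positive_label!r} not among {values}")
        positive_label = matches[0]
    negatives = [v for v in values if v != positive_label]
    negative_label = negatives[0] if negatives else 0

    y = (raw_labels == positive_label).astype(int).to_numpy()
    return TabularDataset(
        features=X,
        labels=y,
        feature_names=list(feats.columns),
        label_column=label_column,
        positive_label=positive_label,
        negative_label=negative_label,
        n_dropped=n_dropped,
    )


def write_csv(ds: TabularDataset, path: str | Path) -> None:
    """Write a dataset to CSV with full float precision (round-trip safe)."""
    if ds.n_features == 0:
        raise DatasetError("refusing to write a dataset with zero feature columns")
    ds.to_frame().to_csv(path, index=False, float_format="%.17g")


def imbalance_ratio(ds: TabularDataset) -> float:
    """Majority count divided by minority count; always >= 1."""
    n_pos, n_neg = ds.n_positive, ds.n_negative
    if n_pos == 0 or n_neg == 0:
        raise DatasetError("imbalance ratio undefined: one class absent")
    return max(n_pos, n_neg) / min(n_pos, n_neg)


def stratified_kfold(ds: TabularDataset, k_folds: int, seed: int) -> FoldAssignment:
    """Deterministic stratified k-fold assignment.

    Within each class the rows are shuffled (seeded) and dealt round-robin,
    so per-fold class counts differ by at most one across folds.
    """
    if k_folds < 2:
        raise DatasetError("k_folds must be >= 2")
    for cls, cnt in ((1, ds.n_positive), (0, ds.n_negative)):
        if 0 < cnt < k_folds:
            raise DatasetError(
                f"class {cls} has {cnt} members, fewer than k_folds={k_folds}"
            )
    rng = np.random.default_rng(seed)
    fold = np.empty(ds.n, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(ds.labels == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % k_folds
    return FoldAssignment(fold_index=fold, k_folds=k_folds, seed=seed)


def scale_minmax(ds: TabularDataset) -> TabularDataset:
    """Optional per-feature min-max scaling to [0, 1].

    Off by default throughout the package: the selection procedure is run on
    raw features unless the caller opts in (K-means is scale-sensitive, so
    this switch can matter for heterogeneous attribute units).  Constant
    columns map to 0.
    """
    X = ds.features
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0
    return replace(ds, features=(X - lo) / span)
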