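"""Baseline rebalancing methods: random undersampling and SMOTE.

RUS keeps every minority row and uniformly subsamples the majority class
down to the minority count.  SMOTE creates synthetic minority points by
interpolating between a minority point and one of its k nearest minority
neighbours, and pairs an ``over`` percentage (synthetic points per 100
original minority points) with an ``under`` percentage (majority rows kept
per 100 synthetic points) — the convention of the classic R implementation,
so over=100/under=300 turns (10 minority, 60 majority) into
(20 minority, 30 majority).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .datasets import TabularDataset

__all__ = ["SmoteParams", "random_undersample", "smote", "rus_indices", "smote_arrays"]


@dataclass(frozen=True)
class SmoteParams:
    """SMOTE configuration: over_pct synthetic %, under_pct majority-retention %."""

    over_pct: int = 100
    under_pct: int = 300
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.over_pct < 100 or self.over_pct % 100 != 0:
            raise ValueError("over_pct must be a multiple of 100 and >= 100")
        if self.under_pct < 0:
            raise ValueError("under_pct must be >= 0")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def rus_indices(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row indices of a random undersample: all minority + an equal-size
    uniform majority subset (without replacement).  Sorted for determinism."""
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    minority, majority = (pos, neg) if pos.size <= neg.size else (neg, pos)
    if minority.size == 0:
        raise ValueError("minority class is empty")
    keep = rng.choice(majority, size=minority.size, replace=False)
    return np.sort(np.concatenate([minority, keep]))


def random_undersample(ds: TabularDataset, seed: int = 0) -> TabularDataset:
    """Balance by uniformly discarding majority rows; minority kept intact."""
    rng = np.random.default_rng(seed)
    return ds.take(rus_indices(ds.labels, rng))


def _minority_neighbors(X_min: np.ndarray, k: int) -> np.ndarray:
    """Index matrix of each minority point's k nearest minority neighbours
    (self excluded; Euclidean; ties broken by row index via stable sort)."""
    dist = cdist(X_min, X_min)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")
    return order[:, :k]


def smote_arrays(
    X: np.ndarray,
    y: np.ndarray,
    params: SmoteParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SMOTE on raw arrays; returns (X_out, y_out, origin).

    ``origin`` maps each output row to its source row in the input, with the
    minority *base* row for synthetic points (used by boosting wrappers to
    carry sample weights across the resample).
    """
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    min_idx, maj_idx = (pos, neg) if pos.size <= neg.size else (neg, pos)
    n_min = min_idx.size
    if n_min <= params.k_neighbors:
        raise ValueError(
            f"minority count {n_min} must exceed k_neighbors={params.k_neighbors}"
        )
    X_min = X[min_idx]
    nn = _minority_neighbors(X_min, params.k_neighbors)

    copies = params.over_pct // 100
    synth = np.empty((n_min * copies, X.shape[1]))
    synth_origin = np.empty(n_min * copies, dtype=int)
    row = 0
    for i in range(n_min):
        for _ in range(copies):
            j = nn[i, rng.integers(params.k_neighbors)]
            u = rng.uniform()
            synth[row] = X_min[i] + u * (X_min[j] - X_min[i])
            synth_origin[row] = min_idx[i]
            row += 1

    n_keep = min(maj_idx.size, int(round(params.under_pct / 100 * synth.shape[0])))
    kept_maj = np.sort(rng.choice(maj_idx, size=n_keep, replace=False))

    keep_real = np.sort(np.concatenate([min_idx, kept_maj]))
    X_out = np.vstack([X[keep_real], synth])
    y_min = y[min_idx[0]]
    y_out = np.concatenate([y[keep_real], np.full(synth.shape[0], y_min, dtype=int)])
    origin = np.concatenate([keep_real, synth_origin])
    return X_out, y_out, origin


def smote(ds: TabularDataset, params: SmoteParams | None = None) -> TabularDataset:
    """SMOTE a dataset with the over/under percentage convention."""
    params = params or SmoteParams()
    rng = np.random.default_rng(params.seed)
    X_out, y_out, _ = smote_arrays(ds.features, ds.labels, params, rng)
    return TabularDataset(
        features=X_out,
        labels=y_out,
        feature_names=list(ds.feature_names),
        label_column=ds.label_column,
        positive_label=ds.positive_label,
        negative_label=ds.negative_label,
    )
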