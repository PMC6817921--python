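"""Boundary-instance selection by K-means distance thresholding.

The core idea: cluster the data, measure every point's Euclidean distance to
its cluster centroid, and keep the points whose distance exceeds eta times
the cluster's average distance.  Points far from their centroid lie near the
cluster border, which for two-class data tends to coincide with the
inter-class decision boundary — these are the informative instances worth
training on.  Selection is followed by a balancing step so the retained
subset has equal class counts; the remainder serves as a held-out test set.

Two threshold directions exist in the field's descriptions of this
procedure: keep the *far* points (boundary; the stated motivation) or keep
the *near* points (interior).  Both are implemented; ``rule="boundary"`` is
the default.  Labels are never consulted during selection itself — only the
balancing step counts them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import TabularDataset
from .kmeans import ClusterModel, average_distance, fit_kmeans

__all__ = [
    "SelectionParams",
    "SelectionResult",
    "DegenerateSelectionError",
    "select_informative",
    "rebalance",
    "split_train_test",
]


class DegenerateSelectionError(ValueError):
    """Selection left a class empty (threshold too aggressive for the data)."""


@dataclass(frozen=True)
class SelectionParams:
    """Knobs of the distance-threshold selector.

    eta : multiplier on the average centroid distance forming the threshold
        (typical useful range 0.25-1.6; eta=0 under the boundary rule keeps
        everything).
    n_clusters : number of K-means clusters (2 for two-class problems).
    rule : "boundary" keeps points with distance >= eta * d_avg;
        "interior" keeps points with distance < eta * d_avg.
    scope : "per_cluster" thresholds against each cluster's own mean
        distance; "global" against the single overall mean.
    cluster_on : "all_data" clusters the pooled sample; "per_class" clusters
        each class separately.
    balance : "trim" (one eta/2 relaxation of the deficient class, then trim
        the larger class to exact equality), "relax_eta" (up to two eta/2
        relaxations, then cap), or "none".
    """

    eta: float = 1.0
    n_clusters: int = 2
    rule: str = "boundary"
    scope: str = "per_cluster"
    cluster_on: str = "all_data"
    balance: str = "trim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.rule not in ("boundary", "interior"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.scope not in ("per_cluster", "global"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.cluster_on not in ("all_data", "per_class"):
            raise ValueError(f"unknown cluster_on {self.cluster_on!r}")
        if self.balance not in ("trim", "relax_eta", "none"):
            raise ValueError(f"unknown balance {self.balance!r}")


@dataclass
class SelectionResult:
    """Outcome of informative-instance selection.

    ``selected_idx`` is the balanced training subset; ``rejected_idx`` the
    remainder (used as the test set in the holdout protocol).  The distance
    machinery (per-point distances, cluster assignment, per-point threshold
    base) is carried along so re-balancing never needs to re-cluster.
    """

    selected_idx: np.ndarray
    rejected_idx: np.ndarray
    eta_effective: float
    per_class_selected: dict[int, int]
    balanced: bool
    distances: np.ndarray = field(repr=False, default=None)
    cluster_assignment: np.ndarray = field(repr=False, default=None)
    threshold_base: np.ndarray = field(repr=False, default=None)
    params: SelectionParams | None = field(repr=False, default=None)

    def report(self) -> dict:
        """JSON-friendly summary (counts, eta actually applied, cluster sizes)."""
        k = int(self.cluster_assignment.max()) + 1 if self.cluster_assignment is not None else 0
        return {
            "n_selected": int(self.selected_idx.size),
            "n_rejected": int(self.rejected_idx.size),
            "eta_effective": float(self.eta_effective),
            "per_class_selected": {str(c): int(v) for c, v in self.per_class_selected.items()},
            "balanced": bool(self.balanced),
            "per_cluster_selected": [
                int(np.sum(self.cluster_assignment[self.selected_idx] == c))
                for c in range(k)
            ],
        }


def _cluster(ds: TabularDataset, params: SelectionParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cluster per params; return (distances, cluster ids, per-point threshold base)."""
    n = ds.n
    if params.cluster_on == "all_data":
        model = fit_kmeans(ds.features, params.n_clusters, seed=params.seed)
        d = model.point_distance
        clusters = model.assignment.copy()
        models = [(model, np.arange(n))]
    else:
        d = np.empty(n)
        clusters = np.empty(n, dtype=int)
        models = []
        for offset, cls in enumerate((0, 1)):
            idx = np.flatnonzero(ds.labels == cls)
            k = min(params.n_clusters, idx.size)
            m = fit_kmeans(ds.features[idx], k, seed=params.seed)
            d[idx] = m.point_distance
            clusters[idx] = m.assignment + offset * params.n_clusters
            models.append((m, idx))

    if params.scope == "global":
        base = np.full(n, d.mean())
    else:
        n_ids = int(clusters.max()) + 1
        base = np.empty(n)
        for c in range(n_ids):
            members = clusters == c
            if members.any():
                base[members] = d[members].mean()
    return d, clusters, base


def _candidate_mask(d: np.ndarray, base: np.ndarray, eta: float, rule: str) -> np.ndarray:
    thr = eta * base
    return d >= thr if rule == "boundary" else d < thr


def _keep_most_informative(
    cand_idx: np.ndarray, d: np.ndarray, m: int, rule: str
) -> np.ndarray:
    """Keep the m most informative candidates (largest distance under the
    boundary rule, smallest under interior); deterministic tie-break by index."""
    key = -d[cand_idx] if rule == "boundary" else d[cand_idx]
    order = np.lexsort((cand_idx, key))
    return np.sort(cand_idx[order[:m]])


def select_informative(ds: TabularDataset, params: SelectionParams) -> SelectionResult:
    """Select boundary (or interior) instances and balance the class counts."""
    if ds.is_degenerate:
        raise DegenerateSelectionError("both classes must be present for selection")
    d, clusters, base = _cluster(ds, params)
    raw = SelectionResult(
        selected_idx=np.arange(ds.n),
        rejected_idx=np.array([], dtype=int),
        eta_effective=params.eta,
        per_class_selected={},
        balanced=False,
        distances=d,
        cluster_assignment=clusters,
        threshold_base=base,
        params=params,
    )
    return rebalance(raw, ds, params)


def rebalance(
    selection: SelectionResult, ds: TabularDataset, params: SelectionParams
) -> SelectionResult:
    """Apply the threshold and the configured balancing to a selection.

    With ``balance="relax_eta"`` a deficient class is re-thresholded with
    eta halved (at most twice); with ``balance="trim"`` one relaxation pass
    is followed by trimming the larger class, dropping its least informative
    points first.  Either way the final class counts are exactly equal.
    """
    d = selection.distances
    base = selection.threshold_base
    if d is None or base is None:
        d, clusters, base = _cluster(ds, params)
        selection = replace(
            selection, distances=d, cluster_assignment=clusters, threshold_base=base
        )
    eta = params.eta
    mask = _candidate_mask(d, base, eta, params.rule)
    pos_rows = np.flatnonzero(ds.labels == 1)
    neg_rows = np.flatnonzero(ds.labels == 0)
    cand = {1: pos_rows[mask[pos_rows]], 0: neg_rows[mask[neg_rows]]}
    eta_eff = eta

    if params.balance == "none":
        sel = np.sort(np.concatenate([cand[0], cand[1]]))
        if sel.size == 0:
            raise DegenerateSelectionError(f"no instance passes the threshold at eta={eta}")
        return _finish(selection, ds, sel, eta_eff)

    rows = {1: pos_rows, 0: neg_rows}
    for _ in range(2):
        n_pos, n_neg = cand[1].size, cand[0].size
        if params.balance == "trim":
            # trim alone balances exactly; relax the threshold only when a
            # class has no candidate at all (otherwise an eta/2 pass would
            # pull nearly the whole deficient class out of the test remainder)
            if min(n_pos, n_neg) > 0:
                break
        elif n_pos == n_neg:
            break
        deficient = 1 if n_pos < n_neg else 0
        eta_eff = eta_eff / 2.0
        sub = rows[deficient]
        sub_mask = _candidate_mask(d[sub], base[sub], eta_eff, params.rule)
        cand[deficient] = sub[sub_mask]

    m = min(cand[1].size, cand[0].size)
    if m == 0:
        raise DegenerateSelectionError(
            f"a class has no candidates even after relaxing eta={params.eta} "
            f"to {eta_eff} (rule={params.rule})"
        )
    sel = np.sort(
        np.concatenate(
            [
                _keep_most_informative(cand[1], d, m, params.rule),
                _keep_most_informative(cand[0], d, m, params.rule),
            ]
        )
    )
    return _finish(selection, ds, sel, eta_eff)


def _finish(
    selection: SelectionResult, ds: TabularDataset, sel: np.ndarray, eta_eff: float
) -> SelectionResult:
    all_idx = np.arange(ds.n)
    rejected = np.setdiff1d(all_idx, sel, assume_unique=False)
    n_pos = int(np.sum(ds.labels[sel] == 1))
    n_neg = int(np.sum(ds.labels[sel] == 0))
    return replace(
        selection,
        selected_idx=sel,
        rejected_idx=rejected,
        eta_effective=eta_eff,
        per_class_selected={1: n_pos, 0: n_neg},
        balanced=(n_pos == n_neg and n_pos > 0),
    )


def split_train_test(
    ds: TabularDataset, selection: SelectionResult
) -> tuple[TabularDataset, TabularDataset]:
    """Materialize (selected -> train, rejected -> test) datasets."""
    if selection.rejected_idx.size == 0:
        raise DegenerateSelectionError("selection rejected nothing: empty test set")
    return ds.take(selection.selected_idx), ds.take(selection.rejected_idx)
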