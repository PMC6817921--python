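"""Imbalance-aware evaluation: confusion-matrix metrics and rank tests.

The metric suite is the one the class-imbalance community leans on when
plain accuracy is misleading: sensitivity (minority recall), specificity,
their geometric mean (G-mean), ROC AUC, and the Matthews correlation
coefficient

    MCC = (TN*TP - FN*FP) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

which stays informative at any class ratio.  A zero marginal makes the MCC
denominator vanish; the conventional value 0 is returned then.

For comparing several methods across several datasets the module provides
the Friedman rank test (chi-square approximation with tie correction, plus
the Iman-Davenport F variant) and the Nemenyi critical difference for the
post-hoc pairwise comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, f as f_dist, rankdata

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "RankTestResult",
    "confusion",
    "mcc",
    "g_mean",
    "auc_from_scores",
    "metric_report",
    "friedman_mean_ranks",
    "friedman_test",
    "nemenyi_cd",
    "pairwise_nemenyi",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Two-class confusion counts, positive = minority/case class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


@dataclass
class MetricReport:
    """The six evaluation measures; ``flags`` records any fallback used
    (e.g. AUC computed as balanced accuracy when no scores exist) and any
    undefined entries (a class absent from the evaluation set)."""

    accuracy: float
    sensitivity: float
    specificity: float
    g_mean: float
    auc: float
    mcc: float
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "g_mean": self.g_mean,
            "auc": self.auc,
            "mcc": self.mcc,
        }


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    """Count TP/FN/FP/TN for 0/1 labels (1 = positive)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 by convention on a zero marginal."""
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tn * tp - fn * fp) / math.sqrt(denom)


def g_mean(sensitivity: float, specificity: float) -> float:
    """Geometric mean of sensitivity and specificity."""
    if sensitivity < 0 or specificity < 0:
        raise ValueError("rates must be non-negative")
    return math.sqrt(sensitivity * specificity)


def auc_from_scores(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC area from continuous scores via the rank (Mann-Whitney) form,
    which equals the trapezoidal ROC area with tied scores rank-averaged."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: a class is absent")
    ranks = rankdata(scores)  # average ranks on ties
    return (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def metric_report(
    cm: ConfusionMatrix,
    scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
) -> MetricReport:
    """Full six-metric report from a confusion matrix (+ scores for AUC).

    When a class is absent its rate is NaN and the report is flagged rather
    than silently zeroed.  Without scores, AUC falls back to
    (sensitivity + specificity)/2 and is flagged accordingly.
    """
    flags: list[str] = []
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    acc = (cm.tp + cm.tn) / n
    if cm.n_positive == 0:
        sens = float("nan")
        flags.append("sensitivity undefined: no positives evaluated")
    else:
        sens = cm.tp / cm.n_positive
    if cm.n_negative == 0:
        spec = float("nan")
        flags.append("specificity undefined: no negatives evaluated")
    else:
        spec = cm.tn / cm.n_negative
    gm = g_mean(sens, spec) if not (math.isnan(sens) or math.isnan(spec)) else float("nan")
    if scores is not None:
        if y_true is None:
            raise ValueError("y_true required alongside scores for AUC")
        if len(y_true) != n:
            raise ValueError("y_true length does not match the confusion matrix total")
        auc = auc_from_scores(y_true, scores)
    else:
        auc = (sens + spec) / 2.0
        flags.append("auc: balanced-accuracy fallback (no scores supplied)")
    return MetricReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        g_mean=gm,
        auc=auc,
        mcc=mcc(cm),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# rank machinery
# ---------------------------------------------------------------------------

@dataclass
class RankTestResult:
    """Friedman/Nemenyi summary over a methods x datasets metric table."""

    mean_ranks: np.ndarray
    friedman_statistic: float
    p_value: float
    nemenyi_cd: float
    alpha: float
    method_names: list[str] | None = None

    def significant_pairs(self) -> np.ndarray:
        """Boolean matrix: |mean rank difference| exceeds the critical difference."""
        diff = np.abs(self.mean_ranks[:, None] - self.mean_ranks[None, :])
        out = diff > self.nemenyi_cd
        np.fill_diagonal(out, False)
        return out


def _rank_table(metric_table: np.ndarray, higher_is_better: bool = True) -> np.ndarray:
    """Per-dataset ranks of each method, k = best; ties get average ranks.

    ``metric_table`` is methods x datasets.  Ranking ascending on the metric
    gives the best method the highest rank k, matching the convention where
    a mean rank of k means "best on every dataset".
    """
    table = np.asarray(metric_table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 1:
        raise ValueError("need a 2-D table with >= 2 methods")
    if np.isnan(table).any():
        raise ValueError("metric table has missing cells")
    vals = table if higher_is_better else -table
    return np.apply_along_axis(rankdata, 0, vals)


def friedman_mean_ranks(
    metric_table: np.ndarray,
    higher_is_better: bool = True,
    polarity: str = "high",
) -> np.ndarray:
    """Mean rank of each method across datasets.

    polarity="high": best method has the highest mean rank (k of k).
    polarity="demsar": the literature's convention, best = rank 1.
    """
    ranks = _rank_table(metric_table, higher_is_better).mean(axis=1)
    if polarity == "demsar":
        k = metric_table.shape[0]
        return k + 1 - ranks
    if polarity != "high":
        raise ValueError(f"unknown polarity {polarity!r}")
    return ranks


def friedman_test(
    metric_table: np.ndarray,
    higher_is_better: bool = True,
    variant: str = "chi2",
) -> tuple[float, float]:
    """Friedman test across the table's datasets (blocks).

    variant="chi2": tie-corrected chi-square approximation with k-1 df.
    variant="iman_davenport": the F-distributed refinement.
    Returns (statistic, p_value).
    """
    ranks = _rank_table(metric_table, higher_is_better)
    k, n = ranks.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 methods and >= 2 datasets")
    rank_sums = ranks.sum(axis=1)
    stat = 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n * (k + 1)
    # tie correction (identical to the classical adjustment)
    ties = 0.0
    for j in range(n):
        _, counts = np.unique(ranks[:, j], return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * (k**3 - k))
    if correction <= 0:
        return 0.0, 1.0  # every method tied on every dataset
    stat /= correction
    if variant == "chi2":
        return stat, float(chi2.sf(stat, k - 1))
    if variant == "iman_davenport":
        if stat >= n * (k - 1):
            return float("inf"), 0.0
        ff = (n - 1) * stat / (n * (k - 1) - stat)
        return ff, float(f_dist.sf(ff, k - 1, (k - 1) * (n - 1)))
    raise ValueError(f"unknown variant {variant!r}")


#: studentized-range-based q values for the Nemenyi test, k = 2..10
_Q_TABLE = {
    0.05: [1.960, 2.343, 2.569, 2.728, 2.850, 2.949, 3.031, 3.102, 3.164],
    0.10: [1.645, 2.052, 2.291, 2.459, 2.589, 2.693, 2.780, 2.855, 2.920],
}


def nemenyi_cd(k: int, n: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference: CD = q_alpha(k) * sqrt(k(k+1)/(6n))."""
    if k < 2 or n < 1:
        raise ValueError("need k >= 2 methods and n >= 1 datasets")
    if alpha not in _Q_TABLE:
        raise ValueError(f"alpha {alpha} not tabulated (use 0.05 or 0.10)")
    q = _Q_TABLE[alpha]
    if k - 2 >= len(q):
        raise ValueError(f"q value untabulated for k={k}")
    return q[k - 2] * math.sqrt(k * (k + 1) / (6.0 * n))


def pairwise_nemenyi(
    metric_table: np.ndarray,
    alpha: float = 0.05,
    higher_is_better: bool = True,
    method_names: list[str] | None = None,
) -> RankTestResult:
    """Friedman test + mean ranks + Nemenyi CD, bundled for reporting."""
    table = np.asarray(metric_table, dtype=float)
    stat, p = friedman_test(table, higher_is_better)
    return RankTestResult(
        mean_ranks=friedman_mean_ranks(table, higher_is_better),
        friedman_statistic=stat,
        p_value=p,
        nemenyi_cd=nemenyi_cd(table.shape[0], table.shape[1], alpha),
        alpha=alpha,
        method_names=method_names,
    )
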