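"""Boosted decision-tree ensembles for imbalanced two-class data.

``fit_adaboost`` is AdaBoost.M1 over the gain-ratio tree: instance weights
start uniform, each trial fits a weighted tree, a trial with weighted error
>= 1/2 stops training, a perfect trial is kept with a capped vote weight,
and otherwise alpha_t = 0.5 * ln((1 - eps_t)/eps_t) with the usual
exponential reweighting.  ``fit_rusboost`` / ``fit_smoteboost`` run the same
loop but hand each weak learner a resampled (random-undersampled / SMOTEd)
view of the weighted training set, while the error and the reweighting are
always computed on the original instances.

``fit_k_boosted`` is the end-to-end hybrid: boundary-instance selection by
K-means distance thresholding produces a balanced training subset, and the
boosted tree ensemble is fitted on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import TabularDataset
from .resample import SmoteParams, rus_indices, smote_arrays
from .tree import DecisionTree, fit_tree
from .undersample import SelectionParams, SelectionResult, select_informative

__all__ = [
    "TreeParams",
    "BoostedEnsemble",
    "KBoostParams",
    "KBoostedModel",
    "fit_adaboost",
    "fit_rusboost",
    "fit_smoteboost",
    "fit_k_boosted",
    "predict",
    "predict_score",
]

#: vote weight assigned to a perfect (zero-weighted-error) weak learner
_ALPHA_CAP = 0.5 * np.log((1.0 - 1e-10) / 1e-10)


@dataclass(frozen=True)
class TreeParams:
    """Weak-learner settings passed through to the gain-ratio tree."""

    min_leaf: int = 2
    pruning_cf: float = 0.25
    max_depth: int | None = None


@dataclass
class BoostedEnsemble:
    """Weighted-vote ensemble of gain-ratio trees.

    ``trees`` and ``alphas`` run in trial order and may be shorter than
    ``trials`` when boosting stopped early.  ``fallback_label`` is the
    training-majority class, used only if no weak learner was accepted.
    ``trial_class_counts`` records the (neg, pos) counts of the set each
    weak learner was actually fitted on (resampling transparency).
    """

    trees: list[DecisionTree]
    alphas: list[float]
    trials: int
    seed: int
    fallback_label: int = 0
    trial_class_counts: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trees)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "trees": [t.to_dict() for t in self.trees],
            "alphas": list(map(float, self.alphas)),
            "trials": self.trials,
            "seed": self.seed,
            "fallback_label": self.fallback_label,
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(text_or_path: str | Path) -> "BoostedEnsemble":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text_or_path).read_text()
        doc = json.loads(text)
        return BoostedEnsemble(
            trees=[DecisionTree.from_dict(t) for t in doc["trees"]],
            alphas=doc["alphas"],
            trials=doc["trials"],
            seed=doc["seed"],
            fallback_label=doc.get("fallback_label", 0),
        )


def predict_score(model: "BoostedEnsemble | KBoostedModel", X: np.ndarray) -> np.ndarray:
    """Positive-class score in [0, 1]: the alpha-weighted share of trees
    voting positive.  An empty ensemble scores a flat 0.5."""
    if isinstance(model, KBoostedModel):
        model = model.ensemble
    X = np.asarray(X, dtype=float)
    if not model.trees:
        return np.full(X.shape[0], 0.5)
    total = float(np.sum(model.alphas))
    if total <= 0:
        return np.full(X.shape[0], 0.5)
    votes = np.zeros(X.shape[0])
    for tree, alpha in zip(model.trees, model.alphas):
        votes += alpha * tree.predict(X)
    return votes / total


def predict(model: "BoostedEnsemble | KBoostedModel", X: np.ndarray) -> np.ndarray:
    """Hard labels: threshold the vote share at 0.5, ties to negative."""
    ens = model.ensemble if isinstance(model, KBoostedModel) else model
    if not ens.trees:
        return np.full(np.asarray(X).shape[0], ens.fallback_label, dtype=int)
    return (predict_score(ens, X) > 0.5).astype(int)


def _boost(
    X: np.ndarray,
    y: np.ndarray,
    trials: int,
    tree_params: TreeParams,
    seed: int,
    resampler,
) -> BoostedEnsemble:
    """Shared AdaBoost.M1 loop; ``resampler(X, y, w, rng)`` returns the
    (X', y', w') triple the weak learner is fitted on (identity for plain
    AdaBoost).  Error and reweighting use the original (X, y, w)."""
    n = y.shape[0]
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if len(np.unique(y)) < 2:
        raise ValueError("boosting needs both classes present")
    rng = np.random.default_rng(seed)
    w = np.full(n, 1.0 / n)
    ens = BoostedEnsemble(
        trees=[],
        alphas=[],
        trials=trials,
        seed=seed,
        fallback_label=int(np.sum(y == 1) > np.sum(y == 0)),
    )
    for _ in range(trials):
        X_fit, y_fit, w_fit = resampler(X, y, w, rng)
        tree = fit_tree(
            X_fit,
            y_fit,
            sample_weight=w_fit,
            min_leaf=tree_params.min_leaf,
            pruning_cf=tree_params.pruning_cf,
            max_depth=tree_params.max_depth,
        )
        ens.trial_class_counts.append(
            (int(np.sum(y_fit == 0)), int(np.sum(y_fit == 1)))
        )
        pred = tree.predict(X)
        miss = pred != y
        eps = float(w[miss].sum())
        if eps >= 0.5:
            break  # weak-learner failure: discard trial, stop
        if eps <= 0.0:
            ens.trees.append(tree)
            ens.alphas.append(float(_ALPHA_CAP))
            break
        alpha = 0.5 * np.log((1.0 - eps) / eps)
        ens.trees.append(tree)
        ens.alphas.append(float(alpha))
        w = w * np.exp(np.where(miss, alpha, -alpha))
        w = w / w.sum()
    return ens


def _identity_resampler(X, y, w, rng):
    return X, y, w


def fit_adaboost(
    X: np.ndarray,
    y: np.ndarray,
    trials: int = 10,
    tree_params: TreeParams | None = None,
    seed: int = 0,
) -> BoostedEnsemble:
    """AdaBoost.M1 over gain-ratio trees."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    return _boost(X, y, trials, tree_params or TreeParams(), seed, _identity_resampler)


def fit_rusboost(
    X: np.ndarray,
    y: np.ndarray,
    trials: int = 10,
    tree_params: TreeParams | None = None,
    seed: int = 0,
) -> BoostedEnsemble:
    """RUSBoost: each trial's tree sees a freshly balanced random
    undersample, carrying the current boosting weights (renormalized)."""

    def resampler(X, y, w, rng):
        idx = rus_indices(y, rng)
        w_sub = w[idx]
        return X[idx], y[idx], w_sub / w_sub.sum()

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    return _boost(X, y, trials, tree_params or TreeParams(), seed, resampler)


def fit_smoteboost(
    X: np.ndarray,
    y: np.ndarray,
    trials: int = 10,
    smote_params: SmoteParams | None = None,
    tree_params: TreeParams | None = None,
    seed: int = 0,
) -> BoostedEnsemble:
    """SMOTEBoost: each trial SMOTEs the training set before fitting the
    tree; synthetic points inherit their base point's boosting weight."""
    sp = smote_params or SmoteParams()

    def resampler(X, y, w, rng):
        X_s, y_s, origin = smote_arrays(X, y, sp, rng)
        w_s = w[origin]
        return X_s, y_s, w_s / w_s.sum()

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    return _boost(X, y, trials, tree_params or TreeParams(), seed, resampler)


@dataclass(frozen=True)
class KBoostParams:
    """End-to-end hybrid configuration: selection + boosting settings."""

    selection: SelectionParams = field(default_factory=SelectionParams)
    trials: int = 10
    tree: TreeParams = field(default_factory=TreeParams)
    seed: int = 0


@dataclass
class KBoostedModel:
    """Fitted hybrid pipeline: the selection that built the balanced subset
    and the ensemble trained on it (selection kept for protocol audit)."""

    selection: SelectionResult
    ensemble: BoostedEnsemble
    params: KBoostParams

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self.ensemble, X)

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return predict_score(self.ensemble, X)


def fit_k_boosted(ds: TabularDataset, params: KBoostParams | None = None) -> KBoostedModel:
    """Select boundary instances, balance, and boost trees on the subset."""
    params = params or KBoostParams()
    selection = select_informative(ds, params.selection)
    sub = ds.take(selection.selected_idx)
    ensemble = fit_adaboost(
        sub.features, sub.labels, trials=params.trials,
        tree_params=params.tree, seed=params.seed,
    )
    return KBoostedModel(selection=selection, ensemble=ensemble, params=params)
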