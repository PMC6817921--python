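"""Gain-ratio decision tree with pessimistic error postpruning.

A C4.5-style binary tree for numeric attributes: every internal node tests
``x[feature] <= threshold`` with the threshold at the midpoint between two
consecutive distinct sorted values, chosen to maximize the gain ratio
(information gain divided by split information) computed from *weighted*
class frequencies — so the same learner serves both plain fitting and
boosting distributions.  After growth the tree is pruned bottom-up by
comparing each subtree's pessimistic error estimate (binomial upper
confidence limit at confidence factor ``pruning_cf``) against collapsing it
to a leaf.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta

__all__ = ["DecisionTree", "fit_tree"]

_EPS = 1e-12


@dataclass
class _Node:
    # leaf payload
    prediction: int = 0
    proba: np.ndarray | None = None  # P(class 0), P(class 1) from weighted counts
    n: int = 0                       # unweighted sample count
    n_errors: int = 0                # unweighted training errors at this node's majority label
    # split payload (leaf iff feature is None)
    feature: int | None = None
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {
                "leaf": True,
                "prediction": int(self.prediction),
                "proba": [float(p) for p in self.proba],
                "n": int(self.n),
            }
        return {
            "leaf": False,
            "feature": int(self.feature),
            "threshold": float(self.threshold),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @staticmethod
    def from_dict(doc: dict) -> "_Node":
        if doc["leaf"]:
            return _Node(
                prediction=doc["prediction"], proba=np.asarray(doc["proba"]), n=doc["n"]
            )
        return _Node(
            feature=doc["feature"],
            threshold=doc["threshold"],
            left=_Node.from_dict(doc["left"]),
            right=_Node.from_dict(doc["right"]),
        )


def _entropy(w1: np.ndarray, wt: np.ndarray) -> np.ndarray:
    """Binary entropy (bits) of weighted positive mass w1 out of wt; 0·log 0 = 0."""
    w1 = np.asarray(w1, dtype=float)
    wt = np.asarray(wt, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(wt > 0, w1 / np.maximum(wt, _EPS), 0.0)
        h = -(
            np.where(p > 0, p * np.log2(np.maximum(p, _EPS)), 0.0)
            + np.where(p < 1, (1 - p) * np.log2(np.maximum(1 - p, _EPS)), 0.0)
        )
    return h


def _best_split(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, min_leaf: int
) -> tuple[int, float] | None:
    """Exhaustive gain-ratio maximization over all (feature, midpoint) splits.

    Only splits with strictly positive information gain qualify; ties break
    toward the lowest feature index, then the lowest threshold.
    """
    n, d = X.shape
    total_w = w.sum()
    h_parent = float(_entropy(w[y == 1].sum(), total_w))
    best_gr = _EPS
    best: tuple[int, float] | None = None
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ws = w[order]
        w1s = ws * y[order]
        cw = np.cumsum(ws)
        cw1 = np.cumsum(w1s)
        cut = np.flatnonzero(xs[1:] > xs[:-1]) + 1  # left side = first `cut` rows
        cut = cut[(cut >= min_leaf) & (n - cut >= min_leaf)]
        if cut.size == 0:
            continue
        wl, wl1 = cw[cut - 1], cw1[cut - 1]
        wr, wr1 = total_w - wl, cw1[-1] - wl1
        gain = h_parent - (wl * _entropy(wl1, wl) + wr * _entropy(wr1, wr)) / total_w
        split_info = _entropy(wl, total_w)
        valid = (gain > _EPS) & (split_info > _EPS) & (wl > 0) & (wr > 0)
        if not valid.any():
            continue
        gr = np.where(valid, gain / np.maximum(split_info, _EPS), -np.inf)
        i = int(gr.argmax())  # argmax -> first max -> lowest threshold
        if gr[i] > best_gr:
            best_gr = float(gr[i])
            c = cut[i]
            best = (j, float((xs[c - 1] + xs[c]) / 2.0))
    return best


def _make_leaf(y: np.ndarray, w: np.ndarray) -> _Node:
    w1 = float(w[y == 1].sum())
    w0 = float(w[y == 0].sum())
    total = w0 + w1
    pred = 1 if w1 > w0 else 0  # tie -> negative
    proba = np.array([0.5, 0.5]) if total == 0 else np.array([w0, w1]) / total
    return _Node(
        prediction=pred,
        proba=proba,
        n=int(y.size),
        n_errors=int(np.sum(y != pred)),
    )


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    min_leaf: int,
    depth: int,
    max_depth: int | None,
) -> _Node:
    leaf = _make_leaf(y, w)
    if (
        leaf.n_errors == 0
        or y.size < 2 * min_leaf
        or (max_depth is not None and depth >= max_depth)
    ):
        return leaf
    split = _best_split(X, y, w, min_leaf)
    if split is None:
        return leaf
    j, thr = split
    mask = X[:, j] <= thr
    node = _Node(
        feature=j,
        threshold=thr,
        left=_grow(X[mask], y[mask], w[mask], min_leaf, depth + 1, max_depth),
        right=_grow(X[~mask], y[~mask], w[~mask], min_leaf, depth + 1, max_depth),
    )
    # carry node-level stats for pruning
    node.prediction = leaf.prediction
    node.proba = leaf.proba
    node.n = leaf.n
    node.n_errors = leaf.n_errors
    return node


def _pessimistic_errors(n_errors: int, n: int, cf: float) -> float:
    """Predicted error count: n times the binomial upper confidence limit."""
    if n == 0:
        return 0.0
    if n_errors >= n:
        return float(n)
    if n_errors == 0:
        return n * (1.0 - cf ** (1.0 / n))
    return n * float(beta.ppf(1.0 - cf, n_errors + 1, n - n_errors))


def _prune(node: _Node, cf: float) -> tuple[_Node, float]:
    if node.is_leaf:
        return node, _pessimistic_errors(node.n_errors, node.n, cf)
    node.left, e_left = _prune(node.left, cf)
    node.right, e_right = _prune(node.right, cf)
    subtree_est = e_left + e_right
    leaf_est = _pessimistic_errors(node.n_errors, node.n, cf)
    if leaf_est <= subtree_est:
        collapsed = _Node(
            prediction=node.prediction, proba=node.proba, n=node.n, n_errors=node.n_errors
        )
        return collapsed, leaf_est
    return node, subtree_est


@dataclass
class DecisionTree:
    """Fitted gain-ratio tree.  Routing: x[feature] <= threshold goes left."""

    root: _Node
    min_leaf: int = 2
    pruning_cf: float = 0.25
    n_features: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature columns, got shape {X.shape}"
            )
        out = np.empty((X.shape[0], 2))
        self._route(self.root, X, np.arange(X.shape[0]), out)
        return out

    def _route(self, node: _Node, X: np.ndarray, idx: np.ndarray, out: np.ndarray) -> None:
        if idx.size == 0:
            return
        if node.is_leaf:
            out[idx] = node.proba
            return
        mask = X[idx, node.feature] <= node.threshold
        self._route(node.left, X, idx[mask], out)
        self._route(node.right, X, idx[~mask], out)

    def n_leaves(self) -> int:
        def count(nd: _Node) -> int:
            return 1 if nd.is_leaf else count(nd.left) + count(nd.right)

        return count(self.root)

    def depth(self) -> int:
        def dep(nd: _Node) -> int:
            return 0 if nd.is_leaf else 1 + max(dep(nd.left), dep(nd.right))

        return dep(self.root)

    def to_dict(self) -> dict:
        return {
            "root": self.root.to_dict(),
            "min_leaf": self.min_leaf,
            "pruning_cf": self.pruning_cf,
            "n_features": self.n_features,
        }

    @staticmethod
    def from_dict(doc: dict) -> "DecisionTree":
        return DecisionTree(
            root=_Node.from_dict(doc["root"]),
            min_leaf=doc["min_leaf"],
            pruning_cf=doc["pruning_cf"],
            n_features=doc["n_features"],
        )


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    min_leaf: int = 2,
    pruning_cf: float = 0.25,
    max_depth: int | None = None,
) -> DecisionTree:
    """Fit a gain-ratio tree on 0/1 labels with optional sample weights.

    ``min_leaf`` bounds the *unweighted* sample count on each side of a
    split; ``pruning_cf`` is the confidence factor of the pessimistic
    postpruning (smaller prunes harder; 0.25 is the customary default).
    A single-class input yields a single leaf.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    if X.shape[0] == 0:
        raise ValueError("need at least one sample")
    if sample_weight is None:
        w = np.full(y.shape[0], 1.0 / y.shape[0])
    else:
        w = np.asarray(sample_weight, dtype=float)
        if w.shape != y.shape or (w < 0).any() or w.sum() <= 0:
            raise ValueError("sample_weight must be non-negative with positive sum")
    if not 0 < pruning_cf < 1:
        raise ValueError("pruning_cf must be in (0, 1)")
    root = _grow(X, y, w, min_leaf, 0, max_depth)
    root, _ = _prune(root, pruning_cf)
    return DecisionTree(
        root=root, min_leaf=min_leaf, pruning_cf=pruning_cf, n_features=X.shape[1]
    )
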