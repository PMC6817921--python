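"""Lloyd-style K-means with a Euclidean (unsquared) inertia and distance stats.

The clustering here is the instrument of the boundary-instance selector: it
must report, for every point, the Euclidean distance to its assigned
centroid, and per-cluster / global averages of those distances.  Iteration is
the classical Lloyd loop — assign each point to its nearest centroid, move
each centroid to its cluster mean — which monotonically decreases the
squared-distance objective; the reported ``inertia`` defaults to the sum of
*unsquared* Euclidean distances, matching the square-root form of the
average-distance statistic the selector thresholds against.

Initialization follows the pseudocode convention of drawing K distinct data
rows as the starting centroids (k-means++ available as an option).  Because
random-row initialization can land in local optima even on tiny inputs, the
fit runs ``n_init`` seeded restarts and keeps the lowest-inertia model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["ClusterModel", "fit_kmeans", "point_distances", "average_distance"]


@dataclass
class ClusterModel:
    """Fitted K-means model.

    centroids : (K, d) centroid coordinates.
    assignment : per-point cluster index in [0, K); nearest-centroid ties are
        broken toward the lowest cluster index.
    point_distance : per-point Euclidean distance to the assigned centroid.
    inertia : sum over points of the per-point objective (unsquared distance
        by default, squared if ``objective="squared"``).
    """

    centroids: np.ndarray
    assignment: np.ndarray
    point_distance: np.ndarray
    inertia: float
    n_iter: int
    seed: int
    objective: str = "euclidean"

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_clusters)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "centroids": self.centroids.tolist(),
            "inertia": self.inertia,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "objective": self.objective,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _init_random_rows(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    rows = rng.choice(X.shape[0], size=k, replace=False)
    return X[rows].copy()


def _init_plusplus(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centroids = [X[rng.integers(X.shape[0])]]
    for _ in range(1, k):
        d2 = cdist(X, np.asarray(centroids)).min(axis=1) ** 2
        total = d2.sum()
        if total == 0:
            centroids.append(X[rng.integers(X.shape[0])])
            continue
        centroids.append(X[rng.choice(X.shape[0], p=d2 / total)])
    return np.asarray(centroids)


def _lloyd(
    X: np.ndarray,
    centroids: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Run Lloyd iterations from given centroids; returns (centroids, assignment, n_iter)."""
    n, _ = X.shape
    k = centroids.shape[0]
    assignment = np.full(n, -1, dtype=int)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        dist = cdist(X, centroids)
        new_assignment = dist.argmin(axis=1)  # argmin takes the lowest index on ties

        # empty-cluster repair: the point farthest from its centroid seeds the gap
        for c in range(k):
            if not np.any(new_assignment == c):
                far = int(dist[np.arange(n), new_assignment].argmax())
                new_assignment[far] = c
                centroids[c] = X[far]

        new_centroids = np.vstack(
            [X[new_assignment == c].mean(axis=0) for c in range(k)]
        )
        shift = float(np.linalg.norm(new_centroids - centroids, axis=1).max())
        stable = np.array_equal(new_assignment, assignment)
        centroids = new_centroids
        assignment = new_assignment
        if stable or shift < tol:
            break
    return centroids, assignment, n_iter


def _inertia(dist: np.ndarray, objective: str) -> float:
    if objective == "euclidean":
        return float(dist.sum())
    if objective == "squared":
        return float((dist**2).sum())
    raise ValueError(f"unknown objective {objective!r}")


def fit_kmeans(
    X: np.ndarray,
    n_clusters: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    init: str | np.ndarray = "random",
    n_init: int = 10,
    objective: str = "euclidean",
) -> ClusterModel:
    """Fit K-means by Lloyd iteration with seeded restarts.

    ``init`` may be ``"random"`` (K distinct data rows), ``"k-means++"``, or
    an explicit (K, d) centroid array (then no restarts).  Deterministic for
    a given seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n = X.shape[0]
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if n_clusters < 1 or n_clusters > n:
        raise ValueError(f"need 1 <= K <= n, got K={n_clusters}, n={n}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    if isinstance(init, np.ndarray):
        starts = [np.asarray(init, dtype=float).copy()]
    else:
        rng = np.random.default_rng(seed)
        init_fn = {"random": _init_random_rows, "k-means++": _init_plusplus}[init]
        starts = [init_fn(X, n_clusters, rng) for _ in range(max(1, n_init))]

    best: ClusterModel | None = None
    for c0 in starts:
        if c0.shape != (n_clusters, X.shape[1]):
            raise ValueError("initial centroids have wrong shape")
        centroids, assignment, n_iter = _lloyd(X, c0, max_iter, tol)
        d = np.linalg.norm(X - centroids[assignment], axis=1)
        model = ClusterModel(
            centroids=centroids,
            assignment=assignment,
            point_distance=d,
            inertia=_inertia(d, objective),
            n_iter=n_iter,
            seed=seed,
            objective=objective,
        )
        if best is None or model.inertia < best.inertia:
            best = model
    assert best is not None
    return best


def point_distances(model: ClusterModel, X: np.ndarray) -> np.ndarray:
    """Euclidean distance of each row of X to the centroid of its assigned cluster."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[1]} columns, model {model.centroids.shape[1]}"
        )
    if X.shape[0] != model.assignment.shape[0]:
        raise ValueError("X row count does not match the fitted assignment")
    return np.linalg.norm(X - model.centroids[model.assignment], axis=1)


def average_distance(
    model: ClusterModel,
    X: np.ndarray | None = None,
    scope: str = "per_cluster",
) -> float | np.ndarray:
    """Average centroid distance, either per cluster or as a single global mean.

    scope="global": sum of all per-point distances divided by the total count
    (one number).  scope="per_cluster": mean distance of each cluster's own
    members (one number per cluster) — the statistic the boundary selector
    thresholds by default.
    """
    d = model.point_distance if X is None else point_distances(model, X)
    if scope == "global":
        return float(d.mean())
    if scope == "per_cluster":
        sizes = model.cluster_sizes()
        if np.any(sizes == 0):
            raise ValueError("empty cluster: per-cluster average undefined")
        sums = np.bincount(model.assignment, weights=d, minlength=model.n_clusters)
        return sums / sizes
    raise ValueError(f"unknown scope {scope!r}")
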