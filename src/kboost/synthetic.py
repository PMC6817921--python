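"""Synthetic two-class imbalanced datasets and hand-checkable fixtures.

``make_imbalanced`` draws each class from a Gaussian mixture with unit
within-component scale, a controllable distance between the class means
(``separation``, in within-class standard deviations), a deterministic
class-count split realizing the requested imbalance ratio exactly, and an
optional number of sub-blobs per class.  Gaussian geometry keeps the
cluster-boundary structure analytically predictable, which is what the
selector's enrichment properties are tested against; real tabular data
(heavy tails, correlated or discrete attributes) is deliberately not
emulated here.

``fixture_suite`` builds the tiny named datasets used across the test
suite, each with a property checkable by hand or exhaustive enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import TabularDataset

__all__ = ["SyntheticSpec", "make_imbalanced", "fixture_suite"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings.

    n : total rows.
    ir : imbalance ratio (majority/minority), >= 1; counts are fixed
        deterministically as minority = round(n / (1 + ir)).
    dims : feature dimensionality.
    separation : distance between the class mean vectors, in units of the
        unit within-component standard deviation (0 = no signal).
    n_subclusters : Gaussian components per class (centers jittered around
        the class mean with unit spread when > 1).
    """

    n: int = 600
    ir: float = 5.0
    dims: int = 8
    separation: float = 4.0
    n_subclusters: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if self.ir < 1:
            raise ValueError("ir must be >= 1")
        if self.dims < 1:
            raise ValueError("dims must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.n_subclusters < 1:
            raise ValueError("n_subclusters must be >= 1")


def make_imbalanced(spec: SyntheticSpec) -> TabularDataset:
    """Generate a two-class Gaussian-mixture dataset per the spec."""
    n_min = int(round(spec.n / (1.0 + spec.ir)))
    n_maj = spec.n - n_min
    if n_min < 2:
        raise ValueError(
            f"minority count {n_min} < 2 for n={spec.n}, ir={spec.ir}"
        )
    rng = np.random.default_rng(spec.seed)
    direction = rng.normal(size=spec.dims)
    direction /= np.linalg.norm(direction)
    means = {0: np.zeros(spec.dims), 1: spec.separation * direction}

    blocks, labels = [], []
    for cls, count in ((0, n_maj), (1, n_min)):
        if spec.n_subclusters == 1:
            centers = means[cls][None, :]
        else:
            centers = means[cls] + rng.normal(size=(spec.n_subclusters, spec.dims))
        sizes = np.full(spec.n_subclusters, count // spec.n_subclusters)
        sizes[: count % spec.n_subclusters] += 1
        for c, sz in zip(centers, sizes):
            blocks.append(c + rng.normal(size=(sz, spec.dims)))
        labels.append(np.full(count, cls, dtype=int))

    X = np.vstack(blocks)
    y = np.concatenate(labels)
    perm = rng.permutation(spec.n)
    return TabularDataset(
        features=X[perm],
        labels=y[perm],
        feature_names=[f"f{j}" for j in range(spec.dims)],
    )


def fixture_suite(seed: int = 0) -> dict[str, TabularDataset]:
    """Small named datasets with hand-verifiable structure.

    kmeans6 : six 2-D points in two tight triads around (0,0) and (10,10);
        the optimal 2-cluster partition is the triad split (provable by
        enumerating all 2^6 labelings).
    triangle345 : a single point at (3,4) plus the origin — the 3-4-5
        distance case for centroid-distance checks.
    stump : 1-D points {1,2,4,5}, label = x > 3; perfectly separable by a
        single threshold at 3.0.
    noisy_xor : 60 points on the XOR pattern with Gaussian jitter; a depth-1
        tree cannot separate it, a boosted ensemble can improve on it.
    rings : 40 points at hand-placed radii from the origin (known distance
        quantiles) with an imbalanced labeling, for selection-threshold
        tests.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, TabularDataset] = {}

    tri = np.array([[0.0, 0.0], [0.5, 0.0], [0.0, 0.5]])
    out["kmeans6"] = TabularDataset(
        features=np.vstack([tri, tri + 10.0]),
        labels=np.array([0, 0, 0, 1, 1, 1]),
    )

    out["triangle345"] = TabularDataset(
        features=np.array([[0.0, 0.0], [3.0, 4.0]]),
        labels=np.array([0, 1]),
    )

    xs = np.array([1.0, 2.0, 4.0, 5.0])
    out["stump"] = TabularDataset(
        features=xs[:, None], labels=(xs > 3).astype(int)
    )

    corners = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    reps = np.repeat(corners, 15, axis=0)
    labels_xor = np.repeat([0, 1, 1, 0], 15)
    out["noisy_xor"] = TabularDataset(
        features=reps + 0.15 * rng.normal(size=reps.shape),
        labels=labels_xor,
    )

    # 40 points on circles of known radius: 8 per radius in {1,2,3,4,5}
    radii = np.repeat([1.0, 2.0, 3.0, 4.0, 5.0], 8)
    angles = np.tile(np.linspace(0, 2 * np.pi, 8, endpoint=False), 5)
    ring_X = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    ring_y = (radii >= 4.0).astype(int)  # outer rings are the minority class
    out["rings"] = TabularDataset(features=ring_X, labels=ring_y)

    return out
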