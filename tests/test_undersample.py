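"""Boundary-instance selection: predicate, balancing, partition and enrichment properties."""

import numpy as np
import pytest

from kboost import (
    DegenerateSelectionError,
    SelectionParams,
    SyntheticSpec,
    TabularDataset,
    make_imbalanced,
    select_informative,
    split_train_test,
)
from kboost.kmeans import fit_kmeans


def oracle_selection(ds, params):
    """Independent filter-then-balance loop coded directly from the procedure:
    cluster, threshold per-point distance against eta times the cluster mean
    distance, then (for trim) keep the m most informative per class."""
    model = fit_kmeans(ds.features, params.n_clusters, seed=params.seed)
    d = model.point_distance
    avg = np.array([d[model.assignment == c].mean() for c in range(params.n_clusters)])
    thr = params.eta * avg[model.assignment]
    cand = d >= thr if params.rule == "boundary" else d < thr
    by_class = {}
    for cls in (0, 1):
        idx = [i for i in range(ds.n) if cand[i] and ds.labels[i] == cls]
        by_class[cls] = idx
    if params.balance == "none":
        return sorted(by_class[0] + by_class[1])
    m = min(len(by_class[0]), len(by_class[1]))
    keep = []
    for cls in (0, 1):
        sign = -1 if params.rule == "boundary" else 1
        ordered = sorted(by_class[cls], key=lambda i: (sign * d[i], i))
        keep += ordered[:m]
    return sorted(keep)


class TestSelectInformative:
    def test_boundary_predicate_holds(self, blobs_ir5):
        params = SelectionParams(eta=1.0, balance="none", seed=0)
        sel = select_informative(blobs_ir5, params)
        d = sel.distances
        base = sel.threshold_base
        assert np.all(d[sel.selected_idx] >= 1.0 * base[sel.selected_idx])
        assert d[sel.selected_idx].mean() > d[sel.rejected_idx].mean()

    def test_eta_zero_selects_everything(self, blobs_ir5):
        sel = select_informative(
            blobs_ir5, SelectionParams(eta=0.0, balance="none", seed=0)
        )
        assert sel.selected_idx.size == blobs_ir5.n

    def test_huge_eta_raises_degenerate(self, blobs_ir5):
        with pytest.raises(DegenerateSelectionError):
            select_informative(
                blobs_ir5, SelectionParams(eta=1e6, balance="none", seed=0)
            )

    @pytest.mark.parametrize("rule", ["boundary", "interior"])
    @pytest.mark.parametrize("balance", ["none", "trim"])
    def test_matches_independent_oracle(self, fixtures, rule, balance):
        ds = fixtures["rings"]
        params = SelectionParams(eta=0.8, rule=rule, balance=balance, seed=0)
        try:
            sel = select_informative(ds, params)
        except DegenerateSelectionError:
            oracle = oracle_selection(ds, params)
            assert min(
                sum(ds.labels[i] == 1 for i in oracle),
                sum(ds.labels[i] == 0 for i in oracle),
            ) == 0 or len(oracle) == 0
            return
        assert sel.selected_idx.tolist() == oracle_selection(ds, params)

    def test_partition_property(self, blobs_ir5):
        for eta in (0.3, 0.8, 1.2):
            sel = select_informative(blobs_ir5, SelectionParams(eta=eta, seed=1))
            merged = np.sort(np.concatenate([sel.selected_idx, sel.rejected_idx]))
            np.testing.assert_array_equal(merged, np.arange(blobs_ir5.n))
            assert np.intersect1d(sel.selected_idx, sel.rejected_idx).size == 0

    def test_eta_monotonicity_boundary_no_balance(self, blobs_ir5):
        etas = [0.2, 0.6, 1.0, 1.4]
        sels = [
            set(
                select_informative(
                    blobs_ir5, SelectionParams(eta=e, balance="none", seed=2)
                ).selected_idx.tolist()
            )
            for e in etas
        ]
        for smaller_eta, larger_eta in zip(sels, sels[1:]):
            assert larger_eta <= smaller_eta

    def test_exact_balance_guarantee(self):
        for seed in range(5):
            ds = make_imbalanced(
                SyntheticSpec(n=240, ir=3.0, dims=3, separation=4.0, seed=seed)
            )
            sel = select_informative(ds, SelectionParams(eta=1.0, seed=seed))
            assert sel.balanced
            assert sel.per_class_selected[0] == sel.per_class_selected[1] > 0

    def test_idempotent_on_own_selection_at_eta_zero(self, blobs_ir5):
        sel = select_informative(blobs_ir5, SelectionParams(eta=1.0, seed=3))
        sub = blobs_ir5.take(sel.selected_idx)
        again = select_informative(sub, SelectionParams(eta=0.0, seed=3))
        np.testing.assert_array_equal(again.selected_idx, np.arange(sub.n))

    def test_degenerate_single_class_input(self):
        ds = TabularDataset(features=np.random.default_rng(0).normal(size=(10, 2)),
                            labels=np.ones(10, dtype=int))
        with pytest.raises(DegenerateSelectionError):
            select_informative(ds, SelectionParams())


class TestRebalance:
    def test_trim_drops_least_informative_negatives(self):
        # hand-placed distances: positives on an outer ring, negatives mixed
        rng = np.random.default_rng(5)
        angles = rng.uniform(0, 2 * np.pi, size=80)
        radii = np.concatenate([np.full(30, 5.0), np.linspace(2.0, 6.0, 50)])
        X = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
        y = np.array([1] * 30 + [0] * 50)
        ds = TabularDataset(features=X, labels=y)
        sel = select_informative(
            ds, SelectionParams(eta=0.0, n_clusters=1, balance="trim", seed=0)
        )
        # eta 0 keeps all candidates; trim must reduce negatives to 30,
        # dropping the 20 closest to the centroid
        assert sel.per_class_selected == {1: 30, 0: 30}
        neg_sel = sel.selected_idx[ds.labels[sel.selected_idx] == 0]
        neg_rej = sel.rejected_idx
        assert sel.distances[neg_sel].min() >= sel.distances[neg_rej].max() - 1e-9

    def test_already_balanced_is_noop(self):
        ds = make_imbalanced(SyntheticSpec(n=200, ir=1.0, dims=2, separation=5.0, seed=2))
        sel = select_informative(ds, SelectionParams(eta=0.0, seed=0))
        assert sel.eta_effective == 0.0
        assert sel.selected_idx.size == ds.n

    def test_relax_eta_caps_at_other_class_count(self):
        # positives clustered tightly at their centroid (tiny distances), so at
        # eta=1 few qualify; at eta/2 many do.  negatives on a wide ring.
        rng = np.random.default_rng(9)
        n_pos, n_neg = 60, 40
        pos_r = np.concatenate([np.full(5, 2.0), np.full(55, 0.9)])
        neg_r = np.full(n_neg, 1.0)
        ang_p = rng.uniform(0, 2 * np.pi, n_pos)
        ang_n = rng.uniform(0, 2 * np.pi, n_neg)
        X = np.vstack(
            [
                np.column_stack([pos_r * np.cos(ang_p), pos_r * np.sin(ang_p)]),
                np.column_stack([20 + neg_r * np.cos(ang_n), neg_r * np.sin(ang_n)]),
            ]
        )
        ds = TabularDataset(features=X, labels=np.array([1] * n_pos + [0] * n_neg))
        sel = select_informative(
            ds, SelectionParams(eta=1.5, balance="relax_eta", seed=0)
        )
        assert sel.per_class_selected[1] == sel.per_class_selected[0]
        assert sel.eta_effective < 1.5  # relaxation happened for the deficient class


class TestSplitTrainTest:
    def test_partition_and_sizes(self, blobs_ir5):
        sel = select_informative(blobs_ir5, SelectionParams(eta=1.0, seed=4))
        train, test = split_train_test(blobs_ir5, sel)
        assert train.n == sel.selected_idx.size
        assert test.n == blobs_ir5.n - train.n
        # conservation: concatenating and sorting by original index reproduces ds
        rebuilt = np.vstack([train.features, test.features])
        order = np.argsort(np.concatenate([sel.selected_idx, sel.rejected_idx]))
        np.testing.assert_array_equal(rebuilt[order], blobs_ir5.features)

    def test_balanced_train_skews_test(self, blobs_ir5):
        sel = select_informative(blobs_ir5, SelectionParams(eta=1.0, seed=4))
        train, test = split_train_test(blobs_ir5, sel)
        assert train.n_positive == train.n_negative
        assert test.n_negative / test.n_positive > 5.0
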