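"""Confusion metrics, MCC conventions, AUC, Friedman/Nemenyi rank statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import friedmanchisquare

from kboost import (
    ConfusionMatrix,
    auc_from_scores,
    confusion,
    friedman_mean_ranks,
    friedman_test,
    g_mean,
    mcc,
    metric_report,
    nemenyi_cd,
    pairwise_nemenyi,
)

# printed benchmark MCC values for four methods on ten datasets; the hybrid
# boundary-selection method is the first row and is best on every dataset
MCC_TABLE = np.array([
    # abalone pima  rw1    rw2    rw3    rw4    white  yst1   yst2   yst3
    [0.299, 0.454, 0.446, 0.712, 0.194, 0.380, 0.625, 0.898, 0.855, 0.280],  # K-Boosted
    [0.264, 0.432, 0.397, 0.590, 0.054, 0.317, 0.502, 0.497, 0.836, 0.232],  # SMOTEBoost
    [0.150, 0.446, 0.340, 0.577, 0.171, 0.152, 0.490, 0.552, 0.824, 0.270],  # RUSBoost
    [0.232, 0.425, 0.377, 0.691, 0.137, 0.232, 0.593, 0.450, 0.821, 0.195],  # SMOTE-Boosted
])


class TestConfusion:
    def test_perfect_agreement(self):
        y = np.array([1] * 10 + [0] * 10)
        cm = confusion(y, y)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (10, 0, 0, 10)

    def test_flipping_predictions_swaps_cells(self, rng):
        y = rng.integers(0, 2, size=50)
        p = rng.integers(0, 2, size=50)
        cm, cm_f = confusion(y, p), confusion(y, 1 - p)
        assert (cm.tp, cm.fn) == (cm_f.fn, cm_f.tp)
        assert (cm.tn, cm.fp) == (cm_f.fp, cm_f.tn)

    def test_matches_counting_loop(self, rng):
        y = rng.integers(0, 2, size=50)
        p = rng.integers(0, 2, size=50)
        cm = confusion(y, p)
        assert cm.tp == sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
        assert cm.fn == sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
        assert cm.fp == sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
        assert cm.total == 50

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(np.array([1, 0]), np.array([1]))


class TestMcc:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((10, 0, 0, 10), 1.0),
            ((0, 10, 10, 0), -1.0),
            ((15, 1, 0, 16), (16 * 15 - 0) / math.sqrt(15 * 16 * 16 * 17)),
        ],
    )
    def test_values(self, cells, expected):
        assert mcc(ConfusionMatrix(*cells)) == pytest.approx(expected, abs=1e-12)

    def test_derived_case_printed_precision(self):
        # (16*15 - 0) / sqrt(15*16*16*17) = 0.93934 -> 0.9393 at 4 d.p.
        assert mcc(ConfusionMatrix(15, 1, 0, 16)) == pytest.approx(0.9393, abs=5e-5)

    def test_zero_marginal_convention(self):
        # constant predictor: TP+FP = 0
        assert mcc(ConfusionMatrix(0, 10, 0, 40)) == 0.0

    @given(
        tp=st.integers(0, 40), fn=st.integers(0, 40),
        fp=st.integers(0, 40), tn=st.integers(0, 40),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_class_swap_symmetry(self, tp, fn, fp, tn):
        a = mcc(ConfusionMatrix(tp, fn, fp, tn))
        b = mcc(ConfusionMatrix(tn, fp, fn, tp))
        assert a == pytest.approx(b, abs=1e-12)


class TestMetricReport:
    @pytest.mark.parametrize(
        "sens,spec,expected",
        [
            (0.9375, 1.0, 0.9682),
            (0.991, 0.969, 0.9799),
            (1.0, 0.9617, 0.9807),
            (0.957, 0.949, 0.953),
        ],
    )
    def test_g_mean_identities_on_reported_rates(self, sens, spec, expected):
        assert g_mean(sens, spec) == pytest.approx(expected, abs=5e-5)

    def test_report_fields_and_gmean_identity(self, rng):
        y = np.array([1] * 16 + [0] * 16)
        p = np.array([1] * 15 + [0] * 1 + [1] * 0 + [0] * 16)
        rep = metric_report(confusion(y, p))
        assert rep.accuracy == pytest.approx(31 / 32)
        assert rep.sensitivity == pytest.approx(15 / 16)
        assert rep.specificity == pytest.approx(1.0)
        assert rep.g_mean**2 == pytest.approx(rep.sensitivity * rep.specificity, abs=1e-12)
        assert "balanced-accuracy fallback" in rep.flags[0]

    def test_absent_class_flagged_not_zeroed(self):
        rep = metric_report(confusion(np.zeros(5, dtype=int), np.zeros(5, dtype=int)))
        assert math.isnan(rep.sensitivity)
        assert any("sensitivity undefined" in f for f in rep.flags)

    def test_perfectly_ranked_scores_auc_one(self):
        y = np.array([0, 0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        assert auc_from_scores(y, s) == pytest.approx(1.0)

    def test_permuted_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 20 + [0] * 80)
        aucs = [
            auc_from_scores(y, rng.permutation(np.linspace(0, 1, 100)))
            for _ in range(1000)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_tied_scores_average(self):
        y = np.array([1, 0])
        s = np.array([0.5, 0.5])
        assert auc_from_scores(y, s) == pytest.approx(0.5)


class TestFriedman:
    def test_best_method_has_mean_rank_k_on_printed_table(self):
        ranks = friedman_mean_ranks(MCC_TABLE)
        assert ranks[0] == pytest.approx(4.0, abs=1e-12)
        assert ranks.mean() == pytest.approx(2.5)  # (k+1)/2

    def test_demsar_polarity(self):
        ranks = friedman_mean_ranks(MCC_TABLE, polarity="demsar")
        assert ranks[0] == pytest.approx(1.0)

    def test_identical_columns_tie_average(self):
        table = np.array([[1.0, 2.0], [1.0, 2.0]])
        np.testing.assert_allclose(friedman_mean_ranks(table), [1.5, 1.5])

    def test_random_table_matches_sort_based_oracle(self, rng):
        table = rng.normal(size=(3, 5))
        ranks = friedman_mean_ranks(table)
        expected = np.zeros(3)
        for j in range(5):
            order = np.argsort(np.argsort(table[:, j]))
            expected += order + 1  # no ties in continuous draws
        np.testing.assert_allclose(ranks, expected / 5)

    def test_identical_methods_statistic_zero(self):
        table = np.tile(np.array([1.0, 2.0, 3.0]), (4, 1))
        stat, p = friedman_test(table)
        assert stat == 0.0 and p == 1.0

    def test_closed_form_dominance_k2_n10(self):
        table = np.vstack([np.arange(10) + 10.0, np.arange(10)])
        stat, p = friedman_test(table)
        assert stat == pytest.approx(10.0, abs=1e-12)

    def test_matches_scipy_reference(self, rng):
        table = rng.normal(size=(4, 10))
        stat, p = friedman_test(table)
        ref_stat, ref_p = friedmanchisquare(*[table[i] for i in range(4)])
        assert stat == pytest.approx(ref_stat, abs=1e-10)
        assert p == pytest.approx(ref_p, abs=1e-10)

    def test_matches_scipy_with_ties(self):
        table = np.array(
            [[1.0, 2.0, 2.0, 5.0], [1.0, 3.0, 2.0, 4.0], [2.0, 3.0, 1.0, 4.0]]
        )
        stat, p = friedman_test(table)
        ref_stat, ref_p = friedmanchisquare(*[table[i] for i in range(3)])
        assert stat == pytest.approx(ref_stat, abs=1e-10)

    def test_iman_davenport_smaller_p_under_strong_effect(self):
        stat_c, p_c = friedman_test(MCC_TABLE, variant="chi2")
        stat_f, p_f = friedman_test(MCC_TABLE, variant="iman_davenport")
        assert p_f < p_c

    def test_input_validation(self):
        with pytest.raises(ValueError):
            friedman_test(np.ones((1, 5)))
        with pytest.raises(ValueError):
            friedman_mean_ranks(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestNemenyi:
    def test_k4_n10(self):
        assert nemenyi_cd(4, 10, 0.05) == pytest.approx(2.569 * math.sqrt(20 / 60), abs=1e-9)
        assert nemenyi_cd(4, 10, 0.05) == pytest.approx(1.483, abs=5e-4)

    def test_k2_n10(self):
        assert nemenyi_cd(2, 10, 0.05) == pytest.approx(1.960 * math.sqrt(6 / 60), abs=1e-9)
        assert nemenyi_cd(2, 10, 0.05) == pytest.approx(0.620, abs=5e-4)

    def test_monotone_decreasing_in_n(self):
        cds = [nemenyi_cd(4, n) for n in (5, 10, 50, 500, 500000)]
        assert all(a > b for a, b in zip(cds, cds[1:]))
        assert cds[-1] < 0.01

    def test_untabulated_alpha_rejected(self):
        with pytest.raises(ValueError):
            nemenyi_cd(4, 10, alpha=0.01)

    def test_pairwise_bundle_on_printed_table(self):
        res = pairwise_nemenyi(MCC_TABLE, method_names=["kboost", "smb", "rusb", "smbc5"])
        assert res.mean_ranks[0] == pytest.approx(4.0)
        sig = res.significant_pairs()
        assert sig[0, 2]  # best vs RUSBoost gap 4 - 1.9 > CD 1.483
        assert not sig.diagonal().any()
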