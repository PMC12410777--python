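"""Group statistics: median split, exact rank-sum, effect sizes, FDR."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from anxsig.stats import (
    GroupAssignment, bh_correct, cohens_d, gad7_change, median_split,
    psd_group_comparison, ranksum_test, results_table, timecourse_tests,
    whole_task_test,
)


def _brute_force_p(x, y):
    """Exact two-sided p by enumerating all group relabelings."""
    from scipy.stats import rankdata
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w_obs = ranks[: len(x)].sum()
    sums = np.array([sum(c) for c in combinations(ranks, len(x))])
    lower = (sums <= w_obs + 1e-9).mean()
    upper = (sums >= w_obs - 1e-9).mean()
    return min(1.0, 2.0 * min(lower, upper))


class TestGad7Change:
    def test_boundary_and_arithmetic(self):
        assert gad7_change(np.zeros(7), np.full(7, 3.0)) == 3.0
        assert gad7_change(np.ones(7), np.ones(7)) == 0.0
        np.testing.assert_allclose(
            gad7_change(np.full(7, 1.0), np.full(7, 1.5)), 0.5)

    def test_item_count_enforced(self):
        with pytest.raises(ValueError, match="7 item"):
            gad7_change(np.zeros(6), np.zeros(7))


class TestMedianSplit:
    def test_17_distinct_scores_give_9_8(self, rng):
        scores = {f"p{i:02d}": float(v)
                  for i, v in enumerate(rng.permutation(17))}
        ga = median_split(scores)
        assert len(ga.anxious) == 9
        assert len(ga.non_anxious) == 8
        assert min(ga.change_scores[p] for p in ga.anxious) > \
            max(ga.change_scores[p] for p in ga.non_anxious)

    def test_even_n_splits_at_median(self):
        ga = median_split({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        assert sorted(ga.anxious) == ["c", "d"]
        assert sorted(ga.non_anxious) == ["a", "b"]

    def test_order_invariance(self, rng):
        scores = {f"p{i}": float(v) for i, v in enumerate(rng.normal(size=9))}
        fwd = median_split(scores)
        rev = median_split(dict(reversed(list(scores.items()))))
        assert fwd.groups == rev.groups

    def test_ties_rejected(self):
        with pytest.raises(ValueError, match="tie"):
            median_split({"a": 1.0, "b": 1.0, "c": 2.0, "d": 3.0})

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError, match="4"):
            median_split({"a": 1.0, "b": 2.0, "c": 3.0})


class TestRankSum:
    def test_canonical_example(self):
        w, p = ranksum_test([3.0, 4.0], [1.0, 2.0])
        assert w == 7.0
        np.testing.assert_allclose(p, 2.0 / 6.0)

    def test_identical_multisets_give_p_one(self):
        _, p = ranksum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 5), (3, 3), (4, 5),
                                       (5, 5), (6, 6), (3, 9)])
    def test_exact_p_matches_enumeration(self, rng, n1, n2):
        for _ in range(3):
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            _, p = ranksum_test(x, y)
            np.testing.assert_allclose(p, _brute_force_p(x, y), rtol=1e-10)

    def test_9_vs_8_spot_check_against_enumeration(self, rng):
        x, y = rng.normal(size=9), rng.normal(size=8)
        _, p = ranksum_test(x, y)
        np.testing.assert_allclose(p, _brute_force_p(x, y), rtol=1e-10)

    def test_agrees_with_scipy_exact(self, rng):
        for n1, n2 in [(4, 4), (9, 8), (10, 10)]:
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            w, p = ranksum_test(x, y)
            res = mannwhitneyu(x, y, method="exact")
            np.testing.assert_allclose(p, res.pvalue, rtol=1e-10)
            # scipy's U statistic is W minus the minimum rank sum
            np.testing.assert_allclose(res.statistic,
                                       w - n1 * (n1 + 1) / 2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ranksum_test([1.0], [2.0, 3.0])


class TestCohensD:
    def test_unit_effect(self, rng):
        z = rng.normal(size=50)
        z = (z - z.mean()) / z.std(ddof=1)
        d = cohens_d(z + 1.0, z)
        np.testing.assert_allclose(d, 1.0, rtol=1e-10)

    def test_identical_groups_zero(self, rng):
        x = rng.normal(size=20)
        assert cohens_d(x, x.copy()) == 0.0

    def test_pooled_formula_on_summary_calibrated_groups(self, rng):
        # groups constructed to the study's printed HR summaries
        def calibrated(n, mean, sd):
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z
        x = calibrated(9, 79.445, 13.424)
        y = calibrated(8, 66.75, 7.184)
        pooled = np.sqrt((8 * 13.424**2 + 7 * 7.184**2) / 15)
        np.testing.assert_allclose(cohens_d(x, y),
                                   (79.445 - 66.75) / pooled, rtol=1e-10)

    def test_zero_pooled_sd_flagged(self):
        assert np.isnan(cohens_d([1.0, 1.0], [1.0, 1.0]))


class TestBH:
    def test_hand_applied_step_up_rule(self):
        np.testing.assert_allclose(bh_correct([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_correct([0.04]), [0.04])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_correct([1.0, 1.0, 1.0]), 1.0)

    def test_matches_manual_step_up_on_random_p(self, rng):
        p = rng.uniform(0.001, 1.0, 40)
        order = np.argsort(p)
        m = len(p)
        adj_sorted = p[order] * m / np.arange(1, m + 1)
        adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
        manual = np.empty(m)
        manual[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(bh_correct(p), manual, rtol=1e-12)

    def test_corrected_at_least_raw_and_capped(self, rng):
        p = rng.uniform(0.001, 1.0, 25)
        q = bh_correct(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            bh_correct([0.0, 0.5])


def _assignment(n1=9, n2=8):
    ids = [f"p{i:02d}" for i in range(n1 + n2)]
    groups = {p: ("anxious" if i < n1 else "non_anxious")
              for i, p in enumerate(ids)}
    return ids, GroupAssignment(groups, {p: float(i)
                                         for i, p in enumerate(ids)})


class TestTimecourseAndWholeTask:
    def test_single_epoch_mask_length_one(self, rng):
        ids, ga = _assignment()
        df = pd.DataFrame(rng.normal(size=(17, 1)), index=ids)
        mask = timecourse_tests(df, ga)
        assert mask.mask.shape == (1,)

    def test_strong_effect_detected_in_most_epochs(self, rng):
        ids, ga = _assignment()
        df = pd.DataFrame(rng.normal(size=(17, 20)), index=ids)
        df.iloc[:9] += 3.0  # 3 pooled SDs separation
        mask = timecourse_tests(df, ga)
        assert mask.mask.mean() > 0.9

    def test_sparse_epoch_masked_missing(self, rng):
        ids, ga = _assignment()
        df = pd.DataFrame(rng.normal(size=(17, 2)), index=ids)
        df.iloc[:8, 1] = np.nan  # one anxious participant left in epoch 1
        mask = timecourse_tests(df, ga)
        assert np.isnan(mask.p_raw[1]) and not mask.mask[1]

    def test_whole_task_excludes_all_missing_participant(self, rng):
        ids, ga = _assignment()
        df = pd.DataFrame(rng.normal(size=(17, 10)), index=ids)
        df.iloc[0] = np.nan
        res = whole_task_test(df, ga, "hr", "bpm")
        assert res.excluded == ["p00"]
        assert res.n_per_group == {"anxious": 8, "non_anxious": 8}

    def test_results_table_shape(self, rng):
        ids, ga = _assignment()
        df = pd.DataFrame(rng.normal(size=(17, 10)), index=ids)
        res = whole_task_test(df, ga, "hr", "bpm")
        table = results_table([res])
        assert list(table.index) == ["hr [bpm]"]
        assert "p_value" in table.columns and "cohens_d" in table.columns


class TestPSDComparison:
    def test_single_cell_corrected_equals_raw(self, rng):
        ids, ga = _assignment()
        psd = rng.uniform(1.0, 2.0, size=(17, 3, 1))  # one bin
        cmpres = psd_group_comparison(psd, np.array([5.0]), ids, ga,
                                      "per_bin_roll")
        np.testing.assert_allclose(cmpres.p_corrected, cmpres.p_raw)

    def test_boosted_band_detected_in_roll_bins(self, rng):
        ids, ga = _assignment()
        freqs = np.arange(51.0)
        psd = rng.uniform(1.0, 1.2, size=(17, 5, 51))
        psd[:9, :, 5:] *= 4.0  # anxious power boosted from 5 Hz up
        cmpres = psd_group_comparison(psd, freqs, ids, ga, "per_bin_roll")
        assert cmpres.mask[5:].mean() > 0.9
        assert cmpres.mask[:5].mean() < 0.5

    def test_unknown_level_rejected(self, rng):
        ids, ga = _assignment()
        with pytest.raises(ValueError, match="level"):
            psd_group_comparison(np.ones((17, 2, 3)), np.arange(3.0), ids,
                                 ga, "nope")
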