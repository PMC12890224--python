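"""Concordance index, time-dependent AUC and risk stratification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survformer import SurvivalTable, concordance_index, km_logrank, time_dependent_auc

from conftest import random_survival


def brute_force_cindex(scores, time, event):
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den, int(den)


def brute_force_auc(scores, time, event, events_only=False):
    Y = sorted(set(time[event == 1]))
    num = den = 0.0
    for t in Y:
        for i in range(len(scores)):
            if not time[i] < t:
                continue
            if events_only and event[i] != 1:
                continue
            for j in range(len(scores)):
                if time[j] > t:
                    den += 1
                    if scores[i] > scores[j]:
                        num += 1
                    elif scores[i] == scores[j]:
                        num += 0.5
    return num / den, int(den)


class TestConcordanceIndex:
    def test_perfect_discrimination(self):
        surv = SurvivalTable([1.0, 2.0, 3.0], [1, 1, 1])
        c, n = concordance_index([3.0, 2.0, 1.0], surv)
        assert c == 1.0 and n == 3

    def test_one_discordant_pair(self):
        surv = SurvivalTable([1.0, 2.0, 3.0], [1, 1, 1])
        c, n = concordance_index([3.0, 1.0, 2.0], surv)
        assert c == pytest.approx(2 / 3) and n == 3

    def test_censored_shorter_time_excludes_pair(self):
        surv = SurvivalTable([1.0, 2.0, 3.0], [1, 0, 1])
        c, n = concordance_index([3.0, 1.0, 2.0], surv)
        assert c == 1.0 and n == 2

    def test_no_comparable_pairs_raises(self):
        surv = SurvivalTable([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1.0, 2.0], surv)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        time, event = random_survival(rng, n, tie_frac=0.5 if seed % 2 else 0.0)
        scores = rng.normal(size=n)
        surv = SurvivalTable(time, event)
        try:
            c, npairs = concordance_index(scores, surv)
        except ValueError:
            return
        bc, bn = brute_force_cindex(scores, time, event)
        assert npairs == bn
        assert c == pytest.approx(bc, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        time, event = random_survival(rng, 25)
        scores = rng.normal(size=25)
        surv = SurvivalTable(time, event)
        c1, _ = concordance_index(scores, surv)
        c2, _ = concordance_index(np.exp(3 * scores), surv)
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_negated_scores_complement(self):
        rng = np.random.default_rng(2)
        time, event = random_survival(rng, 20)
        scores = rng.normal(size=20)  # continuous: no ties
        surv = SurvivalTable(time, event)
        c_pos, _ = concordance_index(scores, surv)
        c_neg, _ = concordance_index(-scores, surv)
        assert c_pos + c_neg == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_lifelines_on_tie_free_data(self):
        from lifelines.utils import concordance_index as ll_cindex

        rng = np.random.default_rng(3)
        time = rng.exponential(size=40) + rng.uniform(0, 1e-6, size=40)
        event = (rng.random(40) > 0.3).astype(int)
        scores = rng.normal(size=40)
        surv = SurvivalTable(time, event)
        ours, _ = concordance_index(scores, surv)
        # lifelines concords on predicted *survival* times (low risk = long life)
        theirs = ll_cindex(time, -scores, event)
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestTimeDependentAuc:
    def test_single_pair_example(self):
        surv = SurvivalTable([1.0, 2.0, 3.0], [1, 1, 1])
        auc, n = time_dependent_auc([3.0, 2.0, 1.0], surv)
        assert auc == 1.0 and n == 1

    def test_reversed_scores_give_zero(self):
        surv = SurvivalTable([1.0, 2.0, 3.0], [1, 1, 1])
        auc, _ = time_dependent_auc([1.0, 2.0, 3.0], surv)
        assert auc == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(4)
        time, event = random_survival(rng, 1500)
        surv = SurvivalTable(time, event)
        auc, _ = time_dependent_auc(rng.uniform(size=1500), surv)
        assert auc == pytest.approx(0.5, abs=0.03)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        time, event = random_survival(rng, n, tie_frac=0.5 if seed % 3 else 0.0)
        scores = rng.normal(size=n)
        surv = SurvivalTable(time, event)
        for mode, flag in (("all", False), ("events_only", True)):
            try:
                auc, npairs = time_dependent_auc(scores, surv, cases=mode)
            except ValueError:
                continue
            b_auc, b_n = brute_force_auc(scores, time, event, events_only=flag)
            assert npairs == b_n
            assert auc == pytest.approx(b_auc, abs=1e-12)


class TestKmLogrank:
    def test_identical_groups_null_statistic(self):
        # two risk groups with identical (time, event) multisets
        time = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        scores = np.array([2.0, 2.0, 2.0, 2.0, 1.0, 1.0, 1.0, 1.0])
        surv = SurvivalTable(time, event)
        res = km_logrank(scores, surv)
        assert res.logrank_stat == pytest.approx(0.0, abs=1e-10)
        assert res.logrank_p == pytest.approx(1.0, abs=1e-10)

    def test_hand_computed_logrank_table(self):
        # group A: events at 1, 2; group B: events at 3, 4 (no censoring).
        # O_A - E_A = 2 - (2/4 + 1/3) = 7/6; V = 1/4 + 2/9 = 17/36;
        # chi-square = (7/6)^2 / (17/36) = 49/17
        surv = SurvivalTable([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        scores = np.array([5.0, 4.0, 1.0, 0.0])  # median split: A high, B low
        res = km_logrank(scores, surv)
        assert res.logrank_stat == pytest.approx(49 / 17, abs=1e-8)

    def test_median_split_balanced(self):
        rng = np.random.default_rng(5)
        time, event = random_survival(rng, 10)
        surv = SurvivalTable(time, event)
        res = km_logrank(rng.permutation(10).astype(float), surv)
        assert (res.group_labels == "high").sum() == 5

    def test_all_tied_scores_fatal(self):
        surv = SurvivalTable([1.0, 2.0, 3.0], [1, 1, 1])
        with pytest.raises(ValueError, match="empty risk group"):
            km_logrank([1.0, 1.0, 1.0], surv)

    def test_km_curve_properties(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.ones(6, dtype=int)
        surv = SurvivalTable(time, event)
        res = km_logrank(np.array([6.0, 5.0, 4.0, 1.0, 2.0, 3.0]), surv)
        for km in res.km_curves.values():
            sf = km.survival_function_.iloc[:, 0].to_numpy()
            assert sf[0] == 1.0
            assert (np.diff(sf) <= 1e-12).all()
        # with no censoring the high-risk group curve is the empirical survival
        km_high = res.km_curves["high"]
        # the high group holds the 3 shortest... scores 6,5,4 -> times 1,2,3
        assert km_high.survival_function_.loc[3.0].iloc[0] == pytest.approx(0.0)
        assert km_high.survival_function_.loc[2.0].iloc[0] == pytest.approx(1 / 3)
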