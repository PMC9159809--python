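"""Scores, group merging, Kaplan-Meier estimation and log-rank tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from moma.survival import (
    build_scores,
    km_estimate,
    logrank_test,
    logrank_trend_test,
    merge_small_groups,
    stratify_by_median,
    stratify_by_overexpression_count,
    stratify_by_score,
)

from oracles import km_oracle, logrank_oracle


def _bool_mat(data, genes, patients):
    return pd.DataFrame(data, index=genes, columns=patients, dtype=bool)


class TestScores:
    def test_additivity(self):
        genes, pats = ["G"], ["p1", "p2", "p3"]
        over = _bool_mat([[True, False, True]], genes, pats)
        mir = _bool_mat([[True, False, False]], genes, pats)
        cn = _bool_mat([[True, False, True]], genes, pats)
        hm = _bool_mat([[True, False, False]], genes, pats)
        scores = build_scores(over, mir, cn, hm)
        assert scores.loc["p1", "G"] == 4
        assert scores.loc["p2", "G"] == 0
        assert scores.loc["p3", "G"] == 2

    def test_misaligned_matrices_rejected(self):
        over = _bool_mat([[True]], ["G"], ["p1"])
        other = _bool_mat([[True]], ["G"], ["p2"])
        with pytest.raises(ValueError, match="misaligned"):
            build_scores(over, other, over, over)


class TestMergeSmallGroups:
    def test_merges_into_larger_neighbour(self):
        assert merge_small_groups({0: 100, 1: 4, 2: 50}) == {
            0: "0-1",
            1: "0-1",
            2: "2",
        }

    def test_no_merge_needed(self):
        assert merge_small_groups({0: 10, 1: 10}) == {0: "0", 1: "1"}

    def test_exhaustion_to_single_group(self):
        assert merge_small_groups({0: 3, 1: 3}) == {0: "0-1", 1: "0-1"}

    def test_five_or_fewer_rule_is_inclusive(self):
        out = merge_small_groups({0: 5, 1: 100})
        assert out[0] == "0-1"
        out = merge_small_groups({0: 6, 1: 100})
        assert out[0] == "0"

    def test_tie_breaks_toward_lower_score(self):
        assert merge_small_groups({0: 50, 1: 4, 2: 50}) == {
            0: "0-1",
            1: "0-1",
            2: "2",
        }

    def test_cascading_merges(self):
        # two undersized neighbours coalesce into one viable group
        out = merge_small_groups({0: 2, 1: 4, 2: 40})
        assert out[0] == out[1] == "0-1"
        assert out[2] == "2"


class TestKaplanMeier:
    def test_closed_form_two_deaths(self):
        c = km_estimate([1.0, 2.0], [1, 1])
        assert c.survival.tolist() == [0.5, 0.0]

    def test_censor_then_death(self):
        c = km_estimate([1.0, 2.0], [0, 1])
        assert c.at(2.0) == 0.0  # risk set of one at t=2

    def test_all_censored(self):
        c = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert c.event_times.size == 0
        assert c.at(5.0) == 1.0

    def test_censored_at_event_time_stays_at_risk(self):
        c = km_estimate([2.0, 2.0], [1, 0])
        assert c.at(2.0) == 0.5

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 20))
    def test_matches_brute_force_product(self, seed, n):
        rng = np.random.default_rng(seed)
        times = rng.integers(1, 8, n).astype(float)  # force ties
        events = rng.integers(0, 2, n)
        c = km_estimate(times, events)
        ev, surv = km_oracle(times, events)
        assert np.array_equal(c.event_times, ev)
        assert np.allclose(c.survival, surv, atol=1e-12)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        times = rng.exponential(100, 50).round(1)
        events = rng.integers(0, 2, 50)
        c = km_estimate(times, events)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for t in c.event_times:
            assert c.at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-12
            )


class TestLogrank:
    def test_two_subject_worked_example(self):
        res = logrank_test([1.0, 2.0], [1, 1], ["A", "B"])
        assert res.statistic == pytest.approx(1.0)
        assert res.p == pytest.approx(0.3173, abs=1e-4)

    def test_identical_groups_give_null(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 0, 1, 1, 0, 1]
        res = logrank_test(times, events, ["A"] * 3 + ["B"] * 3)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_brute_force_and_lifelines(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = 30
            times = rng.exponential(50, n).round(0) + 1
            events = rng.integers(0, 2, n)
            groups = rng.integers(0, 2, n)
            if groups.sum() in (0, n) or events.sum() == 0:
                continue
            res = logrank_test(times, events, groups)
            assert res.statistic == pytest.approx(
                logrank_oracle(times, events, groups == 1), abs=1e-9
            )
        lifelines = pytest.importorskip("lifelines")
        ll = lifelines.statistics.logrank_test(
            times[groups == 0], times[groups == 1],
            events[groups == 0], events[groups == 1],
        )
        assert res.p == pytest.approx(ll.p_value, abs=1e-9)

    def test_permutation_null_p_is_uniform(self):
        """Under random group labels, p-values should be ~U(0,1)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(21)
        n = 80
        times = rng.exponential(100, n)
        events = rng.integers(0, 2, n)
        pvals = []
        for _ in range(200):
            groups = rng.permutation([0] * (n // 2) + [1] * (n - n // 2))
            pvals.append(logrank_test(times, events, groups).p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_time_shift_invariance(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(10, 40)
        events = rng.integers(0, 2, 40)
        groups = rng.integers(0, 2, 40)
        a = logrank_test(times, events, groups)
        b = logrank_test(times + 123.0, events, groups)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)


class TestLogrankTrend:
    def test_two_groups_equals_plain_logrank(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = 40
            times = rng.exponential(30, n)
            events = rng.integers(0, 2, n)
            groups = rng.integers(0, 2, n)
            if len(set(groups)) < 2 or events.sum() == 0:
                continue
            a = logrank_test(times, events, groups)
            b = logrank_trend_test(times, events, groups)
            assert a.statistic == pytest.approx(b.statistic, abs=1e-9)
            assert a.p == pytest.approx(b.p, abs=1e-9)

    def test_identical_groups_give_zero(self):
        times = [1.0, 2.0, 3.0] * 3
        events = [1, 1, 0] * 3
        groups = [0] * 3 + [1] * 3 + [2] * 3
        res = logrank_trend_test(times, events, groups)
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 1

    def test_detects_ordered_hazard(self):
        rng = np.random.default_rng(2)
        scores = np.repeat([0, 1, 2, 3], 40)
        times = rng.exponential(1.0 / (0.01 * np.exp(0.5 * scores)))
        events = np.ones_like(scores)
        res = logrank_trend_test(times, events, scores)
        assert res.p < 1e-4


class TestStratifications:
    def _clin(self, n, seed=0, scores=None, log_hr=0.0):
        rng = np.random.default_rng(seed)
        scores = np.zeros(n) if scores is None else np.asarray(scores)
        t = rng.exponential(1.0 / (0.002 * np.exp(log_hr * scores)), n)
        c = rng.uniform(0, 2000, n)
        return pd.DataFrame(
            {"os_days": np.minimum(t, c), "event": (t <= c).astype(int)},
            index=[f"p{i}" for i in range(n)],
        )

    def test_overexpression_count_groups(self):
        genes = [f"G{i}" for i in range(5)]
        pats = [f"p{i}" for i in range(3)]
        over = pd.DataFrame(
            [[True] * 3, [True, False, True], [True, False, False],
             [True, False, False], [True, False, False]],
            index=genes, columns=pats,
        )
        counts = over.sum(axis=0)
        assert counts.tolist() == [5, 1, 2]
        # permutation of the gene order leaves counts unchanged
        assert over.iloc[::-1].sum(axis=0).tolist() == [5, 1, 2]

    def test_score_stratification_needs_all_patients(self):
        clin = self._clin(4)
        score = pd.Series([0, 1, 2], index=["p0", "p1", "p2"])
        with pytest.raises(ValueError, match="p3"):
            stratify_by_score(score, clin)

    def test_single_group_returns_none(self):
        clin = self._clin(4)
        score = pd.Series([1, 1, 1, 1], index=clin.index)
        res, labels = stratify_by_score(score, clin)
        assert res is None
        assert labels.nunique() == 1

    def test_small_groups_are_merged_before_testing(self):
        clin = self._clin(30, seed=3)
        score = pd.Series([0] * 20 + [1] * 7 + [2] * 3, index=clin.index)
        res, labels = stratify_by_score(score, clin)
        assert set(labels.unique()) == {"0", "1-2"}
        assert res.test == "logrank"

    def test_median_split_constant_feature(self):
        clin = self._clin(5)
        res, labels = stratify_by_median(pd.Series(2.0, index=clin.index), clin)
        assert res is None

    def test_median_split_minimal_two_patients(self):
        clin = self._clin(2, seed=8)
        clin["event"] = [1, 1]
        feat = pd.Series([1.0, 2.0], index=clin.index)
        res, labels = stratify_by_median(feat, clin)
        assert res is not None
        assert sorted(labels.unique()) == ["above_median", "at_or_below_median"]

    def test_median_ties_go_below(self):
        clin = self._clin(4)
        feat = pd.Series([1.0, 2.0, 2.0, 3.0], index=clin.index)
        _, labels = stratify_by_median(feat, clin)
        assert (labels == "above_median").sum() == 1  # only the 3.0

    def test_planted_effect_is_detected(self):
        scores = np.repeat([0, 1, 2, 3, 4], 40)
        clin = self._clin(200, seed=12, scores=scores, log_hr=0.6)
        score = pd.Series(scores, index=clin.index)
        res, _ = stratify_by_score(score, clin)
        assert res.test == "logrank_trend"
        assert res.p < 0.001
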