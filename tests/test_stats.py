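"""Paired tests, exact Wilcoxon, sample size, summaries, evaluation report."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lifeage import (
    InputError,
    PairedCohort,
    SampleSizeSpec,
    evaluate_pre_post,
    paired_t_test,
    required_sample_size,
    summarize_cohort,
    wilcoxon_signed_rank,
)
from lifeage.stats import percent


def brute_force_signed_rank_p(d):
    """Oracle: literal enumeration of every sign assignment of the |d| ranks."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = [
        np.dot(signs, ranks) for signs in itertools.product((0.0, 1.0), repeat=len(d))
    ]
    w_all = np.asarray(w_all)
    p_le = np.mean(w_all <= w_obs + 1e-12)
    p_ge = np.mean(w_all >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestPairedT:
    def test_null_identity(self):
        r = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.statistic, r.p_value) == (0.0, 1.0)
        assert not r.significant

    def test_hand_computed_example(self):
        # d = (1,2,3,4): mean 2.5, sd 1.2910, t = 2.5/(1.2910/2) = 3.873
        r = paired_t_test([0, 0, 0, 0], [1, 2, 3, 4])
        assert r.statistic == pytest.approx(3.873, abs=1e-3)
        assert r.p_value == pytest.approx(0.0305, abs=5e-4)
        assert r.significant and r.n_pairs == 4

    def test_negating_differences_negates_t_preserves_p(self):
        a = paired_t_test([0, 0, 0, 0], [1, 2, 3, 4])
        b = paired_t_test([1, 2, 3, 4], [0, 0, 0, 0])
        assert b.statistic == -a.statistic
        assert b.p_value == a.p_value

    # differences rounded to 3 decimals so a common shift cannot absorb a
    # sub-ulp difference through floating cancellation
    @given(
        st.lists(st.floats(-5, 5).map(lambda x: round(x, 3)), min_size=3, max_size=20),
        st.floats(-100, 100).map(lambda x: round(x, 3)),
    )
    @settings(max_examples=50)
    def test_p_invariant_to_common_shift(self, d, shift):
        pre = np.zeros(len(d))
        post = np.asarray(d)
        base = paired_t_test(pre, post)
        shifted = paired_t_test(pre + shift, post + shift)
        assert shifted.p_value == pytest.approx(base.p_value, rel=1e-9, abs=1e-12)

    def test_matches_scipy_ttest_rel(self):
        rng = np.random.default_rng(7)
        pre, post = rng.normal(size=15), rng.normal(size=15)
        ours = paired_t_test(pre, post)
        ref = sps.ttest_rel(post, pre)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(InputError):
            paired_t_test([1.0], [2.0])

    def test_zero_variance_degenerate_cases(self):
        same = paired_t_test([1, 2, 3], [2, 3, 4])  # constant nonzero differences
        assert same.p_value == 0.0 and np.isinf(same.statistic)


class TestWilcoxon:
    def test_all_positive_small_sample_exact(self):
        r = wilcoxon_signed_rank([0] * 5, [1, 2, 3, 4, 5])
        assert r.statistic == 0.0  # W- = 0
        assert r.p_value == pytest.approx(2 / 32)
        assert r.test == "wilcoxon" and r.n_pairs == 5

    def test_all_zero_differences_degenerate(self):
        r = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert r.p_value == 1.0 and r.n_pairs == 0 and not r.significant

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.4, 1.0, size=10)
        ours = wilcoxon_signed_rank(np.zeros(10), d, mode="exact")
        ref = sps.wilcoxon(d, method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_equals_brute_force_with_ties(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            m = rng.integers(3, 11)
            d = np.round(rng.normal(0.3, 1.0, size=m), 1)  # rounding induces ties
            d = d[d != 0]
            if d.size == 0:
                continue
            ours = wilcoxon_signed_rank(np.zeros(d.size), d, mode="exact")
            assert ours.p_value == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)

    def test_exact_and_approximate_agree_at_m12(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            d = rng.normal(0.5, 1.0, size=12)
            exact = wilcoxon_signed_rank(np.zeros(12), d, mode="exact").p_value
            approx = wilcoxon_signed_rank(np.zeros(12), d, mode="approximate").p_value
            assert approx == pytest.approx(exact, abs=0.02)

    def test_auto_switches_at_m_threshold(self):
        d13 = np.arange(1.0, 14.0)
        auto = wilcoxon_signed_rank(np.zeros(13), d13, mode="auto").p_value
        approx = wilcoxon_signed_rank(np.zeros(13), d13, mode="approximate").p_value
        assert auto == approx

    def test_type_i_error_calibrated_at_nominal_level(self):
        # both tests on pure-null normal differences, n=18 pairs
        rng = np.random.default_rng(2024)
        reps = 10_000
        d = rng.normal(0.0, 1.0, size=(reps, 18))
        mean = d.mean(axis=1)
        s = d.std(axis=1, ddof=1)
        t = mean / (s / np.sqrt(18))
        p_t = 2 * sps.t.sf(np.abs(t), df=17)
        assert np.mean(p_t <= 0.05) == pytest.approx(0.05, abs=0.01)
        hits = 0
        for row in d[:10_000]:
            hits += wilcoxon_signed_rank(np.zeros(18), row).significant
        assert hits / reps == pytest.approx(0.05, abs=0.01)


class TestSampleSize:
    def test_design_point_reproduces_30_enrolled(self):
        n = required_sample_size(SampleSizeSpec(0.5, 0.75, 0.05, 0.90, 0.20))
        assert n.enrolled == 30 and n.complete == 24

    def test_without_dropout_24(self):
        assert required_sample_size(SampleSizeSpec(dropout=0.0)).enrolled == 24

    def test_halving_sd_roughly_quarters_n(self):
        full = required_sample_size(SampleSizeSpec(sd=0.75, dropout=0.0)).complete
        half = required_sample_size(SampleSizeSpec(sd=0.375, dropout=0.0)).complete
        assert half == np.ceil(full / 4) or half <= full / 3

    @pytest.mark.parametrize(
        "field, lo_kwargs, hi_kwargs, direction",
        [
            ("delta", {"delta": 0.25}, {"delta": 0.5}, "non_increasing"),
            ("alpha", {"alpha": 0.01}, {"alpha": 0.05}, "non_increasing"),
            ("sd", {"sd": 0.5}, {"sd": 1.0}, "non_decreasing"),
            ("power", {"power": 0.8}, {"power": 0.95}, "non_decreasing"),
            ("dropout", {"dropout": 0.0}, {"dropout": 0.4}, "non_decreasing"),
        ],
    )
    def test_monotonicity(self, field, lo_kwargs, hi_kwargs, direction):
        lo = required_sample_size(SampleSizeSpec(**lo_kwargs)).enrolled
        hi = required_sample_size(SampleSizeSpec(**hi_kwargs)).enrolled
        if direction == "non_increasing":
            assert lo >= hi
        else:
            assert lo <= hi

    def test_zero_delta_rejected(self):
        with pytest.raises(InputError, match="delta"):
            SampleSizeSpec(delta=0.0)


def _fixture_cohort(n_enrolled=27, n_completers=18, shift=0.0, seed=0, n_female=None):
    rng = np.random.default_rng(seed)
    if n_female is None:
        n_female = min(17, n_enrolled)
    ids = [f"P{i:03d}" for i in range(n_enrolled)]
    base = pd.DataFrame(
        {
            "id": ids,
            "sex": ["female"] * n_female + ["male"] * (n_enrolled - n_female),
            "diet_score": rng.integers(4, 11, n_enrolled),
            "sleep_hours": rng.normal(6.5, 1.0, n_enrolled).round(1),
            "stress": rng.integers(5, 28, n_enrolled),
        }
    )
    fu = base.iloc[:n_completers].copy()
    fu["diet_score"] = fu["diet_score"] + shift
    return PairedCohort(baseline=base, followup=fu)


class TestSummariesAndEvaluation:
    @pytest.mark.parametrize("k, n, expected", [(10, 16, 63), (12, 16, 75), (9, 16, 56), (11, 16, 69)])
    def test_percent_rounds_half_up(self, k, n, expected):
        assert percent(k, n) == expected

    def test_summary_counts_and_percentages(self):
        cohort = _fixture_cohort(16, 10, n_female=10)
        s = summarize_cohort(cohort)
        # 10 of 16 females at baseline -> 63%
        assert s["baseline"]["categorical"]["female_sex"] == {"count": 10, "total": 16, "percent": 63}
        assert s["baseline"]["n"] == 16 and s["followup"]["n"] == 10

    def test_empty_cohort_summary(self):
        cohort = PairedCohort(baseline=pd.DataFrame(), followup=pd.DataFrame())
        s = summarize_cohort(cohort)
        assert s["baseline"] == {"n": 0, "variables": {}, "categorical": {}}

    def test_summary_reports_iqr_and_range_separately(self):
        s = summarize_cohort(_fixture_cohort())
        v = s["baseline"]["variables"]["sleep_hours"]
        assert {"iqr", "range", "median", "mean", "sd"} <= set(v)
        assert v["range"][0] <= v["iqr"][0] <= v["median"] <= v["iqr"][1] <= v["range"][1]

    def test_completion_counts_27_18(self):
        report = evaluate_pre_post(_fixture_cohort(27, 18))
        assert report.n_enrolled == 27 and report.n_completers == 18

    def test_identical_pre_post_all_nonsignificant(self):
        report = evaluate_pre_post(_fixture_cohort(shift=0.0))
        assert report.tests  # at least diet/stress/sleep were testable
        assert not any(t.significant for t in report.tests.values())

    def test_no_followups_no_tests(self):
        report = evaluate_pre_post(_fixture_cohort(27, 0))
        assert report.n_completers == 0 and report.tests == {}

    def test_variable_test_assignment(self):
        report = evaluate_pre_post(_fixture_cohort(shift=2.0))
        assert report.tests["diet_score"].test == "paired_t"
        assert report.tests["stress"].test == "wilcoxon"
        assert report.tests["diet_score"].significant

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame({"id": ["a", "a"], "diet_score": [5, 6]})
        with pytest.raises(InputError, match="duplicate"):
            PairedCohort(baseline=df, followup=pd.DataFrame())
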