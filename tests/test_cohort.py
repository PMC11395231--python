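"""Longitudinal analysis: exact Mann-Whitney against a brute-force oracle,
course classification, phase labeling and cohort summaries."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import rankdata

from hybridscope.cohort import (
    SubjectTimeline,
    classify_course,
    compare_baseline,
    label_chc_phases,
    mann_whitney,
    summarize_cohort,
)
from hybridscope.errors import DataError
from hybridscope.gate import SampleEnumeration
from hybridscope.simgen import CohortConfig, generate_cohort


def brute_force_mw_p(x, y):
    """Exact two-sided p by enumerating all group assignments of the
    pooled mid-ranks (feasible only for tiny samples)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = rankdata(pooled)
    r_obs = ranks[:n1].sum()
    lower = upper = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        rs = ranks[list(combo)].sum()
        total += 1
        lower += rs <= r_obs + 1e-9
        upper += rs >= r_obs - 1e-9
    return min(1.0, 2 * min(lower / total, upper / total))


def make_timeline(subject_id, counts, days=None, cohort="patient",
                  trial_end=None, pbmcs=50_000):
    """Timeline from per-50k counts (assumes integer-compatible raw counts)."""
    days = days if days is not None else [28.0 * i for i in range(len(counts))]
    samples = []
    for i, (day, c) in enumerate(zip(days, counts)):
        raw = int(round(c * pbmcs / 50_000))
        samples.append(
            SampleEnumeration(
                sample_id=f"{subject_id}-{i}",
                subject_id=subject_id,
                days_from_treatment_start=day,
                raw_counts={"CHC": raw, "CTC": 0, "leukocyte": pbmcs - raw, "negative": 0},
                total_pbmcs=pbmcs,
            )
        )
    return SubjectTimeline(
        subject_id=subject_id, cohort=cohort, samples=samples,
        treatment_start=0.0, trial_end=trial_end,
    )


class TestMannWhitney:
    def test_single_tied_pair(self):
        res = mann_whitney([1.0], [1.0])
        assert res.p_two_sided == 1.0 and res.method == "exact"

    def test_complete_separation_closed_form(self):
        x = [10, 11, 12, 13, 14]
        y = list(range(15))
        res = mann_whitney([v + 100 for v in x], y)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(2 / math.comb(20, 5))
        assert res.U == 75  # n1*n2, every x beats every y

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(1, 7), rng.integers(1, 7)
            x = rng.integers(0, 6, n1).astype(float)
            y = rng.integers(0, 6, n2).astype(float)
            assert mann_whitney(x, y).p_two_sided == pytest.approx(
                brute_force_mw_p(x, y), abs=1e-12
            )

    def test_matches_scipy_exact_without_ties(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(10):
            x = rng.normal(size=8)
            y = rng.normal(size=9)
            ours = mann_whitney(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)
            assert ours.U == pytest.approx(ref.statistic)

    def test_group_swap_symmetry(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=9)
        assert mann_whitney(x, y).p_two_sided == pytest.approx(
            mann_whitney(y, x).p_two_sided
        )

    def test_large_samples_use_normal_approx(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        res = mann_whitney(x, y)
        assert res.method == "normal_approx"
        assert 0 < res.p_two_sided <= 1

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            mann_whitney([], [1.0])


class TestCompareBaseline:
    def test_identical_groups_p_one(self):
        pats = [make_timeline(f"p{i}", [5, 0, 0], trial_end=56.0) for i in range(3)]
        heal = [make_timeline(f"h{i}", [5], cohort="healthy") for i in range(3)]
        assert compare_baseline(pats, heal).p_two_sided == 1.0

    def test_separated_cohort_closed_form(self):
        cfg = CohortConfig(n_patients=5, n_healthy=15, healthy_zero_prob=1.0, seed=3)
        timelines = generate_cohort(cfg)
        pats = [t for t in timelines if t.cohort == "patient"]
        heal = [t for t in timelines if t.cohort == "healthy"]
        res = compare_baseline(pats, heal)
        assert res.p_two_sided == pytest.approx(2 / math.comb(20, 5))


class TestClassifyCourse:
    def test_sustained_undetectable_pattern(self):
        t = make_timeline("p", [13, 0, 0, 0], trial_end=84.0)
        c = classify_course(t)
        assert (c.nadir_status, c.end_of_trial_status, c.post_trial_status) == (
            "undetectable", "undetectable", "not_available",
        )
        assert c.interval_increase is None

    def test_on_trial_rebound(self):
        t = make_timeline("p", [9, 0, 0, 6], trial_end=84.0)
        c = classify_course(t)
        assert c.nadir_status == "undetectable"
        assert c.end_of_trial_status == "increased"
        assert c.interval_increase == pytest.approx(6.0)
        assert c.time_of_first_rebound == 84.0

    def test_post_trial_rebound(self):
        t = make_timeline("p", [8, 0, 0, 0, 49.6], trial_end=56.0, pbmcs=100_000)
        c = classify_course(t)
        assert c.end_of_trial_status == "undetectable"
        assert c.post_trial_status == "increased"
        assert c.interval_increase == pytest.approx(49.5)  # integer raw at 100k PBMCs

    def test_healthy_timeline_rejected(self):
        t = make_timeline("h", [0, 0], cohort="healthy")
        with pytest.raises(DataError):
            classify_course(t)

    def test_zero_extension_idempotent(self):
        base = [11, 0, 0]
        t1 = make_timeline("p", base, trial_end=200.0)
        t2 = make_timeline("p", base + [0, 0], trial_end=200.0)
        c1, c2 = classify_course(t1), classify_course(t2)
        assert (c1.nadir_status, c1.end_of_trial_status) == (
            c2.nadir_status, c2.end_of_trial_status,
        )

    def test_regime_recovery_on_synthetic_cohort(self):
        cfg = CohortConfig(n_patients=40, n_healthy=0, seed=21)
        expected = {
            "sustained_response": ("undetectable", "undetectable"),
            "long_term_stable": ("undetectable", "undetectable"),
            "on_trial_resistance": ("undetectable", "increased"),
            "post_trial_progression": ("undetectable", "undetectable"),
        }
        for t in generate_cohort(cfg):
            c = classify_course(t)
            assert (c.nadir_status, c.end_of_trial_status) == expected[t.regime]


class TestPhaseLabels:
    def test_literal_definition(self):
        t = make_timeline("p", [12, 4, 0, 0, 7], trial_end=300.0)
        assert label_chc_phases(t) == [
            "responsive", "responsive", "none", "none", "resistant",
        ]

    def test_minimal_case(self):
        t = make_timeline("p", [10, 0], trial_end=300.0)
        assert label_chc_phases(t) == ["responsive", "none"]

    def test_all_zero(self):
        t = make_timeline("p", [0, 0, 0], trial_end=300.0)
        assert label_chc_phases(t) == ["none", "none", "none"]

    def test_partition_property(self, rng):
        """Every positive sample gets exactly one phase; resistant never
        precedes the first zero."""
        for _ in range(20):
            counts = rng.integers(0, 5, size=8).tolist()
            t = make_timeline("p", counts, trial_end=300.0)
            phases = label_chc_phases(t)
            first_zero = counts.index(0) if 0 in counts else len(counts)
            for i, (c, ph) in enumerate(zip(counts, phases)):
                if c == 0:
                    assert ph == "none"
                else:
                    assert ph in ("responsive", "resistant")
                    assert (ph == "resistant") == (i > first_zero)


class TestSummarizeCohort:
    def test_interval_increase_summary(self):
        tls = [
            make_timeline("p1", [10, 0, 0, 2], trial_end=300.0),
            make_timeline("p2", [12, 0, 0, 7.6], trial_end=300.0, pbmcs=125_000),
            make_timeline("p3", [14, 0, 0, 49.6], trial_end=300.0, pbmcs=100_000),
        ]
        s = summarize_cohort(tls)
        assert s["interval_increase"]["median"] == pytest.approx(7.6)
        assert s["interval_increase"]["min"] == pytest.approx(2.0)
        assert s["interval_increase"]["max"] == pytest.approx(49.5)

    def test_single_subject_degenerate_range(self):
        (s,) = [summarize_cohort([make_timeline("p", [9, 0, 0], trial_end=300.0)])]
        assert s["baseline_chc"]["median"] == s["baseline_chc"]["min"]
        assert s["baseline_chc"]["min"] == s["baseline_chc"]["max"]

    def test_median_between_min_and_max(self, rng):
        tls = [
            make_timeline(f"p{i}", [int(rng.integers(5, 20)), 0, 0], trial_end=300.0)
            for i in range(12)
        ]
        s = summarize_cohort(tls)["baseline_chc"]
        assert s["min"] <= s["median"] <= s["max"]

    def test_empty_cohort_rejected(self):
        with pytest.raises(DataError):
            summarize_cohort([])
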