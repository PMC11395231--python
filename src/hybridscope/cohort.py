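"""Longitudinal analysis of hybrid-cell counts.

Covers the clinical questions the enumeration feeds: are baseline patient
counts higher than healthy-subject counts (Mann-Whitney U, exact for small
samples), how does each patient's trajectory classify (nadir after
treatment initiation, end-of-trial status, post-trial surveillance), when
does a rebound occur and by how much, and which detections belong to the
treatment-responsive versus treatment-resistant phase.

The Mann-Whitney test is implemented here rather than delegated so the
exact small-sample branch is a first-class, testable artifact.  The exact
two-sided p-value is obtained from the full null distribution of the
rank-sum statistic (mid-ranks for ties), computed by subset-sum dynamic
programming over the doubled mid-ranks — identical to enumerating all
C(n1+n2, n1) group assignments, in polynomial time.  For larger samples a
normal approximation with tie and continuity corrections is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DataError
from .gate import SampleEnumeration

#: exact enumeration is used whenever n1*n2 is at or below this product
EXACT_CUTOFF = 400

REGIMES = (
    "sustained_response",
    "on_trial_resistance",
    "post_trial_progression",
    "long_term_stable",
)


@dataclass
class SubjectTimeline:
    """Time-ordered enumerations plus treatment landmarks for one subject."""

    subject_id: str
    cohort: str  # "patient" | "healthy"
    samples: list[SampleEnumeration]
    treatment_start: float = 0.0
    trial_end: float | None = None
    regime: str | None = None  # generating regime, when synthetic

    def __post_init__(self) -> None:
        if self.cohort not in ("patient", "healthy"):
            raise DataError(f"unknown cohort {self.cohort!r}")
        days = [s.days_from_treatment_start for s in self.samples]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise DataError(f"sample times must strictly increase ({self.subject_id})")

    def chc_series(self) -> np.ndarray:
        return np.array([s.chc_per_50k for s in self.samples], dtype=float)


@dataclass
class CourseSummary:
    """Per-patient disease-course classification (nadir / end of trial / post-trial)."""

    subject_id: str
    nadir_status: str  # undetectable | detectable
    end_of_trial_status: str  # undetectable | increased
    post_trial_status: str  # undetectable | increased | not_available
    interval_increase: float | None = None
    time_of_first_rebound: float | None = None


@dataclass
class MWResult:
    U: float
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    n1: int = 0
    n2: int = 0


def _exact_rank_sum_tail(
    doubled_ranks: np.ndarray, n1: int, doubled_r1: int
) -> tuple[float, float]:
    """P(R1 <= r_obs) and P(R1 >= r_obs) under the permutation null.

    ``doubled_ranks`` are the mid-ranks of the pooled sample times two
    (integers even with ties).  dp[k][s] counts size-k subsets of the pool
    with doubled rank-sum s; the null distribution of the group-1 rank sum
    is dp[n1] / C(N, n1).
    """
    total = int(doubled_ranks.sum())
    dp = np.zeros((n1 + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for w in doubled_ranks:
        w = int(w)
        # k descends so each pooled observation enters a subset at most once
        for k in range(n1, 0, -1):
            dp[k, w:] += dp[k - 1, : total + 1 - w]
    counts = dp[n1]
    n_total = counts.sum()
    lower = counts[: doubled_r1 + 1].sum() / n_total
    upper = counts[doubled_r1:].sum() / n_total
    return float(lower), float(upper)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MWResult:
    """Two-sided Mann-Whitney U test of x versus y.

    Exact when ``n1 * n2 <= EXACT_CUTOFF`` (full null enumeration via
    dynamic programming, mid-rank ties included); otherwise a normal
    approximation with continuity and tie corrections.  The two-sided
    p-value is twice the smaller tail mass, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("mann_whitney requires nonempty samples")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # mid-ranks
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if n1 * n2 <= EXACT_CUTOFF:
        doubled = np.rint(2 * ranks).astype(np.int64)
        lower, upper = _exact_rank_sum_tail(doubled, n1, int(round(2 * r1)))
        p = min(1.0, 2.0 * min(lower, upper))
        return MWResult(U=float(u1), p_two_sided=p, method="exact", n1=n1, n2=n2)

    mean = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return MWResult(U=float(u1), p_two_sided=1.0, method="normal_approx", n1=n1, n2=n2)
    # continuity correction pulls u1 toward the mean
    z = (u1 - mean - 0.5 * np.sign(u1 - mean)) / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return MWResult(U=float(u1), p_two_sided=float(p), method="normal_approx", n1=n1, n2=n2)


def baseline_count(timeline: SubjectTimeline) -> float:
    """Baseline normalized CHC count for one subject.

    Patients: last sample at or before treatment start.  Healthy subjects:
    first sample.
    """
    if timeline.cohort == "healthy":
        if not timeline.samples:
            raise DataError(f"no samples for healthy subject {timeline.subject_id}")
        return timeline.samples[0].chc_per_50k
    pre = [
        s
        for s in timeline.samples
        if s.days_from_treatment_start <= timeline.treatment_start
    ]
    if not pre:
        raise DataError(f"no baseline sample for subject {timeline.subject_id}")
    return pre[-1].chc_per_50k


def compare_baseline(
    patients: Sequence[SubjectTimeline], healthy: Sequence[SubjectTimeline]
) -> MWResult:
    """Mann-Whitney comparison of baseline CHC counts, patients vs healthy."""
    x = [baseline_count(t) for t in patients]
    y = [baseline_count(t) for t in healthy]
    return mann_whitney(x, y)


def classify_course(timeline: SubjectTimeline) -> CourseSummary:
    """Classify one patient trajectory into nadir / end-of-trial / post-trial statuses.

    * nadir undetectable iff some on-trial post-treatment sample has zero
      normalized CHC count;
    * end-of-trial increased iff the last on-trial sample is positive,
      undetectable if it is zero;
    * post-trial evaluated on samples after trial end (``not_available``
      when none exist);
    * the interval increase is the first positive count after the first
      zero, with its sample time recorded as the rebound time.
    """
    if timeline.cohort != "patient":
        raise DataError("classify_course expects a patient timeline")
    if timeline.trial_end is None:
        raise DataError(f"trial_end not set for subject {timeline.subject_id}")

    on_trial = [
        s
        for s in timeline.samples
        if timeline.treatment_start < s.days_from_treatment_start <= timeline.trial_end
    ]
    post_trial = [
        s for s in timeline.samples if s.days_from_treatment_start > timeline.trial_end
    ]
    if not on_trial:
        raise DataError(f"no on-trial post-treatment samples for {timeline.subject_id}")

    nadir_status = (
        "undetectable" if any(s.chc_per_50k == 0 for s in on_trial) else "detectable"
    )
    end_of_trial_status = "increased" if on_trial[-1].chc_per_50k > 0 else "undetectable"
    if not post_trial:
        post_trial_status = "not_available"
    elif any(s.chc_per_50k > 0 for s in post_trial):
        post_trial_status = "increased"
    else:
        post_trial_status = "undetectable"

    interval_increase = None
    time_of_first_rebound = None
    after_treatment = on_trial + post_trial
    seen_zero = False
    for s in after_treatment:
        if s.chc_per_50k == 0:
            seen_zero = True
        elif seen_zero:
            interval_increase = s.chc_per_50k
            time_of_first_rebound = s.days_from_treatment_start
            break

    return CourseSummary(
        subject_id=timeline.subject_id,
        nadir_status=nadir_status,
        end_of_trial_status=end_of_trial_status,
        post_trial_status=post_trial_status,
        interval_increase=interval_increase,
        time_of_first_rebound=time_of_first_rebound,
    )


def label_chc_phases(timeline: SubjectTimeline) -> list[str]:
    """Phase label per sample: responsive / resistant / none.

    Detections from treatment onset until counts first reach zero are
    treatment-responsive; detections recurring after any zero-count sample
    are treatment-resistant; zero-count (and strictly pre-treatment)
    samples carry no phase.  Labels propagate to every hybrid-cell crop
    taken from that sample.
    """
    if timeline.cohort != "patient":
        raise DataError("label_chc_phases expects a patient timeline")
    post = [
        s
        for s in timeline.samples
        if s.days_from_treatment_start >= timeline.treatment_start
    ]
    if not post:
        raise DataError(f"no post-treatment samples for {timeline.subject_id}")

    phases = []
    seen_zero = False
    for s in timeline.samples:
        if s.days_from_treatment_start < timeline.treatment_start:
            phases.append("none")
            continue
        if s.chc_per_50k == 0:
            seen_zero = True
            phases.append("none")
        elif seen_zero:
            phases.append("resistant")
        else:
            phases.append("responsive")
    return phases


def summarize_cohort(timelines: Sequence[SubjectTimeline]) -> dict:
    """Descriptive cohort summary: medians with ranges, course-category counts."""
    if not timelines:
        raise DataError("empty cohort")
    patients = [t for t in timelines if t.cohort == "patient"]
    healthy = [t for t in timelines if t.cohort == "healthy"]

    def med_range(values: Sequence[float]) -> dict:
        arr = np.asarray(values, dtype=float)
        return {
            "median": float(np.median(arr)),
            "min": float(arr.min()),
            "max": float(arr.max()),
            "n": int(arr.size),
        }

    summary: dict = {
        "n_patients": len(patients),
        "n_healthy": len(healthy),
        "samples_per_subject": med_range([len(t.samples) for t in timelines]),
    }
    if patients:
        summary["baseline_chc"] = med_range([baseline_count(t) for t in patients])
        courses = [classify_course(t) for t in patients if t.trial_end is not None]
        increases = [c.interval_increase for c in courses if c.interval_increase is not None]
        if increases:
            summary["interval_increase"] = med_range(increases)
        summary["course_counts"] = {
            "nadir_undetectable": sum(c.nadir_status == "undetectable" for c in courses),
            "end_of_trial_increased": sum(
                c.end_of_trial_status == "increased" for c in courses
            ),
            "post_trial_increased": sum(
                c.post_trial_status == "increased" for c in courses
            ),
            "post_trial_not_available": sum(
                c.post_trial_status == "not_available" for c in courses
            ),
        }
    if healthy:
        summary["healthy_baseline_chc"] = med_range([baseline_count(t) for t in healthy])
    return summary
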