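"""Per-patient trajectories, cohort detection rates, and group statistics.

Detection-rate denominators count only patients actually assayed at a
timepoint — cfDNA dropouts and purity-excluded patients simply leave a
"not assayed" hole in the trajectory, which is why mutation and methylation
rates at the same timepoint can have different denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom, mannwhitneyu, spearmanr

from .cohort_io import ClinicalRecord, SampleRecord, ValidationError, timepoint_rank
from .mrd_model import MRDCall
from .mutation_tracking import PlasmaMutationProfile

DAYS_PER_MONTH = 30.4375  # 365.25 / 12

MUTATION = "mutation"
METHYLATION = "methylation"


@dataclass
class Timepoint:
    """One plasma draw; a None assay slot means "not assayed" there."""

    label: str
    days_from_surgery: int
    mrd_call: Optional[MRDCall] = None
    mutation_profile: Optional[PlasmaMutationProfile] = None


@dataclass
class PatientTrajectory:
    patient_id: str
    clinical: ClinicalRecord
    timepoints: list[Timepoint] = field(default_factory=list)

    def timepoint(self, label: str) -> Optional[Timepoint]:
        for tp in self.timepoints:
            if tp.label == label:
                return tp
        return None


@dataclass(frozen=True)
class TimepointSummary:
    timepoint_label: str
    assay: str
    n_positive: int
    n_assayed: int

    def __post_init__(self) -> None:
        if self.n_positive > self.n_assayed:
            raise ValidationError("n_positive cannot exceed n_assayed")

    @property
    def rate(self) -> float:
        """Detection rate as a percentage."""
        return 100.0 * self.n_positive / self.n_assayed


@dataclass(frozen=True)
class RateComparison:
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    test_name: str = "fisher_exact"


def assemble_trajectories(
    samples: Sequence[SampleRecord],
    clinical: Sequence[ClinicalRecord],
    mrd_calls: Mapping[str, MRDCall] = {},
    mutation_profiles: Mapping[str, PlasmaMutationProfile] = {},
) -> list[PatientTrajectory]:
    """Build one ordered trajectory per patient with plasma samples.

    Assay results are attached by sample_id; a plasma sample with neither
    result still appears as a fully "not assayed" timepoint.
    """
    by_patient: dict[str, ClinicalRecord] = {c.patient_id: c for c in clinical}
    grouped: dict[str, list[SampleRecord]] = {}
    for s in samples:
        if s.material != "plasma":
            continue
        if s.patient_id not in by_patient:
            raise ValidationError(f"sample {s.sample_id}: patient {s.patient_id} not in clinical table")
        grouped.setdefault(s.patient_id, []).append(s)

    trajectories: list[PatientTrajectory] = []
    for pid in grouped:
        recs = sorted(grouped[pid], key=lambda r: timepoint_rank(r.timepoint_label))
        labels = [r.timepoint_label for r in recs]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"patient {pid}: duplicate timepoint label")
        days = [r.days_from_surgery for r in recs]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError(f"patient {pid}: timepoint days out of order")
        trajectories.append(
            PatientTrajectory(
                patient_id=pid,
                clinical=by_patient[pid],
                timepoints=[
                    Timepoint(
                        label=r.timepoint_label,
                        days_from_surgery=r.days_from_surgery,
                        mrd_call=mrd_calls.get(r.sample_id),
                        mutation_profile=mutation_profiles.get(r.sample_id),
                    )
                    for r in recs
                ],
            )
        )
    return trajectories


def detection_rate_table(
    trajectories: Sequence[PatientTrajectory], assay: str, timepoint_label: str
) -> TimepointSummary:
    """Positive/assayed counts for one assay at one timepoint."""
    if assay not in (MUTATION, METHYLATION):
        raise ValidationError(f"assay must be '{MUTATION}' or '{METHYLATION}', got {assay!r}")
    n_pos = n_assayed = 0
    for traj in trajectories:
        tp = traj.timepoint(timepoint_label)
        if tp is None:
            continue
        if assay == MUTATION:
            if tp.mutation_profile is None:
                continue
            n_assayed += 1
            n_pos += tp.mutation_profile.detected
        else:
            if tp.mrd_call is None:
                continue
            n_assayed += 1
            n_pos += tp.mrd_call.positive
    if n_assayed == 0:
        raise ValidationError(f"no patient assayed for {assay} at {timepoint_label}")
    return TimepointSummary(
        timepoint_label=timepoint_label, assay=assay, n_positive=n_pos, n_assayed=n_assayed
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's (with a
    1e-7 relative tolerance for floating-point ties).  A zero margin gives
    p = 1 by convention.
    """
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValidationError(f"cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if min(row1, col1, n - row1, n - col1) == 0 or n == 0:
        return 1.0
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def compare_detection_rates(a: TimepointSummary, b: TimepointSummary) -> RateComparison:
    """Fisher exact comparison of two timepoints' positive/negative counts."""
    table = (
        (a.n_positive, a.n_assayed - a.n_positive),
        (b.n_positive, b.n_assayed - b.n_positive),
    )
    return RateComparison(table=table, p_value=fisher_exact_2x2(table))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the smaller group has <= 10 observations and
    there are no ties; otherwise the normal approximation with tie
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0  # every ranking identical; no evidence either way
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=False)
    return float(res.pvalue)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def correlate_maxaf_md(pairs: Sequence[tuple[float, float]]) -> CorrelationResult:
    """Spearman rank correlation between maxAF and MD ratio across samples.

    ``pairs`` holds (max_af, alpha_hat) for samples where both assays
    produced a value; undetected-mutation samples are excluded upstream.
    """
    if len(pairs) < 3:
        raise ValidationError("correlation needs at least 3 complete pairs")
    arr = np.asarray(pairs, dtype=float)
    rho, p = spearmanr(arr[:, 0], arr[:, 1])
    return CorrelationResult(rho=float(rho), p_value=float(p), n=len(pairs))


def paired_maxaf_md(trajectories: Sequence[PatientTrajectory]) -> tuple[list[tuple[float, float]], int]:
    """Collect (max_af, alpha_hat) pairs across all assayed timepoints.

    Returns the pairs plus the count of timepoints excluded because the
    mutation assay detected nothing (maxAF absent by design).
    """
    pairs: list[tuple[float, float]] = []
    excluded = 0
    for traj in trajectories:
        for tp in traj.timepoints:
            if tp.mutation_profile is None or tp.mrd_call is None:
                continue
            if not tp.mutation_profile.detected:
                excluded += 1
                continue
            pairs.append((tp.mutation_profile.max_af, tp.mrd_call.estimate.alpha_hat))
    return pairs, excluded


def recurrence_lead_time(trajectory: PatientTrajectory, mode: str = "positive") -> Optional[float]:
    """Months between the earliest post-op MRD signal and radiologic recurrence.

    ``mode='positive'`` (default) anchors on the earliest postoperative
    Wald-positive methylation call at or before the recurrence day;
    ``mode='increase'`` instead requires the score to exceed the previous
    assayed timepoint's.  Returns None when no qualifying call precedes
    recurrence; months use the 30.4375-day calendar average, reported to
    0.1 month.
    """
    rec_day = trajectory.clinical.recurrence_day
    if rec_day is None:
        raise ValidationError(f"patient {trajectory.patient_id}: no recurrence recorded")
    if rec_day <= 0:
        raise ValidationError(f"patient {trajectory.patient_id}: recurrence before surgery")

    prev_wald: Optional[float] = None
    signal_day: Optional[int] = None
    for tp in trajectory.timepoints:
        if tp.mrd_call is None:
            continue
        wald = tp.mrd_call.estimate.wald
        if tp.days_from_surgery > 0 and tp.days_from_surgery <= rec_day and signal_day is None:
            if mode == "positive":
                if tp.mrd_call.positive:
                    signal_day = tp.days_from_surgery
            elif mode == "increase":
                if prev_wald is not None and wald > prev_wald:
                    signal_day = tp.days_from_surgery
            else:
                raise ValidationError(f"unknown mode {mode!r}")
        prev_wald = wald
    if signal_day is None:
        return None
    return round((rec_day - signal_day) / DAYS_PER_MONTH, 1)
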