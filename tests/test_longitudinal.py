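"""Trajectory assembly, detection-rate tables, exact tests, lead times."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from mrdseq.cohort_io import ClinicalRecord, MutationCall, SampleRecord, ValidationError
from mrdseq.longitudinal import (
    METHYLATION,
    MUTATION,
    PatientTrajectory,
    Timepoint,
    assemble_trajectories,
    compare_detection_rates,
    correlate_maxaf_md,
    detection_rate_table,
    fisher_exact_2x2,
    paired_maxaf_md,
    recurrence_lead_time,
    wilcoxon_rank_sum,
)
from mrdseq.mrd_model import MDEstimate, MRDCall
from mrdseq.mutation_tracking import summarize_plasma


def mrd_call(sid, wald):
    est = MDEstimate(alpha_hat=wald / 100, variance=1.0, wald=wald, loglik_at_max=0.0, n_blocks_used=5, n_reads_used=500)
    return MRDCall(sid, est, positive=wald > 1.96)


def mut_profile(sid, detected, af=0.02):
    calls = [MutationCall(sid, "EGFR", "chr7", 55191822, "T", "G", af, 10000, True)] if detected else []
    return summarize_plasma(sid, calls)


CLIN = [ClinicalRecord("P1", "LUAD", "IA", 0.6), ClinicalRecord("P2", "LUSC", "IIB", 0.7)]


class TestAssemble:
    def samples(self):
        return [
            SampleRecord("P1_T0", "P1", "plasma", "baseline", -7),
            SampleRecord("P1_T1", "P1", "plasma", "followup_1", 90),
            SampleRecord("P1_T2", "P1", "plasma", "followup_2", 180),
        ]

    def test_missing_assay_leaves_not_assayed_marker(self):
        calls = {"P1_T0": mrd_call("P1_T0", 5.0), "P1_T2": mrd_call("P1_T2", 0.5)}
        (traj,) = assemble_trajectories(self.samples(), CLIN, calls, {})
        assert [tp.mrd_call is None for tp in traj.timepoints] == [False, True, False]
        assert all(tp.mutation_profile is None for tp in traj.timepoints)

    def test_empty_cohort(self):
        assert assemble_trajectories([], CLIN) == []

    def test_duplicate_timepoint_label_rejected(self):
        samples = self.samples() + [SampleRecord("P1_T1b", "P1", "plasma", "followup_1", 120)]
        with pytest.raises(ValidationError, match="duplicate timepoint"):
            assemble_trajectories(samples, CLIN)

    def test_days_out_of_order_rejected(self):
        samples = [
            SampleRecord("P1_T0", "P1", "plasma", "baseline", -7),
            SampleRecord("P1_T1", "P1", "plasma", "followup_1", 200),
            SampleRecord("P1_T2", "P1", "plasma", "followup_2", 100),
        ]
        with pytest.raises(ValidationError, match="out of order"):
            assemble_trajectories(samples, CLIN)

    def test_tissue_samples_ignored(self):
        samples = self.samples() + [SampleRecord("P1_TT", "P1", "tumor_tissue", "baseline", -7)]
        (traj,) = assemble_trajectories(samples, CLIN)
        assert len(traj.timepoints) == 3


class TestDetectionRates:
    def build(self, n_pos, n_assayed, assay=MUTATION, label="followup_1"):
        trajectories = []
        for i in range(n_assayed):
            pid = f"Q{i}"
            sid = f"{pid}_{label}"
            tp = Timepoint(label=label, days_from_surgery=90)
            if assay == MUTATION:
                tp.mutation_profile = mut_profile(sid, i < n_pos)
            else:
                tp.mrd_call = mrd_call(sid, 5.0 if i < n_pos else 0.0)
            trajectories.append(
                PatientTrajectory(pid, ClinicalRecord(pid, "LUAD", "IA", 0.6), [tp])
            )
        return trajectories

    def test_fourteen_of_sixtyone_rounds_to_23_percent(self):
        summary = detection_rate_table(self.build(14, 61), MUTATION, "followup_1")
        assert (summary.n_positive, summary.n_assayed) == (14, 61)
        assert round(summary.rate) == 23

    @pytest.mark.parametrize("n_pos,n_assayed,rate", [(0, 10, 0.0), (7, 7, 100.0)])
    def test_boundary_rates(self, n_pos, n_assayed, rate):
        assert detection_rate_table(self.build(n_pos, n_assayed), MUTATION, "followup_1").rate == rate

    def test_zero_assayed_is_an_error(self):
        with pytest.raises(ValidationError, match="no patient assayed"):
            detection_rate_table(self.build(2, 5), METHYLATION, "followup_1")

    def test_counts_stable_under_patient_shuffle(self):
        trajectories = self.build(5, 12, METHYLATION)
        a = detection_rate_table(trajectories, METHYLATION, "followup_1")
        b = detection_rate_table(list(reversed(trajectories)), METHYLATION, "followup_1")
        assert (a.n_positive, a.n_assayed) == (b.n_positive, b.n_assayed)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by explicit enumeration with binomial coefficients."""
    n, r, k = a + b + c + d, a + b, a + c
    if min(r, k, n - r, n - k) == 0:
        return 1.0

    def prob(x):
        return math.comb(r, x) * math.comb(n - r, k - x) / math.comb(n, k)

    p_obs = prob(a)
    return sum(p for x in range(max(0, r + k - n), min(r, k) + 1) if (p := prob(x)) <= p_obs * (1 + 1e-7))


class TestFisherExact:
    def test_identical_rates_give_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_fully_crossed_table(self):
        assert fisher_exact_2x2([[0, 5], [5, 0]]) == pytest.approx(2 / 252)

    def test_zero_margin_convention(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_matches_enumeration_and_scipy_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 13, size=4))
            p = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)
            assert p == pytest.approx(scipy_fisher([[a, b], [c, d]]).pvalue, abs=1e-7)

    def test_rate_comparison_wires_counts_into_table(self):
        a = detection_rate_table(
            TestDetectionRates().build(26, 35, METHYLATION), METHYLATION, "followup_1"
        )
        b = detection_rate_table(
            TestDetectionRates().build(7, 7, METHYLATION), METHYLATION, "followup_1"
        )
        cmp = compare_detection_rates(a, b)
        assert cmp.table == ((26, 9), (7, 0))
        assert 0 < cmp.p_value <= 1


def rank_sum_oracle(x, y):
    """Exact two-sided p by enumerating every assignment of ranks to group x."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # no ties by construction
    observed = sum(ranks[v] for v in x)
    n = len(x)
    sums = [sum(c) for c in combinations(range(1, len(pooled) + 1), n)]
    mean = np.mean(sums)
    extreme = sum(1 for s in sums if abs(s - mean) >= abs(observed - mean) - 1e-12)
    return extreme / len(sums)


class TestWilcoxon:
    def test_small_disjoint_groups(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(2 / 6)

    def test_identical_multisets_give_p_one(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_exact_matches_enumeration_at_n4_m4(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            vals = rng.permutation(np.arange(1.0, 9.0))
            x, y = list(vals[:4]), list(vals[4:])
            assert wilcoxon_rank_sum(x, y) == pytest.approx(rank_sum_oracle(x, y), abs=1e-12)

    def test_ties_fall_back_to_normal_approximation(self):
        p = wilcoxon_rank_sum([1, 1, 2, 2, 5], [1, 2, 2, 3, 3])
        assert 0 < p <= 1


class TestCorrelation:
    def test_monotone_pairs(self):
        pairs = [(0.01 * i, 0.002 * i) for i in range(1, 7)]
        assert correlate_maxaf_md(pairs).rho == pytest.approx(1.0)
        reversed_pairs = [(0.01 * i, -0.002 * i) for i in range(1, 7)]
        assert correlate_maxaf_md(reversed_pairs).rho == pytest.approx(-1.0)

    def test_fixed_pairs_match_rank_difference_formula(self):
        x = [0.02, 0.001, 0.015, 0.04, 0.008, 0.03]
        y = [0.01, 0.002, 0.02, 0.05, 0.001, 0.025]
        rx = np.argsort(np.argsort(x)) + 1
        ry = np.argsort(np.argsort(y)) + 1
        d2 = float(np.sum((rx - ry) ** 2))
        expected = 1 - 6 * d2 / (6 * 35)
        assert correlate_maxaf_md(list(zip(x, y))).rho == pytest.approx(expected)

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(ValidationError, match="at least 3"):
            correlate_maxaf_md([(0.1, 0.2), (0.2, 0.3)])

    def test_paired_extraction_skips_and_counts_undetected(self):
        tps = [
            Timepoint("baseline", -7, mrd_call("a", 3.0), mut_profile("a", True)),
            Timepoint("followup_1", 90, mrd_call("b", 0.5), mut_profile("b", False)),
            Timepoint("followup_2", 180, None, mut_profile("c", True)),
        ]
        traj = PatientTrajectory("P1", ClinicalRecord("P1", "LUAD", "IA", 0.6), tps)
        pairs, excluded = paired_maxaf_md([traj])
        assert len(pairs) == 1 and excluded == 1


class TestLeadTime:
    def traj(self, rec_day, waldmap):
        tps = []
        for label, day, wald in waldmap:
            call = None if wald is None else mrd_call(f"S_{label}", wald)
            tps.append(Timepoint(label, day, call, None))
        clin = ClinicalRecord("P1", "LUAD", "IA", 0.6, recurrence_day=rec_day)
        return PatientTrajectory("P1", clin, tps)

    def test_positive_call_day_100_recurrence_310_is_6p9_months(self):
        traj = self.traj(310, [("baseline", -7, 5.0), ("followup_1", 100, 3.0)])
        assert recurrence_lead_time(traj) == pytest.approx(6.9)

    def test_no_positive_followup_gives_none(self):
        traj = self.traj(310, [("baseline", -7, 5.0), ("followup_1", 100, 0.5)])
        assert recurrence_lead_time(traj) is None

    def test_positive_on_recurrence_day_gives_zero(self):
        traj = self.traj(100, [("baseline", -7, 5.0), ("followup_1", 100, 3.0)])
        assert recurrence_lead_time(traj) == 0.0

    def test_earliest_positive_anchors_the_lead(self):
        traj = self.traj(
            310,
            [("baseline", -7, 5.0), ("followup_1", 100, 3.0), ("followup_2", 200, 4.0)],
        )
        assert recurrence_lead_time(traj) == pytest.approx(6.9)

    def test_missing_recurrence_is_an_error(self):
        traj = self.traj(None, [("baseline", -7, 5.0)])
        with pytest.raises(ValidationError, match="no recurrence"):
            recurrence_lead_time(traj)

    def test_increase_mode_requires_rise_over_previous(self):
        traj = self.traj(310, [("baseline", -7, 5.0), ("followup_1", 100, 2.5)])
        assert recurrence_lead_time(traj, mode="positive") == pytest.approx(6.9)
        assert recurrence_lead_time(traj, mode="increase") is None  # 2.5 < 5.0

    def test_lead_time_non_negative_whenever_present(self):
        for rec_day in (95, 150, 400):
            traj = self.traj(rec_day, [("baseline", -7, 5.0), ("followup_1", 90, 3.0)])
            lead = recurrence_lead_time(traj)
            assert lead is None or lead >= 0.0
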