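"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emits everything the pipeline consumes — a healthy-donor
panel, per-patient tumor profiles, per-timepoint plasma block counts and
mutation calls, a sample manifest with clinical metadata — plus the ground
truth behind every table, so estimator properties (bias, type-I error,
lead-time behaviour) can be measured against known answers.

Generative model
----------------
* Each methylation block carries a latent background rate beta_j: tumor-hyper
  blocks draw beta_j from a low Beta (default Beta(1,19), mean 0.05), the
  rest from a neutral Beta(5,5).  Healthy donors scatter around beta_j with
  a Beta of matching mean and concentration ``donor_concentration``, so the
  panel mean is a consistent per-block estimate of the rate that actually
  generates plasma reads.
* Tumor-hyper blocks get true tumor rates from Beta(18,2) (mean 0.9); other
  blocks jitter around their background.  The observed tissue profile adds
  binomial noise at ``tissue_depth``.
* A plasma sample at ctDNA fraction alpha draws, per block,
  n_j ~ Poisson(depth) reads and k_j ~ Binomial(n_j, alpha*p_T_j +
  (1-alpha)*beta_j) methylated reads.
* Plasma mutation allelic fractions scale the patient's tissue AFs by
  alpha/purity; a synthetic caller emits a call when the observed AF clears
  0.05% with at least 3 alternate reads.
* Recurring patients ramp alpha geometrically over the last one or two
  follow-ups before their recurrence day; all other post-operative samples
  have alpha = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import cohort_io
from .cohort_io import (
    BlockCounts,
    ClinicalRecord,
    GenomicInterval,
    MutationCall,
    SampleRecord,
    ValidationError,
)
from .mb_selection import NormalPlasmaPanel, TumorProfile

PathLike = Union[str, Path]
RngLike = Union[int, np.random.Generator, None]

# (gene, chrom, pos, ref, alt) pool for synthetic mutation sets; one locus
# per gene so variant identities are distinct across a patient's set
_GENE_POOL = (
    ("EGFR", "chr7", 55191822, "T", "G"),
    ("KRAS", "chr12", 25245350, "C", "A"),
    ("TP53", "chr17", 7673802, "G", "A"),
    ("CTNNB1", "chr3", 41224610, "C", "T"),
    ("PIK3CA", "chr3", 179234297, "A", "G"),
    ("BRAF", "chr7", 140753336, "A", "T"),
    ("MET", "chr7", 116771936, "G", "T"),
    ("SOX2", "chr3", 181712562, "G", "C"),
    ("FGFR1", "chr8", 38428337, "C", "G"),
    ("ALK", "chr2", 29223584, "G", "A"),
)


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults mirror the assay design.

    Depths follow the assay's nominal 10,000x plasma / 1,000x tissue
    sequencing; ``plasma_depth`` is the per-block mean read count (panel-wide
    depth spread over blocks), kept at 100 as the desk-scale default.
    """

    seed: int = 0
    n_patients: int = 65
    n_blocks: int = 2000
    n_donors: int = 30
    plasma_depth: float = 100.0
    tissue_depth: int = 1000
    tumor_hyper_fraction: float = 0.05
    tumor_beta: tuple = (18.0, 2.0)
    background_beta: tuple = (1.0, 19.0)
    neutral_beta: tuple = (5.0, 5.0)
    donor_concentration: float = 100.0
    tumor_jitter_concentration: float = 50.0
    baseline_alpha_range: tuple = (0.001, 0.05)
    ramp_alpha_start: float = 0.002
    ramp_growth: float = 2.0
    recurrence_fraction: float = 8 / 65
    recurrence_window: tuple = (150, 420)
    followup_days: tuple = (90, 180, 270)
    baseline_day: int = -7
    purity_range: tuple = (0.2, 0.9)
    n_mutations_range: tuple = (1, 5)
    tissue_af_range: tuple = (0.05, 0.4)
    mutation_depth: int = 10000
    af_floor: float = 0.0005
    min_alt_reads: int = 3
    assay_dropout: float = 0.1

    def __post_init__(self) -> None:
        for name in ("tumor_hyper_fraction", "recurrence_fraction", "assay_dropout", "af_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_blocks < 1 or self.n_donors < 1 or self.n_patients < 0:
            raise ValidationError("n_blocks, n_donors must be >= 1 and n_patients >= 0")

    def to_yaml(self, path: PathLike) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: PathLike) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        return cfg


def _rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def block_id(i: int) -> str:
    return f"MB{i:05d}"


def block_interval(i: int) -> GenomicInterval:
    return GenomicInterval(chrom=f"chr{(i % 22) + 1}", start=10_000 + 1_000 * i, end=10_300 + 1_000 * i)


@dataclass
class BlockModel:
    """Latent per-block truth shared by panel, tumors, and plasma."""

    block_ids: list[str]
    is_hyper: np.ndarray
    background: np.ndarray

    def background_map(self) -> dict[str, float]:
        return dict(zip(self.block_ids, self.background.tolist()))


def simulate_block_model(config: SimulationConfig, rng: RngLike = None) -> BlockModel:
    rng = _rng(rng)
    n = config.n_blocks
    n_hyper = int(round(config.tumor_hyper_fraction * n))
    is_hyper = np.zeros(n, dtype=bool)
    is_hyper[:n_hyper] = True
    a_bg, b_bg = config.background_beta
    a_nt, b_nt = config.neutral_beta
    background = np.where(
        is_hyper,
        rng.beta(a_bg, b_bg, size=n),
        rng.beta(a_nt, b_nt, size=n),
    )
    background = np.clip(background, 1e-4, 1 - 1e-4)
    return BlockModel(block_ids=[block_id(i) for i in range(n)], is_hyper=is_hyper, background=background)


def simulate_normal_panel(
    config: SimulationConfig, rng: RngLike = None, block_model: Optional[BlockModel] = None
) -> NormalPlasmaPanel:
    """Healthy-donor plasma methylation rates, one row of donors per block."""
    rng = _rng(rng)
    if block_model is None:
        block_model = simulate_block_model(config, rng)
    c = config.donor_concentration
    rates: dict[str, np.ndarray] = {}
    for bid, bg in zip(block_model.block_ids, block_model.background):
        rates[bid] = rng.beta(bg * c, (1.0 - bg) * c, size=config.n_donors)
    return NormalPlasmaPanel(rates=rates, n_donors=config.n_donors)


def simulate_tumor_profile(
    config: SimulationConfig,
    patient_id: str,
    rng: RngLike = None,
    block_model: Optional[BlockModel] = None,
    purity: Optional[float] = None,
) -> tuple[TumorProfile, dict[str, float]]:
    """Observed tissue profile plus the latent true tumor rates.

    The observed rate at each block is a binomial draw of the true rate at
    ``tissue_depth`` reads; truth is what plasma simulation uses.
    """
    rng = _rng(rng)
    if block_model is None:
        block_model = simulate_block_model(config, rng)
    a_t, b_t = config.tumor_beta
    c_t = config.tumor_jitter_concentration
    n = len(block_model.block_ids)
    hyper_rates = rng.beta(a_t, b_t, size=n)
    jitter = rng.beta(
        np.clip(block_model.background * c_t, 1e-3, None),
        np.clip((1.0 - block_model.background) * c_t, 1e-3, None),
    )
    true_rates = np.where(block_model.is_hyper, hyper_rates, jitter)
    observed = rng.binomial(config.tissue_depth, true_rates) / config.tissue_depth
    profile = TumorProfile(
        patient_id=patient_id,
        rates=dict(zip(block_model.block_ids, observed.tolist())),
        tumor_purity=purity,
    )
    return profile, dict(zip(block_model.block_ids, true_rates.tolist()))


def simulate_plasma_sample(
    tumor_rates: Union[TumorProfile, Mapping[str, float]],
    background: Union[NormalPlasmaPanel, Mapping[str, float]],
    true_alpha: float,
    depth: float,
    rng: RngLike = None,
) -> list[BlockCounts]:
    """Plasma block counts at a known spiked ctDNA fraction.

    Per block: total reads ~ Poisson(depth), methylated reads ~
    Binomial(total, alpha*p_T + (1-alpha)*p_N).  Accepts either latent-truth
    mappings or the observed objects (panel background then falls back to
    per-block donor means).
    """
    if not 0.0 <= true_alpha <= 1.0:
        raise ValidationError(f"true_alpha must be in [0, 1], got {true_alpha}")
    rng = _rng(rng)
    if isinstance(tumor_rates, TumorProfile):
        tumor_rates = tumor_rates.rates
    if isinstance(background, NormalPlasmaPanel):
        background = {bid: background.mean_rate(bid) for bid in background.block_ids}
    blocks: list[BlockCounts] = []
    ids = list(tumor_rates)
    pt = np.array([tumor_rates[b] for b in ids])
    pn = np.array([background[b] for b in ids])
    theta = np.clip(true_alpha * pt + (1.0 - true_alpha) * pn, 0.0, 1.0)
    totals = rng.poisson(depth, size=len(ids))
    meth = rng.binomial(totals, theta)
    for i, bid in enumerate(ids):
        idx = int(bid[2:]) if bid.startswith("MB") and bid[2:].isdigit() else i
        blocks.append(
            BlockCounts(
                block_id=bid,
                interval=block_interval(idx),
                methylated_reads=int(meth[i]),
                total_reads=int(totals[i]),
            )
        )
    return blocks


def simulate_mutations(
    config: SimulationConfig,
    variants: Sequence[tuple[str, str, int, str, str, float]],
    purity: float,
    true_alpha: float,
    sample_id: str,
    rng: RngLike = None,
) -> list[MutationCall]:
    """Plasma mutation calls from a patient's tissue variant set.

    ``variants`` rows are (gene, chrom, pos, ref, alt, tissue_af).  The
    plasma AF of each variant is true_alpha * tissue_af / purity (capped at
    1); observed alternate reads are binomial at ``mutation_depth`` and a
    call is emitted only when the observed AF clears the caller floor with
    at least ``min_alt_reads`` alternate reads.
    """
    rng = _rng(rng)
    depth = config.mutation_depth
    calls: list[MutationCall] = []
    for gene, chrom, pos, ref, alt, tissue_af in variants:
        plasma_af = min(1.0, true_alpha * tissue_af / purity)
        alt_reads = int(rng.binomial(depth, plasma_af))
        observed_af = alt_reads / depth
        if alt_reads >= config.min_alt_reads and observed_af >= config.af_floor:
            calls.append(
                MutationCall(
                    sample_id=sample_id,
                    gene=gene,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    allelic_fraction=observed_af,
                    depth=depth,
                    chip_filtered=True,
                )
            )
    return calls


@dataclass
class GroundTruth:
    """Latent truth emitted alongside every simulated cohort."""

    alpha: pd.DataFrame  # patient_id, timepoint_label, days_from_surgery, true_alpha
    blocks: pd.DataFrame  # block_id, is_hyper, background_rate
    tumor_rates: pd.DataFrame  # patient_id, block_id, true_rate
    mutations: pd.DataFrame  # patient_id, gene, tissue_af


@dataclass
class SimulatedCohort:
    """In-memory cohort: every pipeline input plus its ground truth.

    ``plasma_blocks`` / ``mutations`` contain an entry only for samples
    where that assay was performed (an empty call list still means
    "assayed, nothing found").
    """

    config: SimulationConfig
    samples: list[SampleRecord]
    clinical: list[ClinicalRecord]
    panel: NormalPlasmaPanel
    tumor_profiles: dict[str, TumorProfile]
    plasma_blocks: dict[str, list[BlockCounts]]
    mutations: dict[str, list[MutationCall]]
    truth: GroundTruth

    def write(self, outdir: PathLike) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        cohort_io.write_manifest(self.samples, out / "manifest.tsv")
        cohort_io.write_clinical_table(self.clinical, out / "clinical.tsv")
        self.panel.to_tsv(out / "panel.tsv")
        for pid, profile in self.tumor_profiles.items():
            profile.to_tsv(out / "tumor" / f"{pid}.tsv")
        for sid, blocks in self.plasma_blocks.items():
            cohort_io.write_block_table(blocks, out / "blocks" / f"{sid}.tsv")
        all_calls = [c for calls in self.mutations.values() for c in calls]
        cohort_io.write_mutation_table(all_calls, out / "mutations.tsv")
        assay_rows = [
            (s.sample_id, str(s.sample_id in self.plasma_blocks).lower(), str(s.sample_id in self.mutations).lower())
            for s in self.samples
            if s.material == "plasma"
        ]
        cohort_io._write_tsv(out / "assays.tsv", ("sample_id", "methylation_assayed", "mutation_assayed"), assay_rows)
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        for name in ("alpha", "blocks", "tumor_rates", "mutations"):
            getattr(self.truth, name).to_csv(truth_dir / f"{name}.tsv", sep="\t", index=False)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full longitudinal cohort under one master seed."""
    rng = _rng(config.seed)
    bm = simulate_block_model(config, rng)
    panel = simulate_normal_panel(config, rng, bm)

    n = config.n_patients
    n_recur = int(round(config.recurrence_fraction * n))
    recurring = set(rng.permutation(n)[:n_recur].tolist())

    samples: list[SampleRecord] = []
    clinical: list[ClinicalRecord] = []
    tumor_profiles: dict[str, TumorProfile] = {}
    plasma_blocks: dict[str, list[BlockCounts]] = {}
    mutations: dict[str, list[MutationCall]] = {}
    alpha_rows, tumor_rows, mut_rows = [], [], []

    lo_a, hi_a = config.baseline_alpha_range
    for i in range(n):
        pid = f"P{i + 1:03d}"
        purity = float(rng.uniform(*config.purity_range))
        histology = str(rng.choice(["LUAD", "LUSC", "other"], p=[0.75, 0.20, 0.05]))
        stage = str(rng.choice(["IA", "IB", "IIA", "IIB", "IIIA", "IIIB"], p=[0.4, 0.2, 0.1, 0.1, 0.15, 0.05]))
        grade = int(rng.integers(1, 4))
        rec_day = int(rng.integers(*config.recurrence_window)) if i in recurring else None
        clinical.append(
            ClinicalRecord(
                patient_id=pid,
                histology=histology,
                stage=stage,
                tumor_purity=purity,
                recurrence_day=rec_day,
                differentiation_grade=grade,
            )
        )

        profile, true_rates = simulate_tumor_profile(config, pid, rng, bm, purity)
        tumor_profiles[pid] = profile
        tumor_rows.extend((pid, bid, r) for bid, r in true_rates.items())

        n_mut = int(rng.integers(config.n_mutations_range[0], config.n_mutations_range[1] + 1))
        pool_idx = rng.choice(len(_GENE_POOL), size=n_mut, replace=False)
        variants = []
        for j in pool_idx:
            gene, chrom, pos, ref, alt = _GENE_POOL[int(j)]
            tissue_af = float(rng.uniform(*config.tissue_af_range))
            variants.append((gene, chrom, pos, ref, alt, tissue_af))
            mut_rows.append((pid, gene, tissue_af))

        # tumor tissue sample (baseline) and its call table
        tissue_sid = f"{pid}_TT"
        samples.append(
            SampleRecord(tissue_sid, pid, "tumor_tissue", "baseline", config.baseline_day)
        )
        mutations[tissue_sid] = [
            MutationCall(tissue_sid, g, c, p, r, a, af, config.tissue_depth, True)
            for g, c, p, r, a, af in variants
        ]

        # timepoint schedule: baseline plus follow-ups up to recurrence
        days = [config.baseline_day] + [
            d for d in config.followup_days if rec_day is None or d <= rec_day
        ]
        baseline_alpha = float(np.exp(rng.uniform(np.log(lo_a), np.log(hi_a))))
        n_follow = len(days) - 1
        ramp_len = 0
        if rec_day is not None and n_follow > 0:
            ramp_len = min(int(rng.integers(1, 3)), n_follow)

        for t, day in enumerate(days):
            label = "baseline" if t == 0 else f"followup_{t}"
            if t == 0:
                alpha = baseline_alpha
            elif ramp_len and t > n_follow - ramp_len:
                alpha = config.ramp_alpha_start * config.ramp_growth ** (t - (n_follow - ramp_len) - 1)
            else:
                alpha = 0.0
            alpha = min(alpha, 1.0)
            sid = f"{pid}_T{t}"
            samples.append(SampleRecord(sid, pid, "plasma", label, day))
            alpha_rows.append((pid, label, day, alpha))

            meth_assayed = t == 0 or rng.uniform() >= config.assay_dropout
            mut_assayed = t == 0 or rng.uniform() >= config.assay_dropout
            if meth_assayed:
                plasma_blocks[sid] = simulate_plasma_sample(
                    true_rates, bm.background_map(), alpha, config.plasma_depth, rng
                )
            if mut_assayed:
                mutations[sid] = simulate_mutations(config, variants, purity, alpha, sid, rng)

    truth = GroundTruth(
        alpha=pd.DataFrame(alpha_rows, columns=["patient_id", "timepoint_label", "days_from_surgery", "true_alpha"]),
        blocks=pd.DataFrame(
            {"block_id": bm.block_ids, "is_hyper": bm.is_hyper, "background_rate": bm.background}
        ),
        tumor_rates=pd.DataFrame(tumor_rows, columns=["patient_id", "block_id", "true_rate"]),
        mutations=pd.DataFrame(mut_rows, columns=["patient_id", "gene", "tissue_af"]),
    )
    return SimulatedCohort(
        config=config,
        samples=samples,
        clinical=clinical,
        panel=panel,
        tumor_profiles=tumor_profiles,
        plasma_blocks=plasma_blocks,
        mutations=mutations,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# deterministic worked-example cohorts


def counts_cohort(
    mutation: Mapping[str, tuple[int, int]] = {},
    methylation: Mapping[str, tuple[int, int]] = {},
    followup_spacing_days: int = 90,
) -> list:
    """Build a cohort realizing exact per-timepoint positive/assayed counts.

    For each (assay, timepoint) entry ``label -> (n_positive, n_assayed)``,
    patients P001..P{n_assayed} are assayed and the first n_positive are
    positive.  Methylation positivity is produced by actually fitting the MD
    ratio on strong-signal vs background-level block counts, so the scored
    pipeline (fit, Wald, threshold) is exercised rather than flags being
    assigned.  Useful for reproducing printed detection-rate tables.
    """
    from .longitudinal import assemble_trajectories
    from .mrd_model import MixtureBlock, call_mrd, fit_md_ratio
    from .mutation_tracking import summarize_plasma

    def day_of(label: str) -> int:
        return -7 if label == "baseline" else followup_spacing_days * cohort_io.timepoint_rank(label)

    n_patients = max(
        [assayed for _, assayed in mutation.values()] + [assayed for _, assayed in methylation.values()]
    )
    pids = [f"P{i + 1:03d}" for i in range(n_patients)]
    clinical = [ClinicalRecord(pid, "LUAD", "IA", 0.6) for pid in pids]

    labels = sorted(set(mutation) | set(methylation), key=cohort_io.timepoint_rank)
    samples: list[SampleRecord] = []
    mrd_calls = {}
    profiles = {}

    strong = [MixtureBlock(f"S{j}", 160, 200, 0.9, 0.05) for j in range(5)]
    null = [MixtureBlock(f"S{j}", 10, 200, 0.9, 0.05) for j in range(5)]
    positive_call = fit_md_ratio(strong)
    negative_call = fit_md_ratio(null)

    for label in labels:
        mut_pos, mut_n = mutation.get(label, (0, 0))
        met_pos, met_n = methylation.get(label, (0, 0))
        for i in range(max(mut_n, met_n)):
            pid = pids[i]
            sid = f"{pid}_{label}"
            samples.append(SampleRecord(sid, pid, "plasma", label, day_of(label)))
            if i < mut_n:
                calls = (
                    [MutationCall(sid, "EGFR", "chr7", 55191822, "T", "G", 0.02, 10000, True)]
                    if i < mut_pos
                    else []
                )
                profiles[sid] = summarize_plasma(sid, calls)
            if i < met_n:
                est = positive_call if i < met_pos else negative_call
                mrd_calls[sid] = call_mrd(sid, est)
    return assemble_trajectories(samples, clinical, mrd_calls, profiles)
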