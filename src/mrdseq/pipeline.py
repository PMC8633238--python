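"""End-to-end orchestration: select blocks, score samples, assemble cohort.

Thin composition of the stage modules — no statistics of its own.  Serves
the command-line interface and scripted analyses that start from a cohort
directory or a :class:`~mrdseq.synthetic.SimulatedCohort`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import cohort_io
from .cohort_io import MutationCall
from .longitudinal import PatientTrajectory, assemble_trajectories
from .mb_selection import (
    HYPER,
    MBSet,
    NormalPlasmaPanel,
    TumorProfile,
    check_tumor_content,
    select_methylation_blocks,
)
from .mrd_model import MRD_WALD_THRESHOLD, MRDCall, call_mrd, fit_md_ratio, mixture_blocks
from .mutation_tracking import PlasmaMutationProfile, summarize_plasma
from .synthetic import SimulatedCohort

PathLike = Union[str, Path]


@dataclass
class CohortAnalysis:
    trajectories: list[PatientTrajectory]
    mbsets: dict[str, MBSet]
    mrd_calls: dict[str, MRDCall]
    mutation_profiles: dict[str, PlasmaMutationProfile]
    excluded_patients: list[str] = field(default_factory=list)  # purity gate


def load_cohort(indir: PathLike) -> SimulatedCohort:
    """Load a cohort directory in the layout ``SimulatedCohort.write`` emits."""
    from .synthetic import GroundTruth, SimulationConfig
    import pandas as pd

    indir = Path(indir)
    config = (
        SimulationConfig.from_yaml(indir / "config.yaml")
        if (indir / "config.yaml").exists()
        else SimulationConfig()
    )
    samples, clinical = cohort_io.read_manifest(indir / "manifest.tsv", indir / "clinical.tsv")
    panel = NormalPlasmaPanel.from_tsv(indir / "panel.tsv")
    purity = {c.patient_id: c.tumor_purity for c in clinical}
    tumor_profiles = {
        p.stem: TumorProfile.from_tsv(p, tumor_purity=purity.get(p.stem))
        for p in sorted((indir / "tumor").glob("*.tsv"))
    }
    plasma_blocks = {
        p.stem: cohort_io.read_block_table(p) for p in sorted((indir / "blocks").glob("*.tsv"))
    }
    calls_by_sample: dict[str, list[MutationCall]] = {}
    for call in cohort_io.read_mutation_table(indir / "mutations.tsv"):
        calls_by_sample.setdefault(call.sample_id, []).append(call)
    mutations: dict[str, list[MutationCall]] = {}
    assays = indir / "assays.tsv"
    if assays.exists():
        for _, row in _read_assays(assays):
            sid = row["sample_id"]
            if row["mutation_assayed"] == "true":
                mutations[sid] = calls_by_sample.get(sid, [])
    else:  # without the assay ledger, presence of calls is the only signal
        mutations = calls_by_sample
    for s in samples:
        if s.material == "tumor_tissue" and s.sample_id in calls_by_sample:
            mutations[s.sample_id] = calls_by_sample[s.sample_id]

    empty = GroundTruth(pd.DataFrame(), pd.DataFrame(), pd.DataFrame(), pd.DataFrame())
    truth_dir = indir / "truth"
    if truth_dir.exists():
        empty = GroundTruth(
            alpha=pd.read_csv(truth_dir / "alpha.tsv", sep="\t"),
            blocks=pd.read_csv(truth_dir / "blocks.tsv", sep="\t"),
            tumor_rates=pd.read_csv(truth_dir / "tumor_rates.tsv", sep="\t"),
            mutations=pd.read_csv(truth_dir / "mutations.tsv", sep="\t"),
        )
    return SimulatedCohort(
        config=config,
        samples=samples,
        clinical=clinical,
        panel=panel,
        tumor_profiles=tumor_profiles,
        plasma_blocks=plasma_blocks,
        mutations=mutations,
        truth=empty,
    )


def _read_assays(path: Path):
    import csv

    with path.open(encoding="utf-8") as fh:
        reader = csv.DictReader((l for l in fh if not l.startswith("#")), delimiter="\t")
        for i, row in enumerate(reader):
            yield i, row


def analyze_cohort(
    cohort: SimulatedCohort,
    alpha_level: float = 0.05,
    min_delta: float = 0.1,
    direction: str = HYPER,
    threshold: float = MRD_WALD_THRESHOLD,
    purity_threshold: float = 0.30,
) -> CohortAnalysis:
    """Run selection, MD-ratio scoring, and mutation summaries for a cohort."""
    clinical_by_pid = {c.patient_id: c for c in cohort.clinical}

    mbsets: dict[str, MBSet] = {}
    excluded: list[str] = []
    for pid, tumor in cohort.tumor_profiles.items():
        record = clinical_by_pid[pid]
        if not check_tumor_content(record, purity_threshold):
            excluded.append(pid)
            continue
        mbsets[pid] = select_methylation_blocks(
            tumor, cohort.panel, alpha_level=alpha_level, min_delta=min_delta, direction=direction
        )

    mrd_calls: dict[str, MRDCall] = {}
    mutation_profiles: dict[str, PlasmaMutationProfile] = {}
    for sample in cohort.samples:
        if sample.material != "plasma":
            continue
        sid = sample.sample_id
        mbset = mbsets.get(sample.patient_id)
        blocks = cohort.plasma_blocks.get(sid)
        if mbset is not None and len(mbset) and blocks is not None:
            mix = mixture_blocks(mbset, blocks)
            if mix and sum(b.n for b in mix) > 0:
                mrd_calls[sid] = call_mrd(sid, fit_md_ratio(mix), threshold)
        if sid in cohort.mutations:
            mutation_profiles[sid] = summarize_plasma(sid, cohort.mutations[sid])

    trajectories = assemble_trajectories(cohort.samples, cohort.clinical, mrd_calls, mutation_profiles)
    return CohortAnalysis(
        trajectories=trajectories,
        mbsets=mbsets,
        mrd_calls=mrd_calls,
        mutation_profiles=mutation_profiles,
        excluded_patients=excluded,
    )
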