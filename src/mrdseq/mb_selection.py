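"""Patient-specific selection of cancer methylation blocks.

A tumor-informed MRD assay only tracks blocks where the patient's tumor is
clearly differentially methylated against background cell-free DNA.  The
background here is a panel of healthy-donor plasma methylation rates; each
candidate block gets a one-sided empirical rank p-value of the tumor rate
against the donor rates, plus an effect-size floor.  Patients whose resected
tissue has tumor content below 30% are excluded from scoring altogether,
because their tissue profile is too diluted to define tumor-specific blocks.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .cohort_io import ClinicalRecord, ValidationError, _write_tsv

PathLike = Union[str, Path]

TUMOR_CONTENT_THRESHOLD = 0.30
RATE_EPS = 1e-6  # clamp for degenerate 0/1 methylation rates

HYPER = "hyper"
HYPO = "hypo"


def clamp_rate(rate: float, eps: float = RATE_EPS) -> float:
    """Clamp a methylation rate into (0, 1) to avoid log/division blowups."""
    return float(min(max(rate, eps), 1.0 - eps))


@dataclass
class NormalPlasmaPanel:
    """Per-block methylation rates across healthy plasma donors.

    ``rates`` maps block_id -> array of donor beta values; blocks may have
    missing donors, so arrays can differ in length but never exceed
    ``n_donors``.
    """

    rates: dict[str, np.ndarray]
    n_donors: int

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValidationError("panel needs at least one donor")
        for bid, arr in self.rates.items():
            arr = np.asarray(arr, dtype=float)
            if arr.size == 0 or arr.size > self.n_donors:
                raise ValidationError(f"panel block {bid}: donor count {arr.size} outside 1..{self.n_donors}")
            if np.any((arr < 0) | (arr > 1)):
                raise ValidationError(f"panel block {bid}: rates outside [0, 1]")
            self.rates[bid] = arr

    @property
    def block_ids(self) -> list[str]:
        return list(self.rates)

    def mean_rate(self, block_id: str) -> float:
        return float(np.mean(self.rates[block_id]))

    def to_tsv(self, path: PathLike) -> None:
        rows = []
        for bid, arr in self.rates.items():
            for j, r in enumerate(arr):
                rows.append((bid, f"D{j + 1:03d}", repr(float(r))))
        _write_tsv(path, ("block_id", "donor_id", "rate"), rows)

    @classmethod
    def from_tsv(cls, path: PathLike) -> "NormalPlasmaPanel":
        rates: dict[str, list[float]] = {}
        with Path(path).open(encoding="utf-8") as fh:
            reader = csv.DictReader(
                (line for line in fh if not line.startswith("#")), delimiter="\t"
            )
            for row in reader:
                rates.setdefault(row["block_id"], []).append(float(row["rate"]))
        if not rates:
            raise ValidationError(f"{path}: empty panel")
        n_donors = max(len(v) for v in rates.values())
        return cls({k: np.asarray(v) for k, v in rates.items()}, n_donors=n_donors)


@dataclass
class TumorProfile:
    """One patient's tumor-tissue methylation rates (beta values)."""

    patient_id: str
    rates: dict[str, float]
    tumor_purity: Optional[float] = None

    def __post_init__(self) -> None:
        for bid, r in self.rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"tumor block {bid}: rate {r} outside [0, 1]")

    def to_tsv(self, path: PathLike) -> None:
        _write_tsv(
            path,
            ("patient_id", "block_id", "rate"),
            ((self.patient_id, bid, repr(float(r))) for bid, r in self.rates.items()),
        )

    @classmethod
    def from_tsv(cls, path: PathLike, tumor_purity: Optional[float] = None) -> "TumorProfile":
        rates: dict[str, float] = {}
        patient_id = ""
        with Path(path).open(encoding="utf-8") as fh:
            reader = csv.DictReader(
                (line for line in fh if not line.startswith("#")), delimiter="\t"
            )
            for row in reader:
                patient_id = row["patient_id"]
                rates[row["block_id"]] = float(row["rate"])
        if not rates:
            raise ValidationError(f"{path}: empty tumor profile")
        return cls(patient_id=patient_id, rates=rates, tumor_purity=tumor_purity)


@dataclass(frozen=True)
class SelectedBlock:
    block_id: str
    p_tumor: float
    p_normal: float
    direction: str
    p_value: float


@dataclass
class MBSet:
    """The patient-specific set of selected methylation blocks."""

    patient_id: str
    blocks: list[SelectedBlock] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def block_ids(self) -> list[str]:
        return [b.block_id for b in self.blocks]

    def to_tsv(self, path: PathLike) -> None:
        _write_tsv(
            path,
            ("patient_id", "block_id", "p_T", "p_N", "direction", "p_value"),
            (
                (self.patient_id, b.block_id, repr(b.p_tumor), repr(b.p_normal), b.direction, repr(b.p_value))
                for b in self.blocks
            ),
        )

    @classmethod
    def from_tsv(cls, path: PathLike) -> "MBSet":
        blocks: list[SelectedBlock] = []
        patient_id = ""
        with Path(path).open(encoding="utf-8") as fh:
            reader = csv.DictReader(
                (line for line in fh if not line.startswith("#")), delimiter="\t"
            )
            for row in reader:
                patient_id = row["patient_id"]
                blocks.append(
                    SelectedBlock(
                        block_id=row["block_id"],
                        p_tumor=float(row["p_T"]),
                        p_normal=float(row["p_N"]),
                        direction=row["direction"],
                        p_value=float(row["p_value"]),
                    )
                )
        return cls(patient_id=patient_id, blocks=blocks)


def check_tumor_content(clinical: ClinicalRecord, threshold: float = TUMOR_CONTENT_THRESHOLD) -> bool:
    """Eligibility gate: tumor content strictly below ``threshold`` is excluded.

    A purity exactly at the threshold is eligible (the exclusion applies to
    "less than" the cutoff).
    """
    if clinical.tumor_purity is None:
        raise ValidationError(
            f"patient {clinical.patient_id}: tumor_purity missing; add it to the clinical table"
        )
    return clinical.tumor_purity >= threshold


def empirical_block_pvalue(
    tumor_rate: float, donor_rates: Sequence[float], direction: str = HYPER
) -> float:
    """One-sided empirical rank p-value of the tumor rate against donors.

    p = (1 + #{donors at least as extreme as the tumor}) / (N + 1); ties
    count as extreme, so p is in (0, 1] and a panel of N donors can reach at
    best 1/(N+1).
    """
    donors = np.asarray(donor_rates, dtype=float)
    if donors.size < 1:
        raise ValidationError("empirical p-value needs at least one donor rate")
    if direction == HYPER:
        extreme = int(np.sum(donors >= tumor_rate))
    elif direction == HYPO:
        extreme = int(np.sum(donors <= tumor_rate))
    else:
        raise ValidationError(f"direction must be '{HYPER}' or '{HYPO}', got {direction!r}")
    return (1 + extreme) / (donors.size + 1)


def select_methylation_blocks(
    tumor: TumorProfile,
    panel: NormalPlasmaPanel,
    alpha_level: float = 0.05,
    min_delta: float = 0.1,
    direction: str = HYPER,
) -> MBSet:
    """Select blocks where the tumor is significantly shifted from donors.

    A block is kept iff its empirical p-value is strictly below
    ``alpha_level`` AND the tumor-vs-panel-mean shift is at least
    ``min_delta`` in the requested direction.  The background rate attached
    to each kept block is the donor mean, clamped away from 0/1.
    """
    shared = [bid for bid in tumor.rates if bid in panel.rates]
    if not shared:
        raise ValidationError(
            f"patient {tumor.patient_id}: tumor profile and panel share no block_ids"
        )
    selected: list[SelectedBlock] = []
    for bid in shared:
        p_t = tumor.rates[bid]
        donors = panel.rates[bid]
        p_n = float(np.mean(donors))
        delta = p_t - p_n if direction == HYPER else p_n - p_t
        if delta < min_delta:
            continue
        p = empirical_block_pvalue(p_t, donors, direction)
        if p < alpha_level:
            selected.append(
                SelectedBlock(
                    block_id=bid,
                    p_tumor=p_t,
                    p_normal=clamp_rate(p_n),
                    direction=direction,
                    p_value=p,
                )
            )
    return MBSet(patient_id=tumor.patient_id, blocks=selected)
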