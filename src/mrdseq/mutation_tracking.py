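"""Plasma somatic-mutation summaries: maxAF, concordance, clearance.

maxAF is the highest mutant allelic fraction among the variants detected in
one plasma sample; a sample with no calls is "not detected" and carries no
maxAF (it is never coerced to 0).  Tissue-plasma concordance classifies each
variant of a patient's baseline pair as detected in both materials (Match),
tissue only, or plasma only.  ctDNA clearance marks a baseline
mutation-positive patient whose follow-up sample has no detectable panel
mutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .cohort_io import MutationCall, ValidationError

MATCH = "Match"
TISSUE_ONLY = "Tis_only"
PLASMA_ONLY = "Pla_only"


class ClearanceStatus(str, Enum):
    CLEARED = "cleared"
    NOT_CLEARED = "not_cleared"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class PlasmaMutationProfile:
    sample_id: str
    calls: tuple[MutationCall, ...]
    detected: bool
    max_af: Optional[float]


@dataclass(frozen=True)
class ConcordanceRecord:
    key: tuple
    gene: str
    category: str  # MATCH / TISSUE_ONLY / PLASMA_ONLY


def variant_key(call: MutationCall) -> tuple:
    """Identity used to match a variant across materials.

    Point variants match on (chrom, pos, ref, alt); calls without coordinates
    (rearrangements, fusions) fall back to a (gene, alt-label) string key.
    """
    if call.pos is None:
        return (call.gene, call.alt)
    return (call.chrom, call.pos, call.ref, call.alt)


def summarize_plasma(
    sample_id: str,
    calls: Sequence[MutationCall],
    allow_unfiltered: bool = False,
) -> PlasmaMutationProfile:
    """Collapse one plasma sample's calls into a detection flag and maxAF."""
    for c in calls:
        if c.sample_id != sample_id:
            raise ValidationError(
                f"mixed sample_ids: expected {sample_id!r}, found {c.sample_id!r}"
            )
        if not c.chip_filtered and not allow_unfiltered:
            raise ValidationError(
                f"sample {sample_id}: call {c.gene} lacks clonal-hematopoiesis filtering "
                "(chip_filtered=false); pass allow_unfiltered=True to override"
            )
    detected = len(calls) > 0
    return PlasmaMutationProfile(
        sample_id=sample_id,
        calls=tuple(calls),
        detected=detected,
        max_af=max(c.allelic_fraction for c in calls) if detected else None,
    )


def classify_concordance(
    tissue_calls: Sequence[MutationCall], plasma_calls: Sequence[MutationCall]
) -> tuple[list[ConcordanceRecord], bool]:
    """Classify every variant of a baseline tissue/plasma pair.

    Returns the per-variant records (tissue-ordered first, then plasma-only
    in input order) and the patient-level concordance flag: plasma shares at
    least one tissue variant.
    """
    tissue_keys = {variant_key(c): c for c in tissue_calls}
    plasma_keys = {variant_key(c): c for c in plasma_calls}
    records: list[ConcordanceRecord] = []
    for key, call in tissue_keys.items():
        category = MATCH if key in plasma_keys else TISSUE_ONLY
        records.append(ConcordanceRecord(key=key, gene=call.gene, category=category))
    for key, call in plasma_keys.items():
        if key not in tissue_keys:
            records.append(ConcordanceRecord(key=key, gene=call.gene, category=PLASMA_ONLY))
    concordant = any(r.category == MATCH for r in records)
    return records, concordant


def ctdna_clearance(
    baseline: PlasmaMutationProfile, followup: PlasmaMutationProfile
) -> ClearanceStatus:
    """Clearance requires baseline positivity and a mutation-free follow-up.

    Patients with nothing detectable at baseline are out of scope for the
    definition (not_applicable), never "cleared".
    """
    if not baseline.detected:
        return ClearanceStatus.NOT_APPLICABLE
    return ClearanceStatus.NOT_CLEARED if followup.detected else ClearanceStatus.CLEARED
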