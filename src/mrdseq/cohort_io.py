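"""Readers, writers and shared record types for cohort tables.

Every table the pipeline touches is plain tab-separated UTF-8 text with a
header row; lines starting with ``#`` are comments.  Methylation blocks use
BED-style 0-based half-open coordinates; point mutations are 1-based
(VCF-like).  Allelic fractions are stored as fractions in [0, 1] — percent
formatting is a presentation concern only.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

PathLike = Union[str, Path]

MATERIALS = ("tumor_tissue", "plasma", "lymphocyte")
HISTOLOGIES = ("LUAD", "LUSC", "other")

BLOCK_COLUMNS = ("chrom", "start", "end", "block_id", "methylated_reads", "total_reads")
MANIFEST_COLUMNS = ("sample_id", "patient_id", "material", "timepoint_label", "days_from_surgery")
CLINICAL_COLUMNS = ("patient_id", "histology", "stage", "tumor_purity", "recurrence_day", "differentiation_grade")
MUTATION_COLUMNS = ("sample_id", "gene", "chrom", "pos", "ref", "alt", "af", "depth", "chip_filtered")


class CohortIOError(ValueError):
    """Base class for table reading/validation failures."""


class ParseError(CohortIOError):
    """A row could not be parsed; message names the file and line."""


class ValidationError(CohortIOError):
    """A parsed record violates a domain invariant."""


# ---------------------------------------------------------------------------
# record types


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval (0-based start, exclusive end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValidationError(f"interval start must be < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BlockCounts:
    """Bisulfite read counts for one methylation block in one sample.

    ``methylated_reads`` (k) out of ``total_reads`` (n) support methylation
    over the block.
    """

    block_id: str
    interval: GenomicInterval
    methylated_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.total_reads < 0 or self.methylated_reads < 0:
            raise ValidationError(f"block {self.block_id}: negative read count")
        if self.methylated_reads > self.total_reads:
            raise ValidationError(
                f"block {self.block_id}: methylated_reads ({self.methylated_reads}) "
                f"exceeds total_reads ({self.total_reads})"
            )

    @property
    def beta(self) -> float:
        """Methylated fraction of reads; nan when the block has no reads."""
        if self.total_reads == 0:
            return float("nan")
        return self.methylated_reads / self.total_reads


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    patient_id: str
    material: str
    timepoint_label: str
    days_from_surgery: int

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise ValidationError(f"sample {self.sample_id}: unknown material {self.material!r}")
        timepoint_rank(self.timepoint_label)  # raises on malformed labels
        if self.timepoint_label == "baseline" and self.days_from_surgery > 0:
            raise ValidationError(f"sample {self.sample_id}: baseline must have days_from_surgery <= 0")


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    histology: str
    stage: str
    tumor_purity: Optional[float]
    recurrence_day: Optional[int] = None
    differentiation_grade: Optional[int] = None

    def __post_init__(self) -> None:
        if self.histology not in HISTOLOGIES:
            raise ValidationError(f"patient {self.patient_id}: unknown histology {self.histology!r}")
        if self.tumor_purity is not None and not 0.0 <= self.tumor_purity <= 1.0:
            raise ValidationError(f"patient {self.patient_id}: tumor_purity outside [0, 1]")
        if self.recurrence_day is not None and self.recurrence_day <= 0:
            raise ValidationError(f"patient {self.patient_id}: recurrence_day must be > 0")

    @property
    def recurred(self) -> bool:
        return self.recurrence_day is not None


@dataclass(frozen=True)
class MutationCall:
    """One somatic variant observed in one sample.

    ``pos`` may be None for variants without point coordinates (gene
    rearrangements); such calls are matched by (gene, alt) downstream.
    ``chip_filtered`` records that paired-lymphocyte clonal-hematopoiesis
    filtering was already applied upstream.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: Optional[int]
    ref: str
    alt: str
    allelic_fraction: float
    depth: int
    chip_filtered: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.allelic_fraction <= 1.0:
            raise ValidationError(
                f"call {self.sample_id}/{self.gene}: allelic_fraction {self.allelic_fraction} outside [0, 1]"
            )
        if self.depth <= 0:
            raise ValidationError(f"call {self.sample_id}/{self.gene}: depth must be positive")
        if self.pos is not None and self.pos <= 0:
            raise ValidationError(f"call {self.sample_id}/{self.gene}: pos must be positive (1-based)")


_TIMEPOINT_RE = re.compile(r"^followup_(\d+)$")


def timepoint_rank(label: str) -> int:
    """Ordinal rank of a timepoint label: baseline=0, followup_k=k."""
    if label == "baseline":
        return 0
    m = _TIMEPOINT_RE.match(label)
    if m:
        return int(m.group(1))
    raise ValidationError(f"unknown timepoint label {label!r}")


# ---------------------------------------------------------------------------
# low-level TSV plumbing


def _read_rows(path: PathLike, columns: Sequence[str]) -> Iterable[tuple[int, dict]]:
    """Yield (line_number, row_dict) from a TSV with the expected header."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header: Optional[list[str]] = None
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].startswith("#")):
                continue
            if header is None:
                header = [c.strip() for c in row]
                if header != list(columns):
                    raise ParseError(
                        f"{path}:{lineno}: expected header {list(columns)}, got {header}"
                    )
                continue
            if len(row) != len(columns):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(columns)} fields, got {len(row)}"
                )
            yield lineno, dict(zip(columns, row))
        if header is None:
            raise ParseError(f"{path}: missing header row")


def _int(value: str, path: PathLike, lineno: int, field: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: field {field!r} is not an integer: {value!r}") from None


def _float(value: str, path: PathLike, lineno: int, field: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: field {field!r} is not a number: {value!r}") from None


def _opt(value: str) -> Optional[str]:
    value = value.strip()
    return None if value in ("", ".", "NA") else value


def _bool(value: str, path: PathLike, lineno: int, field: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise ParseError(f"{path}:{lineno}: field {field!r} is not a boolean: {value!r}")


def _write_tsv(path: PathLike, columns: Sequence[str], rows: Iterable[Sequence]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for row in rows:
            writer.writerow(row)


def _wrap_validation(path: PathLike, lineno: int):
    """Context that re-raises ValidationError with file/line prefix."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc_type is not None and issubclass(exc_type, ValidationError):
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
            return False

    return _Ctx()


# ---------------------------------------------------------------------------
# block tables


def read_block_table(path: PathLike) -> list[BlockCounts]:
    """Read a per-sample methylation block count table (BED-like TSV)."""
    blocks: list[BlockCounts] = []
    for lineno, row in _read_rows(path, BLOCK_COLUMNS):
        with _wrap_validation(path, lineno):
            blocks.append(
                BlockCounts(
                    block_id=row["block_id"],
                    interval=GenomicInterval(
                        chrom=row["chrom"],
                        start=_int(row["start"], path, lineno, "start"),
                        end=_int(row["end"], path, lineno, "end"),
                    ),
                    methylated_reads=_int(row["methylated_reads"], path, lineno, "methylated_reads"),
                    total_reads=_int(row["total_reads"], path, lineno, "total_reads"),
                )
            )
    return blocks


def write_block_table(blocks: Iterable[BlockCounts], path: PathLike) -> None:
    _write_tsv(
        path,
        BLOCK_COLUMNS,
        (
            (b.interval.chrom, b.interval.start, b.interval.end, b.block_id, b.methylated_reads, b.total_reads)
            for b in blocks
        ),
    )


# ---------------------------------------------------------------------------
# manifest + clinical


def read_clinical_table(path: PathLike) -> list[ClinicalRecord]:
    records: list[ClinicalRecord] = []
    seen: set[str] = set()
    for lineno, row in _read_rows(path, CLINICAL_COLUMNS):
        pid = row["patient_id"]
        if pid in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate patient_id {pid!r}")
        seen.add(pid)
        purity = _opt(row["tumor_purity"])
        rec_day = _opt(row["recurrence_day"])
        grade = _opt(row["differentiation_grade"])
        with _wrap_validation(path, lineno):
            records.append(
                ClinicalRecord(
                    patient_id=pid,
                    histology=row["histology"],
                    stage=row["stage"],
                    tumor_purity=None if purity is None else _float(purity, path, lineno, "tumor_purity"),
                    recurrence_day=None if rec_day is None else _int(rec_day, path, lineno, "recurrence_day"),
                    differentiation_grade=None if grade is None else _int(grade, path, lineno, "differentiation_grade"),
                )
            )
    return records


def read_manifest(
    manifest_path: PathLike, clinical_path: PathLike
) -> tuple[list[SampleRecord], list[ClinicalRecord]]:
    """Read the sample manifest and clinical table, cross-validating them.

    Every sample's patient must exist in the clinical table; sample_ids must
    be unique; within a patient, timepoint labels must be strictly ordered by
    days_from_surgery.
    """
    clinical = read_clinical_table(clinical_path)
    patients = {c.patient_id for c in clinical}

    samples: list[SampleRecord] = []
    seen: set[str] = set()
    for lineno, row in _read_rows(manifest_path, MANIFEST_COLUMNS):
        sid = row["sample_id"]
        if sid in seen:
            raise ValidationError(f"{manifest_path}:{lineno}: duplicate sample_id {sid!r}")
        seen.add(sid)
        with _wrap_validation(manifest_path, lineno):
            samples.append(
                SampleRecord(
                    sample_id=sid,
                    patient_id=row["patient_id"],
                    material=row["material"],
                    timepoint_label=row["timepoint_label"],
                    days_from_surgery=_int(row["days_from_surgery"], manifest_path, lineno, "days_from_surgery"),
                )
            )

    orphans = sorted({s.sample_id for s in samples if s.patient_id not in patients})
    if orphans:
        raise ValidationError(f"{manifest_path}: samples reference unknown patients: {', '.join(orphans)}")

    _check_timepoint_order(samples)
    return samples, clinical


def _check_timepoint_order(samples: Sequence[SampleRecord]) -> None:
    by_patient: dict[str, list[SampleRecord]] = {}
    for s in samples:
        if s.material == "plasma":
            by_patient.setdefault(s.patient_id, []).append(s)
    for pid, recs in by_patient.items():
        recs = sorted(recs, key=lambda r: timepoint_rank(r.timepoint_label))
        days = [r.days_from_surgery for r in recs]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError(
                f"patient {pid}: plasma timepoint labels are not strictly ordered by days_from_surgery"
            )


def write_manifest(samples: Iterable[SampleRecord], path: PathLike) -> None:
    _write_tsv(
        path,
        MANIFEST_COLUMNS,
        ((s.sample_id, s.patient_id, s.material, s.timepoint_label, s.days_from_surgery) for s in samples),
    )


def write_clinical_table(records: Iterable[ClinicalRecord], path: PathLike) -> None:
    def fmt(v):
        return "." if v is None else v

    _write_tsv(
        path,
        CLINICAL_COLUMNS,
        (
            (c.patient_id, c.histology, c.stage, fmt(c.tumor_purity), fmt(c.recurrence_day), fmt(c.differentiation_grade))
            for c in records
        ),
    )


# ---------------------------------------------------------------------------
# mutation tables


def read_mutation_table(path: PathLike) -> list[MutationCall]:
    calls: list[MutationCall] = []
    for lineno, row in _read_rows(path, MUTATION_COLUMNS):
        pos = _opt(row["pos"])
        with _wrap_validation(path, lineno):
            calls.append(
                MutationCall(
                    sample_id=row["sample_id"],
                    gene=row["gene"],
                    chrom=row["chrom"],
                    pos=None if pos is None else _int(pos, path, lineno, "pos"),
                    ref=row["ref"],
                    alt=row["alt"],
                    allelic_fraction=_float(row["af"], path, lineno, "af"),
                    depth=_int(row["depth"], path, lineno, "depth"),
                    chip_filtered=_bool(row["chip_filtered"], path, lineno, "chip_filtered"),
                )
            )
    return calls


def write_mutation_table(calls: Iterable[MutationCall], path: PathLike) -> None:
    _write_tsv(
        path,
        MUTATION_COLUMNS,
        (
            (
                c.sample_id,
                c.gene,
                c.chrom,
                "." if c.pos is None else c.pos,
                c.ref,
                c.alt,
                repr(c.allelic_fraction),
                c.depth,
                "true" if c.chip_filtered else "false",
            )
            for c in calls
        ),
    )
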