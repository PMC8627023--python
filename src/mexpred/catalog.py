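"""Record types and eligibility filters for microexons and microindels.

Coordinates are 0-based half-open throughout the package. VCF input
(1-based, anchor-base convention) is converted on read; BED output is
emitted unchanged.

A *microindel* is a small insertion or deletion; it is non-frameshifting
(NFS) when its length is a multiple of three and at most 30 nt. A
*microexon* is an exon of 3-30 nt; the eligible (frame-preserving) ones
are those whose length is a multiple of three, that lie in the coding
sequence, and that do not introduce a stop codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

NFS_MIN_LENGTH = 3
NFS_MAX_LENGTH = 30

_VALID_STRANDS = {"+", "-", "."}
_VALID_KINDS = {"deletion", "insertion"}
_VALID_LABELS = {"functional", "neutral", "unknown"}


class DataError(ValueError):
    """Unrecoverable problem with an input file or record collection."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval.

    Insertions are represented as zero-length intervals anchored at the
    0-based position immediately after the VCF anchor base (``end ==
    start``); deletions and exons have ``end > start``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MicroindelRecord:
    """A small insertion or deletion with an optional functional label."""

    interval: GenomicInterval
    kind: str
    indel_length: int
    label: str = "unknown"
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"invalid kind {self.kind!r}")
        if self.label not in _VALID_LABELS:
            raise ValueError(f"invalid label {self.label!r}")
        if self.indel_length <= 0:
            raise ValueError("indel_length must be positive")
        if self.kind == "deletion" and self.indel_length != len(self.interval):
            raise ValueError(
                "deletion length must equal interval span "
                f"({self.indel_length} != {len(self.interval)})"
            )
        if self.kind == "insertion" and len(self.interval) != 0:
            raise ValueError("insertions must have zero-length intervals")

    @property
    def is_nfs(self) -> bool:
        """True when the indel is non-frameshifting and micro-scale."""
        return (
            NFS_MIN_LENGTH <= self.indel_length <= NFS_MAX_LENGTH
            and self.indel_length % 3 == 0
        )


@dataclass(frozen=True)
class MicroexonRecord:
    """A short exon with the flags needed by the eligibility filter."""

    interval: GenomicInterval
    exon_length: int
    in_cds: bool = True
    contains_stop: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.exon_length != len(self.interval):
            raise ValueError(
                "exon_length must equal interval span "
                f"({self.exon_length} != {len(self.interval)})"
            )

    @property
    def frame_preserving(self) -> bool:
        return self.exon_length % 3 == 0

    @property
    def is_nfs(self) -> bool:
        """True when the exon is an eligible frame-preserving microexon."""
        return (
            NFS_MIN_LENGTH <= self.exon_length <= NFS_MAX_LENGTH
            and self.frame_preserving
            and self.in_cds
            and not self.contains_stop
        )


# ---------------------------------------------------------------------------
# readers


def _indel_from_alleles(
    chrom: str, pos0: int, ref: str, alt: str, label: str, name: str = ""
) -> MicroindelRecord | None:
    """Classify a biallelic VCF REF/ALT pair as a pure indel.

    ``pos0`` is the 0-based position of the VCF anchor base. Alleles are
    normalized by trimming the shared suffix then prefix (so alleles
    from split multi-allelic rows resolve too); anything that is not a
    pure insertion or deletion after trimming returns None (caller
    logs/counts).
    """
    suffix = 0
    while (
        len(ref) - suffix > 1
        and len(alt) - suffix > 1
        and ref[-1 - suffix] == alt[-1 - suffix]
    ):
        suffix += 1
    ref_t = ref[: len(ref) - suffix]
    alt_t = alt[: len(alt) - suffix]
    prefix = 0
    while prefix < len(ref_t) and prefix < len(alt_t) and ref_t[prefix] == alt_t[prefix]:
        prefix += 1
    ref_rem = ref_t[prefix:]
    alt_rem = alt_t[prefix:]
    if ref_rem and not alt_rem:  # pure deletion
        start = pos0 + prefix
        interval = GenomicInterval(chrom, start, start + len(ref_rem))
        return MicroindelRecord(interval, "deletion", len(ref_rem), label, name)
    if alt_rem and not ref_rem:  # pure insertion, anchored after the prefix
        start = pos0 + prefix
        interval = GenomicInterval(chrom, start, start)
        return MicroindelRecord(interval, "insertion", len(alt_rem), label, name)
    return None  # SNV, MNV or complex allele


def _read_microindels_vcf(path: Path, label: str) -> list[MicroindelRecord]:
    import pysam

    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot read VCF {path}: {exc}") from exc
    records: list[MicroindelRecord] = []
    skipped = 0
    with vcf:
        for row in vcf:
            alts = row.alts or ()
            for alt in alts:  # multi-allelic rows split into biallelic pairs
                if alt is None or row.ref is None:
                    skipped += 1
                    continue
                rec = _indel_from_alleles(
                    row.chrom, row.pos - 1, row.ref, alt, label, row.id or ""
                )
                if rec is None:
                    skipped += 1
                else:
                    records.append(rec)
    if skipped:
        logger.warning("%s: skipped %d non-indel or complex alleles", path, skipped)
    return records


_INDEL_TSV_REQUIRED = ["chrom", "start", "end", "kind", "length"]


def _read_microindels_tsv(path: Path, label: str) -> list[MicroindelRecord]:
    try:
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except (OSError, pd.errors.ParserError) as exc:
        raise DataError(f"cannot read indel table {path}: {exc}") from exc
    missing = [c for c in _INDEL_TSV_REQUIRED if c not in table.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    records = []
    skipped = 0
    for row in table.itertuples(index=False):
        row_label = getattr(row, "label", label) or label
        try:
            interval = GenomicInterval(
                str(row.chrom), int(row.start), int(row.end),
                getattr(row, "strand", "."),
            )
            records.append(
                MicroindelRecord(
                    interval, str(row.kind), int(row.length),
                    str(row_label), str(getattr(row, "name", "") or ""),
                )
            )
        except (ValueError, TypeError) as exc:
            skipped += 1
            logger.warning("%s: skipping malformed row %r (%s)", path, row, exc)
    if skipped:
        logger.warning("%s: skipped %d malformed rows", path, skipped)
    return records


def read_microindels(path: str | Path, label: str = "unknown") -> list[MicroindelRecord]:
    """Read microindels from a VCF (``.vcf``) or flat TSV file.

    ``label`` is assigned to every record unless the TSV carries its own
    ``label`` column. VCF 1-based positions are converted to the internal
    0-based convention; multi-allelic rows are split and non-indel
    alleles are skipped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if label not in _VALID_LABELS:
        raise ValueError(f"invalid label {label!r}")
    if path.suffix.lower() == ".vcf" or str(path).endswith(".vcf.gz"):
        return _read_microindels_vcf(path, label)
    return _read_microindels_tsv(path, label)


def read_microexons(path: str | Path) -> list[MicroexonRecord]:
    """Read microexons from a BED file or a flat TSV.

    The TSV dialect requires ``chrom, start, end`` and optionally
    ``in_cds, contains_stop, name, strand``; BED6 input sets the flags
    to their permissive defaults (in CDS, no stop codon).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if path.suffix.lower() == ".bed":
        records = []
        for interval, name in _iter_bed(path):
            records.append(
                MicroexonRecord(interval, len(interval), name=name)
            )
        return records
    try:
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except (OSError, pd.errors.ParserError) as exc:
        raise DataError(f"cannot read exon table {path}: {exc}") from exc
    missing = [c for c in ("chrom", "start", "end") if c not in table.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    records = []
    for row in table.itertuples(index=False):
        interval = GenomicInterval(
            str(row.chrom), int(row.start), int(row.end),
            getattr(row, "strand", "."),
        )
        records.append(
            MicroexonRecord(
                interval,
                len(interval),
                in_cds=bool(getattr(row, "in_cds", True)),
                contains_stop=bool(getattr(row, "contains_stop", False)),
                name=str(getattr(row, "name", "") or ""),
            )
        )
    return records


# ---------------------------------------------------------------------------
# filters


def filter_nfs_microindels(
    records: Iterable[MicroindelRecord],
) -> list[MicroindelRecord]:
    """Keep non-frameshifting microindels (3-30 nt, multiple of 3).

    Order is preserved; the filter is idempotent.
    """
    return [r for r in records if r.is_nfs]


def filter_nfs_microexons(
    records: Iterable[MicroexonRecord],
) -> list[MicroexonRecord]:
    """Keep eligible microexons: 3-30 nt, frame-preserving, coding, no stop."""
    return [r for r in records if r.is_nfs]


# ---------------------------------------------------------------------------
# BED I/O


def write_bed(
    records: Sequence[MicroindelRecord | MicroexonRecord],
    path: str | Path,
    probabilities: Sequence[float] | None = None,
) -> None:
    """Write records as 6-column BED (0-based half-open).

    The score column carries ``round(probability * 1000)`` when
    probabilities are given, else 0.
    """
    if probabilities is not None and len(probabilities) != len(records):
        raise ValueError("probabilities length must match records")
    path = Path(path)
    try:
        with path.open("w") as handle:
            for i, rec in enumerate(records):
                iv = rec.interval
                name = rec.name or f"record{i}"
                score = 0 if probabilities is None else round(probabilities[i] * 1000)
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )
    except OSError as exc:
        raise DataError(f"cannot write BED {path}: {exc}") from exc


def _iter_bed(path: Path):
    with path.open() as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}: malformed BED line {line!r}")
            strand = parts[5] if len(parts) >= 6 and parts[5] in _VALID_STRANDS else "."
            interval = GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand)
            name = parts[3] if len(parts) >= 4 else ""
            yield interval, name


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read intervals from a BED file (names dropped)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    return [interval for interval, _ in _iter_bed(path)]
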