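"""Genomic interval model, BED / variant-table I/O, and the overlap engine.

Coordinates follow the two standards they come from: intervals are BED-style
0-based half-open ``[start, end)``; variant positions are VCF-style 1-based
and converted at assignment time. Strand is carried for reporting but ignored
by all overlap logic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "VariantRecord",
    "Track",
    "read_bed",
    "write_bed",
    "read_variants",
    "overlaps",
    "assign_variants",
    "normalize_chrom",
]

_VALID_STRANDS = {"+", "-", "."}
_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A located genomic segment: 0-based half-open ``[start, end)``."""

    chrom: str
    start: int
    end: int
    region_id: str
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(
                f"negative start {self.start} for region {self.region_id!r}"
            )
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval [{self.start}, {self.end}) "
                f"for region {self.region_id!r}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {_VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def padded(self, padding_bp: int) -> "GenomicInterval":
        """Return the interval widened by ``padding_bp`` on each side, clipped at 0."""
        if padding_bp < 0:
            raise ValueError("padding_bp must be >= 0")
        return GenomicInterval(
            self.chrom,
            max(0, self.start - padding_bp),
            self.end + padding_bp,
            f"{self.region_id}+-{padding_bp}bp",
            self.strand,
        )


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """A somatic single-nucleotide variant; ``pos`` is 1-based (VCF convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_id: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        for base, label in ((self.ref, "ref"), (self.alt, "alt")):
            if base not in _BASES:
                raise ValueError(f"{label} must be a single base A/C/G/T, got {base!r}")

    @property
    def pos0(self) -> int:
        """0-based coordinate of the variant base."""
        return self.pos - 1


@dataclass(slots=True)
class Track:
    """A named collection of intervals (a peak set or similar annotation)."""

    name: str
    category: str = "other"
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in {"histone", "tf", "dhs", "other"}:
            raise ValueError(f"unknown track category {self.category!r}")


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed; carries the line number."""


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4/BED6 into intervals, preserving file order.

    Missing name columns are auto-assigned ``chrom:start-end``. Lines starting
    with ``#``, ``track`` or ``browser`` and blank lines are skipped.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    seen_ids: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else (
                f"{chrom}:{start}-{end}"
            )
            strand = fields[5] if len(fields) >= 6 and fields[5] in _VALID_STRANDS else "."
            try:
                iv = GenomicInterval(chrom, start, end, name, strand)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            if iv.region_id in seen_ids:
                raise BedParseError(
                    f"{path}:{lineno}: duplicate region_id {iv.region_id!r}"
                )
            seen_ids.add(iv.region_id)
            intervals.append(iv)
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (score column fixed at 0)."""
    with Path(path).open("w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.region_id}\t0\t{iv.strand}\n")


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read SNVs from a 5-column TSV (CHROM POS REF ALT TUMOR_ID) or minimal VCF.

    VCF is detected by the ``##fileformat`` header; the tumor/donor identifier
    is taken from the first sample column (column 10) when present, otherwise
    from the ID column. Only single-nucleotide REF/ALT records are accepted.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        return _read_vcf(path)
    return _read_variant_tsv(path)


def _read_variant_tsv(path: Path) -> list[VariantRecord]:
    variants: list[VariantRecord] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].upper() in {"CHROM", "#CHROM"}:
                continue  # header row
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns CHROM POS REF ALT TUMOR_ID")
            variants.append(
                VariantRecord(fields[0], int(fields[1]), fields[2], fields[3], fields[4])
            )
    return variants


def _read_vcf(path: Path) -> list[VariantRecord]:
    variants: list[VariantRecord] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: truncated VCF record")
            chrom, pos, vid, ref, alt = fields[:5]
            if len(ref) != 1 or len(alt) != 1:
                continue  # indels / multiallelic out of scope
            tumor = fields[9] if len(fields) >= 10 else vid
            variants.append(VariantRecord(chrom, int(pos), ref, alt, tumor))
    return variants


def normalize_chrom(name: str) -> str:
    """Map chromosome-name dialects onto the ``chr``-prefixed convention."""
    return name if name.startswith("chr") else f"chr{name}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def assign_variants(
    variants: Sequence[VariantRecord],
    regions: Sequence[GenomicInterval],
    normalize_chroms: bool = False,
) -> dict[str, list[VariantRecord]]:
    """Map each region_id to the variants whose base falls inside it.

    A variant at 1-based ``pos`` hits a region iff ``pos - 1`` lies in
    ``[start, end)``; a variant overlapping several regions is assigned to all
    of them. Regions without variants map to empty lists. When chromosome-name
    dialects disagree between the two inputs (``chr1`` vs ``1``) nothing is
    assigned and a warning is emitted, unless ``normalize_chroms`` is set.
    """
    key = normalize_chrom if normalize_chroms else (lambda c: c)
    trees: dict[str, IntervalTree] = {}
    for region in regions:
        trees.setdefault(key(region.chrom), IntervalTree()).addi(
            region.start, region.end, region.region_id
        )
    assigned: dict[str, list[VariantRecord]] = {r.region_id: [] for r in regions}
    n_hits = 0
    for var in variants:
        tree = trees.get(key(var.chrom))
        if tree is None:
            continue
        for hit in sorted(tree[var.pos0], key=lambda h: (h.begin, h.end, h.data)):
            assigned[hit.data].append(var)
            n_hits += 1
    if variants and regions and n_hits == 0 and not normalize_chroms:
        region_styles = {c.startswith("chr") for c in trees}
        variant_styles = {v.chrom.startswith("chr") for v in variants}
        if region_styles and variant_styles and region_styles.isdisjoint(variant_styles):
            warnings.warn(
                "no variant assigned and chromosome-name styles differ between "
                "variants and regions; pass normalize_chroms=True to reconcile "
                "'chr14' vs '14' dialects",
                stacklevel=2,
            )
    return assigned
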