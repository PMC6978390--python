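"""Region-by-track annotation, active-CRE filtering, and the stage-count cascade.

The cascade mirrors how candidate regulatory elements are narrowed down:
all DHS in the padded TAD window -> plexus members (anchor correlation above
threshold) -> active members (overlap with an activity mark such as primary
tumor H3K27ac) -> mutated members (harboring one or more somatic SNVs), with
tallies of variants and distinct tumors at the final stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import GenomicInterval, Track, VariantRecord, assign_variants
from .plexus import PlexusResult, candidate_regions, infer_plexus
from .signal import SignalMatrix

__all__ = [
    "AnnotationMatrix",
    "CascadeReport",
    "build_annotation_matrix",
    "call_active",
    "run_cascade",
    "percent_one_decimal",
]


def percent_one_decimal(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (6/33 -> 18.2)."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero; percentage undefined")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class AnnotationMatrix:
    """Boolean region x track overlap matrix in input order."""

    region_ids: list[str]
    track_names: list[str]
    cells: np.ndarray  # bool, shape (n_regions, n_tracks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells.astype(int),
            index=pd.Index(self.region_ids, name="region_id"),
            columns=self.track_names,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class CascadeReport:
    """Counts surviving each filter stage plus mutation tallies."""

    n_dhs_in_window: int
    n_plexus_members: int
    n_active: int
    n_mutated: int
    n_variants: int
    n_tumors: int

    def __post_init__(self) -> None:
        stages = (self.n_dhs_in_window, self.n_plexus_members,
                  self.n_active, self.n_mutated)
        if any(a < b for a, b in zip(stages, stages[1:])):
            raise ValueError(f"cascade counts must be non-increasing, got {stages}")
        if self.n_variants < self.n_mutated:
            raise ValueError("cannot have fewer variants than mutated regions")

    @property
    def fraction_mutated(self) -> float | None:
        """n_mutated / n_active, or None when no region is active."""
        if self.n_active == 0:
            return None
        return self.n_mutated / self.n_active

    @property
    def fraction_mutated_pct(self) -> float | None:
        """fraction_mutated as a half-up one-decimal percentage."""
        if self.n_active == 0:
            return None
        return percent_one_decimal(self.n_mutated, self.n_active)

    def as_dict(self) -> dict:
        return {
            "n_dhs_in_window": self.n_dhs_in_window,
            "n_plexus_members": self.n_plexus_members,
            "n_active": self.n_active,
            "n_mutated": self.n_mutated,
            "n_variants": self.n_variants,
            "n_tumors": self.n_tumors,
            "fraction_mutated": self.fraction_mutated,
            "fraction_mutated_pct": self.fraction_mutated_pct,
        }

    def text(self) -> str:
        pct = self.fraction_mutated_pct
        lines = [
            "CRE filter cascade",
            f"  DHS in padded TAD window : {self.n_dhs_in_window}",
            f"  plexus members (r>thr)   : {self.n_plexus_members}",
            f"  active (activity-marked) : {self.n_active}",
            f"  mutated (>=1 SNV)        : {self.n_mutated}",
            f"  SNVs in mutated CREs     : {self.n_variants}",
            f"  distinct tumors          : {self.n_tumors}",
            f"  mutated / active         : "
            + ("n/a" if pct is None else f"{pct}%"),
        ]
        return "\n".join(lines) + "\n"


def build_annotation_matrix(
    regions: Sequence[GenomicInterval], tracks: Sequence[Track]
) -> AnnotationMatrix:
    """True iff a region overlaps >=1 interval of a track; orders preserved."""
    names = [t.name for t in tracks]
    if len(set(names)) != len(names):
        raise ValueError("track names must be unique")
    cells = np.zeros((len(regions), len(tracks)), dtype=bool)
    for j, track in enumerate(tracks):
        trees: dict[str, IntervalTree] = {}
        for iv in track.intervals:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        for i, region in enumerate(regions):
            tree = trees.get(region.chrom)
            cells[i, j] = bool(tree and tree.overlap(region.start, region.end))
    return AnnotationMatrix([r.region_id for r in regions], names, cells)


def call_active(
    members: Sequence[GenomicInterval], activity_track: Track
) -> list[GenomicInterval]:
    """Members overlapping at least one activity-mark peak, in input order."""
    if activity_track.category != "histone":
        raise ValueError(
            f"activity track must be a histone mark, got {activity_track.category!r}"
        )
    trees: dict[str, IntervalTree] = {}
    for iv in activity_track.intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    out = []
    for region in members:
        tree = trees.get(region.chrom)
        if tree and tree.overlap(region.start, region.end):
            out.append(region)
    return out


@dataclass
class CascadeOutput:
    """Cascade report plus the per-stage region sets behind it."""

    report: CascadeReport
    plexus: PlexusResult
    active: list[GenomicInterval]
    mutated: list[GenomicInterval]
    variants_by_region: dict[str, list[VariantRecord]]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "cascade.json").write_text(
            json.dumps(self.report.as_dict(), indent=2) + "\n"
        )
        (out / "cascade.txt").write_text(self.report.text())


def run_cascade(
    dhs: Sequence[GenomicInterval],
    tad: GenomicInterval,
    padding_bp: int,
    matrix: SignalMatrix,
    anchor_id: str,
    threshold: float,
    activity_track: Track,
    variants: Sequence[VariantRecord],
) -> CascadeOutput:
    """Compose candidate selection, plexus inference, activity and SNV filters."""
    window_dhs = candidate_regions(dhs, tad, padding_bp)
    plexus = infer_plexus(matrix, anchor_id, window_dhs, threshold, padding_bp)
    active = call_active(plexus.members, activity_track)
    assigned = assign_variants(variants, active)
    mutated = [r for r in active if assigned[r.region_id]]
    hit_variants = [v for r in mutated for v in assigned[r.region_id]]
    # a variant spanning two overlapping mutated regions is tallied once
    unique_hits = sorted(set(hit_variants),
                         key=lambda v: (v.chrom, v.pos, v.tumor_id, v.alt))
    report = CascadeReport(
        n_dhs_in_window=len(window_dhs),
        n_plexus_members=plexus.n_members,
        n_active=len(active),
        n_mutated=len(mutated),
        n_variants=len(unique_hits),
        n_tumors=len({v.tumor_id for v in unique_hits}),
    )
    return CascadeOutput(report, plexus, active, mutated, assigned)
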