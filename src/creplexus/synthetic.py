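"""Synthetic fixtures with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes: a
multi-cell-type accessibility panel in which a designated anchor region and a
planted member set share a target correlation; independent background regions
inside the TAD and distractors in the flanks; peak tracks marking a chosen
subset of members; somatic SNVs planted inside a subset of marked members;
and an essentiality score table in which a designated group is shifted toward
essentiality. Every call is driven by a single seed and writes/returns a
truth manifest, so downstream stages can be checked against construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import GenomicInterval, Track, VariantRecord, write_bed
from .signal import SignalMatrix
from .essentiality import ScoreTable

__all__ = [
    "PlantedTruth",
    "simulate_accessibility_panel",
    "simulate_tracks_and_variants",
    "simulate_essentiality",
    "write_fixture",
]

_BASES = np.array(list("ACGT"))

# region layout: fixed-width DHS with random gaps, exercising padding logic
REGION_WIDTH = 500
MIN_GAP, MAX_GAP = 200, 2_000
TAD_START = 1_000_000
FLANK_OFFSET = 100_000  # distractors this far beyond the padded window


@dataclass
class PlantedTruth:
    """Ground-truth manifest written alongside every synthetic fixture."""

    anchor_id: str
    member_ids: list[str]
    rho: float
    tad: GenomicInterval
    background_ids: list[str] = field(default_factory=list)
    flank_ids: list[str] = field(default_factory=list)
    marked_ids: list[str] = field(default_factory=list)
    mutated_ids: list[str] = field(default_factory=list)
    variants: list[VariantRecord] = field(default_factory=list)
    essential_group: list[str] = field(default_factory=list)
    effect_delta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.rho <= 1.0:
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")
        if not set(self.mutated_ids) <= set(self.marked_ids) <= set(self.member_ids):
            raise ValueError("need mutated_ids <= marked_ids <= member_ids")

    @property
    def n_tumors(self) -> int:
        return len({v.tumor_id for v in self.variants})

    def expected_cascade(self) -> dict[str, int]:
        """Stage counts a correct cascade run must reproduce."""
        return {
            "n_plexus_members": len(self.member_ids),
            "n_active": len(self.marked_ids),
            "n_mutated": len(self.mutated_ids),
            "n_variants": len(self.variants),
            "n_tumors": self.n_tumors,
        }

    def to_json(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["tad"] = asdict(self.tad)
        doc["variants"] = [asdict(v) for v in self.variants]
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        doc = json.loads(Path(path).read_text())
        doc["tad"] = GenomicInterval(**doc["tad"])
        doc["variants"] = [VariantRecord(**v) for v in doc["variants"]]
        return cls(**doc)


def _layout_regions(
    rng: np.random.Generator, n_inside: int, n_flank: int, chrom: str
) -> tuple[list[tuple[int, int]], GenomicInterval, list[tuple[int, int]]]:
    """Place fixed-width regions with random gaps inside a TAD, plus flanks."""
    coords = []
    pos = TAD_START
    for _ in range(n_inside):
        pos += int(rng.integers(MIN_GAP, MAX_GAP + 1))
        coords.append((pos, pos + REGION_WIDTH))
        pos += REGION_WIDTH
    tad_end = pos + int(rng.integers(MIN_GAP, MAX_GAP + 1))
    tad = GenomicInterval(chrom, TAD_START, tad_end, "TAD1")
    flank = []
    fpos = tad_end + FLANK_OFFSET
    for _ in range(n_flank):
        fpos += int(rng.integers(MIN_GAP, MAX_GAP + 1))
        flank.append((fpos, fpos + REGION_WIDTH))
        fpos += REGION_WIDTH
    return coords, tad, flank


def simulate_accessibility_panel(
    n_background: int = 200,
    n_members: int = 10,
    n_celltypes: int = 50,
    rho: float = 0.95,
    seed: int | None = None,
    n_flank: int = 10,
    chrom: str = "chr14",
    padding_bp: int = 40_000,
) -> tuple[SignalMatrix, list[GenomicInterval], PlantedTruth]:
    """Accessibility panel with a planted anchor-correlated member set.

    The anchor profile is i.i.d. standard normal across cell types; each
    member profile is ``rho * anchor + sqrt(1 - rho^2) * noise`` so its
    population correlation with the anchor is exactly ``rho``. Background
    profiles are independent. The whole matrix is shifted by one global
    constant to non-negative values, which leaves every Pearson correlation
    unchanged. Anchor, members and background sit inside a generated TAD;
    ``n_flank`` extra independent regions sit beyond the padded window so
    candidate selection is exercised.
    """
    if n_celltypes < 5:
        raise ValueError("need >= 5 cell types")
    if not 0.0 < rho <= 1.0:
        raise ValueError(f"rho must be in (0, 1], got {rho}")
    rng = np.random.default_rng(seed)

    n_inside = 1 + n_members + n_background
    inside, tad, flank = _layout_regions(rng, n_inside, n_flank, chrom)

    # interleave member/background placement so members are not positionally
    # clustered, with the anchor at the leftmost region (a promoter-like spot)
    roles = np.array(["member"] * n_members + ["background"] * n_background)
    rng.shuffle(roles)

    regions: list[GenomicInterval] = []
    anchor_id = "anchor"
    member_ids: list[str] = []
    background_ids: list[str] = []
    rows: list[np.ndarray] = []

    anchor_profile = rng.standard_normal(n_celltypes)
    regions.append(GenomicInterval(chrom, *inside[0], anchor_id))
    rows.append(anchor_profile)
    for (start, end), role in zip(inside[1:], roles):
        if role == "member":
            rid = f"member_{len(member_ids) + 1:03d}"
            member_ids.append(rid)
            noise = rng.standard_normal(n_celltypes)
            profile = rho * anchor_profile + np.sqrt(1 - rho**2) * noise
        else:
            rid = f"background_{len(background_ids) + 1:03d}"
            background_ids.append(rid)
            profile = rng.standard_normal(n_celltypes)
        regions.append(GenomicInterval(chrom, start, end, rid))
        rows.append(profile)

    flank_ids: list[str] = []
    for i, (start, end) in enumerate(flank, start=1):
        rid = f"flank_{i:03d}"
        flank_ids.append(rid)
        regions.append(GenomicInterval(chrom, start, end, rid))
        rows.append(rng.standard_normal(n_celltypes))

    values = np.vstack(rows)
    values = values - min(values.min(), 0.0)  # global shift; r-invariant
    matrix = SignalMatrix(
        [r.region_id for r in regions],
        [f"celltype_{j + 1:02d}" for j in range(n_celltypes)],
        values,
    )
    truth = PlantedTruth(anchor_id, member_ids, rho, tad,
                         background_ids=background_ids, flank_ids=flank_ids)
    return matrix, regions, truth


def simulate_tracks_and_variants(
    truth: PlantedTruth,
    regions: Sequence[GenomicInterval],
    marked_fraction: float = 0.65,
    mutated_count: int = 3,
    variants_per_region: int | Sequence[int] = 1,
    n_tumors: int = 3,
    seed: int | None = None,
    n_tf_tracks: int = 2,
) -> tuple[list[Track], list[VariantRecord], PlantedTruth]:
    """Plant an activity mark on a member subset and SNVs in a marked subset.

    Activity peaks cover exactly the marked members, jittered to extend past
    the region edges. SNV positions are uniform within each mutated region;
    the first ``n_tumors`` variants each come from a distinct tumor so the
    realized distinct-tumor count equals ``n_tumors`` exactly. A few TF peak
    tracks covering random region subsets are included for annotation only.
    """
    if not 0.0 <= marked_fraction <= 1.0:
        raise ValueError("marked_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    by_id = {r.region_id: r for r in regions}

    n_marked = int(round(marked_fraction * len(truth.member_ids)))
    if mutated_count > n_marked:
        raise ValueError(
            f"mutated_count {mutated_count} exceeds marked count {n_marked}"
        )
    marked = sorted(rng.choice(truth.member_ids, size=n_marked, replace=False))
    mutated = sorted(rng.choice(marked, size=mutated_count, replace=False))

    peaks = []
    for i, rid in enumerate(marked, start=1):
        region = by_id[rid]
        left = int(rng.integers(10, 100))
        right = int(rng.integers(10, 100))
        peaks.append(GenomicInterval(region.chrom, region.start - left,
                                     region.end + right, f"h3k27ac_peak_{i:03d}"))
    activity = Track("H3K27ac_tumor", "histone", peaks)

    if isinstance(variants_per_region, int):
        counts = [variants_per_region] * len(mutated)
    else:
        counts = list(variants_per_region)
        if len(counts) != len(mutated):
            raise ValueError(
                f"variants_per_region has {len(counts)} entries for "
                f"{len(mutated)} mutated regions"
            )
    total = sum(counts)
    if total < n_tumors:
        raise ValueError(
            f"cannot realize {n_tumors} distinct tumors from {total} variants"
        )
    tumor_pool = [f"tumor_{t + 1:03d}" for t in range(n_tumors)]
    tumor_assignment = tumor_pool + [
        tumor_pool[int(rng.integers(n_tumors))] for _ in range(total - n_tumors)
    ]
    rng.shuffle(tumor_assignment)

    variants: list[VariantRecord] = []
    vi = 0
    for rid, count in zip(mutated, counts):
        region = by_id[rid]
        offsets = rng.choice(region.length, size=count, replace=False)
        for off in sorted(int(o) for o in offsets):
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            variants.append(
                VariantRecord(region.chrom, region.start + off + 1,
                              str(ref), str(alt), tumor_assignment[vi])
            )
            vi += 1

    tf_tracks = []
    annotatable = list(truth.member_ids) + list(truth.background_ids)
    for t in range(n_tf_tracks):
        n_bound = max(1, len(annotatable) // 4)
        bound = rng.choice(annotatable, size=n_bound, replace=False)
        tf_peaks = [
            GenomicInterval(by_id[rid].chrom,
                            by_id[rid].start - int(rng.integers(10, 100)),
                            by_id[rid].end + int(rng.integers(10, 100)),
                            f"tf{t + 1}_peak_{i:03d}")
            for i, rid in enumerate(sorted(bound), start=1)
        ]
        tf_tracks.append(Track(f"TF_{t + 1}", "tf", tf_peaks))

    updated = PlantedTruth(
        truth.anchor_id, truth.member_ids, truth.rho, truth.tad,
        background_ids=truth.background_ids, flank_ids=truth.flank_ids,
        marked_ids=list(marked), mutated_ids=list(mutated), variants=variants,
        essential_group=truth.essential_group, effect_delta=truth.effect_delta,
    )
    return [activity, *tf_tracks], variants, updated


def simulate_essentiality(
    n_lines: int = 707,
    group_size: int = 8,
    effect_delta: float = 1.5,
    seed: int | None = None,
    force_extreme: bool = False,
) -> tuple[ScoreTable, list[str]]:
    """Essentiality score table with a group shifted toward essentiality.

    Background scores are i.i.d. standard normal; the designated group is
    shifted by ``-effect_delta`` (lower = more essential). With
    ``force_extreme`` the group scores are instead placed strictly below the
    background minimum, making the group unambiguously the most essential.
    """
    if group_size > n_lines:
        raise ValueError("group_size exceeds n_lines")
    rng = np.random.default_rng(seed)
    ids = [f"line_{i + 1:04d}" for i in range(n_lines)]
    scores = rng.standard_normal(n_lines)
    group = [ids[i] for i in rng.choice(n_lines, size=group_size, replace=False)]
    group_idx = [ids.index(g) for g in group]
    if force_extreme:
        background_min = np.delete(scores, group_idx).min() if (
            group_size < n_lines
        ) else scores.min()
        scores[group_idx] = background_min - 1.0 - rng.random(group_size)
    else:
        scores[group_idx] -= effect_delta
    return ScoreTable(ids, scores), sorted(group)


def write_fixture(
    out_dir: str | Path,
    seed: int,
    n_background: int = 200,
    n_members: int = 10,
    n_celltypes: int = 50,
    rho: float = 0.95,
    marked_fraction: float = 0.65,
    mutated_count: int = 3,
    variants_per_region: int | Sequence[int] = 1,
    n_tumors: int = 3,
    n_lines: int = 707,
    group_size: int = 8,
    effect_delta: float = 1.5,
    force_extreme: bool = False,
) -> PlantedTruth:
    """Write a complete fixture directory: BED/TSV inputs plus truth.json.

    Files: dhs.bed, tads.bed, matrix.tsv, tracks/*.bed, snvs.tsv, scores.csv,
    group.txt, truth.json — the inputs a full pipeline run consumes.
    """
    out = Path(out_dir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    matrix, regions, truth = simulate_accessibility_panel(
        n_background, n_members, n_celltypes, rho, seed=seed
    )
    tracks, variants, truth = simulate_tracks_and_variants(
        truth, regions, marked_fraction, mutated_count, variants_per_region,
        n_tumors, seed=seed + 1,
    )
    scores, group = simulate_essentiality(
        n_lines, group_size, effect_delta, seed=seed + 2,
        force_extreme=force_extreme,
    )
    truth.essential_group = group
    truth.effect_delta = effect_delta

    write_bed(regions, out / "dhs.bed")
    write_bed([truth.tad], out / "tads.bed")
    matrix.to_tsv(out / "matrix.tsv")
    for track in tracks:
        write_bed(track.intervals, out / "tracks" / f"{track.name}.bed")
    with (out / "snvs.tsv").open("w") as fh:
        fh.write("CHROM\tPOS\tREF\tALT\tTUMOR_ID\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.tumor_id}\n")
    scores.to_csv(out / "scores.csv")
    (out / "group.txt").write_text("\n".join(group) + "\n")
    truth.to_json(out / "truth.json")
    return truth
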