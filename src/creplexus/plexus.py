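"""TAD-constrained candidate selection and correlation-threshold plexus inference.

The regulatory plexus of a gene is inferred by anchoring on its promoter DHS
and keeping every accessible region, within the containing TAD padded by the
Hi-C map resolution, whose accessibility profile across cell types correlates
with the anchor's at Pearson r strictly above a threshold (default 0.7).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import math

import pandas as pd

from .genome import GenomicInterval, overlaps
from .signal import SignalMatrix, correlate_with_anchor

__all__ = ["PlexusCandidate", "PlexusResult", "candidate_regions", "infer_plexus",
           "DEFAULT_THRESHOLD", "DEFAULT_PADDING_BP"]

DEFAULT_THRESHOLD = 0.7
DEFAULT_PADDING_BP = 40_000  # Hi-C map resolution


@dataclass(frozen=True)
class PlexusCandidate:
    region: GenomicInterval
    r: float                # NaN when undefined
    included: bool
    reason: str             # "member" | "below_threshold" | "undefined_r"


@dataclass
class PlexusResult:
    anchor: GenomicInterval
    candidates: list[PlexusCandidate]
    threshold: float
    padding_bp: int

    @property
    def members(self) -> list[GenomicInterval]:
        return [c.region for c in self.candidates if c.included]

    @property
    def n_members(self) -> int:
        return sum(c.included for c in self.candidates)

    @property
    def n_undefined(self) -> int:
        return sum(c.reason == "undefined_r" for c in self.candidates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": [c.region.region_id for c in self.candidates],
                "chrom": [c.region.chrom for c in self.candidates],
                "start": [c.region.start for c in self.candidates],
                "end": [c.region.end for c in self.candidates],
                "r": [c.r for c in self.candidates],
                "included": [c.included for c in self.candidates],
                "reason": [c.reason for c in self.candidates],
            }
        )

    def summary(self) -> dict:
        return {
            "anchor": self.anchor.region_id,
            "threshold": self.threshold,
            "padding_bp": self.padding_bp,
            "n_candidates": len(self.candidates),
            "n_members": self.n_members,
            "n_undefined_r": self.n_undefined,
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "plexus.tsv", sep="\t", index=False,
                               float_format="%.6f")
        (out / "plexus_summary.json").write_text(
            json.dumps(self.summary(), indent=2) + "\n"
        )


def candidate_regions(
    dhs: Sequence[GenomicInterval],
    tad: GenomicInterval,
    padding_bp: int = DEFAULT_PADDING_BP,
) -> list[GenomicInterval]:
    """DHS overlapping the TAD widened by ``padding_bp`` on each side.

    Any overlap with the half-open padded window counts; input order is kept.
    """
    window = tad.padded(padding_bp)
    return [d for d in dhs if overlaps(d, window)]


def infer_plexus(
    m: SignalMatrix,
    anchor_id: str,
    candidates: Sequence[GenomicInterval],
    threshold: float = DEFAULT_THRESHOLD,
    padding_bp: int = DEFAULT_PADDING_BP,
) -> PlexusResult:
    """Threshold anchor correlations over the candidate regions.

    Members are candidates with a defined correlation strictly greater than
    ``threshold``. The anchor is never a member of its own candidate list;
    candidates with undefined r are reported with a reason code.
    """
    if not -1.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (-1, 1), got {threshold}")
    matrix_ids = set(m.region_ids)
    if anchor_id not in matrix_ids:
        raise KeyError(f"anchor {anchor_id!r} not in matrix")
    missing = [c.region_id for c in candidates if c.region_id not in matrix_ids]
    if missing:
        raise KeyError(f"candidates absent from matrix: {missing[:5]}")

    corr = correlate_with_anchor(m, anchor_id)
    r_of = corr.as_dict()
    anchor_region = next(
        (c for c in candidates if c.region_id == anchor_id), None
    ) or GenomicInterval("unknown", 0, 1, anchor_id)

    out: list[PlexusCandidate] = []
    for region in candidates:
        if region.region_id == anchor_id:
            continue  # the anchor is not a candidate for its own plexus
        r = r_of[region.region_id]
        if math.isnan(r):
            out.append(PlexusCandidate(region, r, False, "undefined_r"))
        elif r > threshold:
            out.append(PlexusCandidate(region, r, True, "member"))
        else:
            out.append(PlexusCandidate(region, r, False, "below_threshold"))
    return PlexusResult(anchor_region, out, threshold, padding_bp)
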