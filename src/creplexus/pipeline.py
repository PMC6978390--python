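"""Configuration, orchestration and report emission for a full pipeline run.

A run consumes the interval, matrix, track, variant and (optionally) score
inputs, executes candidate selection -> plexus inference -> annotation ->
cascade -> permutation test in a fixed order, and writes machine-readable
reports plus a provenance block. Outputs carry no timestamps, so a rerun
with identical inputs and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .annotation import build_annotation_matrix, run_cascade
from .essentiality import ScoreTable, permutation_median_test
from .genome import Track, read_bed, read_variants
from .plexus import DEFAULT_PADDING_BP, DEFAULT_THRESHOLD
from .signal import SignalMatrix

log = logging.getLogger("creplexus")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Validated inputs and parameters for one end-to-end run."""

    dhs: Path
    tads: Path
    matrix: Path
    activity_track: Path
    anchor_id: str
    out_dir: Path
    variants: Path | None = None
    other_tracks: list[Path] = field(default_factory=list)
    scores: Path | None = None
    group: Path | None = None
    threshold: float = DEFAULT_THRESHOLD
    padding_bp: int = DEFAULT_PADDING_BP
    n_perm: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dhs", "tads", "matrix", "activity_track", "out_dir",
                     "variants", "scores", "group"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        self.other_tracks = [Path(p) for p in self.other_tracks]
        if not -1.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (-1, 1), got {self.threshold}")
        if self.padding_bp < 0:
            raise ValueError("padding_bp must be >= 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def validate_paths(self) -> None:
        """Fail before any computation if a named input is missing."""
        required = {"dhs": self.dhs, "tads": self.tads, "matrix": self.matrix,
                    "activity_track": self.activity_track}
        optional = {"variants": self.variants, "scores": self.scores,
                    "group": self.group}
        optional.update({f"track:{p.name}": p for p in self.other_tracks})
        for name, path in {**required, **optional}.items():
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input {name!r} not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def canonical_json(self) -> str:
        doc = asdict(self)
        return json.dumps({k: str(v) if isinstance(v, Path) else v
                           for k, v in sorted(doc.items())},
                          sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    import numpy
    import scipy

    return {
        "tool": "creplexus",
        "version": __version__,
        "config_sha256_16": config.config_hash(),
        "seed": config.seed,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
    }


def run_all(config: RunConfig) -> dict:
    """Execute every stage in fixed order; returns the combined run report."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("loading inputs")
    dhs = read_bed(config.dhs)
    tads = read_bed(config.tads)
    if len(tads) != 1:
        raise ValueError(f"expected exactly one TAD interval, got {len(tads)}")
    tad = tads[0]
    matrix = SignalMatrix.from_tsv(config.matrix)
    activity = Track("activity", "histone", read_bed(config.activity_track))
    variants = read_variants(config.variants) if config.variants else []

    log.info("plexus inference and filter cascade (anchor=%s, threshold=%s)",
             config.anchor_id, config.threshold)
    cascade = run_cascade(dhs, tad, config.padding_bp, matrix, config.anchor_id,
                          config.threshold, activity, variants)
    cascade.plexus.write(out)
    cascade.write(out)

    log.info("annotation matrix over %d window regions", cascade.report.n_dhs_in_window)
    tracks = [activity] + [
        Track(p.stem, "other", read_bed(p)) for p in config.other_tracks
    ]
    window = [c.region for c in cascade.plexus.candidates]
    build_annotation_matrix(window, tracks).to_tsv(out / "annotation.tsv")

    report: dict = {
        "cascade": cascade.report.as_dict(),
        "plexus": cascade.plexus.summary(),
        "provenance": _provenance(config),
    }

    if config.scores and config.group:
        log.info("permutation median test (n_perm=%d)", config.n_perm)
        scores = ScoreTable.from_csv(config.scores)
        group = [g for g in Path(config.group).read_text().split() if g]
        perm = permutation_median_test(scores, group, n_perm=config.n_perm,
                                       seed=config.seed)
        perm.to_json(out / "permutation.json")
        report["permutation"] = perm.as_dict()

    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    log.info("report written to %s", out / "report.json")
    return report
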