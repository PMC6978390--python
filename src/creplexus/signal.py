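"""Region x cell-type accessibility matrix and the Pearson correlation primitive.

The matrix cell for (region, cell type) is the mean per-base signal of that
cell type's accessibility track over the region, with uncovered bases counted
as zero. Correlation against an anchor region is the product-moment (Pearson)
coefficient across cell types; regions with fewer than ``MIN_PAIRED`` unmasked
cell types, or with zero variance, get an undefined (NaN) coefficient that is
reported but never thresholded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .genome import GenomicInterval

__all__ = [
    "SignalMatrix",
    "CorrelationVector",
    "SignalSource",
    "ArraySource",
    "BedGraphSource",
    "BigWigSource",
    "aggregate_signal",
    "pearson",
    "correlate_with_anchor",
    "MIN_PAIRED",
]

#: minimum paired (unmasked) cell types for a defined correlation
MIN_PAIRED = 3


class SignalSource(Protocol):
    """Per-base signal over one cell type's genome."""

    def chroms(self) -> set[str]: ...

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base signal over ``[start, end)``; uncovered bases are 0."""
        ...


class ArraySource:
    """In-memory per-chromosome signal vectors (dense from base 0)."""

    def __init__(self, values: Mapping[str, np.ndarray]):
        self._values = {c: np.asarray(v, dtype=float) for c, v in values.items()}

    def chroms(self) -> set[str]:
        return set(self._values)

    def mean(self, chrom: str, start: int, end: int) -> float:
        arr = self._values[chrom]
        covered = arr[start:min(end, arr.size)]
        return float(covered.sum() / (end - start))


class BedGraphSource:
    """Signal from a bedGraph file (chrom, start, end, value; 0-based half-open)."""

    def __init__(self, path: str | Path):
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        self._by_chrom = {
            chrom: sub[["start", "end", "value"]].to_numpy(dtype=float)
            for chrom, sub in df.groupby("chrom", sort=False)
        }

    def chroms(self) -> set[str]:
        return set(self._by_chrom)

    def mean(self, chrom: str, start: int, end: int) -> float:
        rows = self._by_chrom[chrom]
        lo = np.minimum(np.maximum(rows[:, 0], start), end)
        hi = np.minimum(np.maximum(rows[:, 1], start), end)
        total = float(np.sum((hi - lo) * rows[:, 2]))
        return total / (end - start)


class BigWigSource:
    """Signal from a bigWig file via pyBigWig (imported lazily)."""

    def __init__(self, path: str | Path):
        import pyBigWig  # heavy/optional; only needed for bigWig input

        self._bw = pyBigWig.open(str(path))

    def chroms(self) -> set[str]:
        return set(self._bw.chroms())

    def mean(self, chrom: str, start: int, end: int) -> float:
        length = self._bw.chroms().get(chrom)
        hi = min(end, length)
        if hi <= start:
            return 0.0
        vals = np.nan_to_num(
            np.asarray(self._bw.values(chrom, start, hi), dtype=float)
        )
        return float(vals.sum() / (end - start))


@dataclass
class SignalMatrix:
    """Region x cell-type mean accessibility; NaN marks masked cells."""

    region_ids: list[str]
    celltype_ids: list[str]
    values: np.ndarray  # shape (n_regions, n_celltypes), NaN where masked

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_ids), len(self.celltype_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.region_ids)} regions x {len(self.celltype_ids)} cell types"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("accessibility values must be non-negative")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("duplicate region_ids")

    def row(self, region_id: str) -> np.ndarray:
        try:
            return self.values[self.region_ids.index(region_id)]
        except ValueError:
            raise KeyError(f"region {region_id!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.region_ids, name="region_id"),
            columns=self.celltype_ids,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignalMatrix":
        df = pd.read_csv(path, sep="\t", index_col="region_id")
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float))


@dataclass
class CorrelationVector:
    """Per-region Pearson correlation with a fixed anchor region."""

    anchor_id: str
    region_ids: list[str]
    r: np.ndarray        # NaN where undefined
    n_used: np.ndarray   # paired cell types per region

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.region_ids, self.r.tolist()))


def aggregate_signal(
    regions: Sequence[GenomicInterval],
    sources: Mapping[str, SignalSource],
    statistic: str = "mean",
) -> SignalMatrix:
    """Build the region x cell-type matrix from per-base signal sources.

    A region whose chromosome is absent from a source is masked (NaN) in that
    column with a warning. ``statistic`` is ``mean`` (default) or ``sum``.
    """
    if statistic not in {"mean", "sum"}:
        raise ValueError("statistic must be 'mean' or 'sum'")
    values = np.empty((len(regions), len(sources)))
    for j, (celltype, src) in enumerate(sources.items()):
        available = src.chroms()
        for i, region in enumerate(regions):
            if region.chrom not in available:
                warnings.warn(
                    f"chromosome {region.chrom!r} absent from source "
                    f"{celltype!r}; masking region {region.region_id!r}",
                    stacklevel=2,
                )
                values[i, j] = np.nan
                continue
            m = src.mean(region.chrom, region.start, region.end)
            values[i, j] = m if statistic == "mean" else m * region.length
    return SignalMatrix([r.region_id for r in regions], list(sources), values)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN when undefined.

    Masked (NaN) entries are removed pairwise. The result is undefined — and
    returned as NaN — when fewer than ``MIN_PAIRED`` pairs remain or either
    vector is constant over the paired entries.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < MIN_PAIRED:
        return float("nan")
    # exact constant check: mean-centering roundoff must not fake a variance
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx @ dx) * (dy @ dy))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((dx @ dy) / denom, -1.0, 1.0))


def correlate_with_anchor(m: SignalMatrix, anchor_id: str) -> CorrelationVector:
    """Correlate every region's accessibility profile with the anchor's.

    The anchor correlates with itself at exactly 1. Regions failing the
    correlation preconditions are flagged undefined (NaN), never dropped.
    """
    anchor_row = m.row(anchor_id)  # raises KeyError if absent
    n = len(m.region_ids)
    r = np.empty(n)
    n_used = np.empty(n, dtype=int)
    for i, rid in enumerate(m.region_ids):
        row = m.values[i]
        n_used[i] = int(np.sum(~(np.isnan(row) | np.isnan(anchor_row))))
        r[i] = 1.0 if rid == anchor_id else pearson(anchor_row, row)
    return CorrelationVector(anchor_id, list(m.region_ids), r, n_used)
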