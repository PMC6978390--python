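"""Percentile ranking and the permutation median test for group essentiality.

Essentiality scores are normalized Z scores from genome-wide knockdown
screens: lower means the gene is more required for proliferation. The test
asks whether a designated group of cell lines (e.g. all prostate lines) is
collectively shifted toward essentiality: the observed group median is
compared against the medians of randomly drawn same-size groups, one-sided in
the lower tail. The Monte-Carlo p-value is floored at 1/n_perm — with one
million draws the smallest reportable p is 1e-6.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoreTable",
    "PermutationResult",
    "percentile_rank",
    "permutation_median_test",
    "MAX_EXHAUSTIVE_SUBSETS",
]

MAX_EXHAUSTIVE_SUBSETS = 10**6


@dataclass
class ScoreTable:
    """Per-entity scores (cell lines x one gene, or samples x expression)."""

    ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.ids) != self.scores.size:
            raise ValueError("ids and scores length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("entity ids must be unique")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def subset(self, wanted: Iterable[str]) -> np.ndarray:
        index = {eid: i for i, eid in enumerate(self.ids)}
        try:
            rows = [index[w] for w in wanted]
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in score table") from None
        return self.scores[rows]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"id": self.ids, "score": self.scores}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, id_col: str = "id",
                 score_col: str = "score") -> "ScoreTable":
        df = pd.read_csv(path)
        return cls(list(df[id_col].astype(str)), df[score_col].to_numpy(dtype=float))


@dataclass
class PermutationResult:
    observed_median: float
    group_size: int
    n_perm: int
    b: int          # background medians <= observed
    p_value: float
    seed: int | None
    mode: str       # "montecarlo" | "exhaustive"
    p_is_floor: bool = False  # montecarlo: no draw at or below observed

    def as_dict(self) -> dict:
        return {
            "observed_median": self.observed_median,
            "group_size": self.group_size,
            "n_perm": self.n_perm,
            "b": self.b,
            "p_value": self.p_value,
            "seed": self.seed,
            "mode": self.mode,
            "p_is_floor": self.p_is_floor,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


def percentile_rank(value: float, reference: Sequence[float]) -> float:
    """Inclusive percentile: 100 x (reference values <= value) / size."""
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("reference distribution is empty")
    return float(100.0 * np.count_nonzero(ref <= value) / ref.size)


def _random_subsets(rng: np.random.Generator, n: int, k: int,
                    n_draws: int) -> np.ndarray:
    """Uniform k-subsets of range(n), one per row, without replacement per row.

    When k is small relative to n the rows are drawn by vectorized sampling
    with replacement, redrawing any row containing a duplicate until all rows
    are duplicate-free — exactly uniform over ordered k-tuples of distinct
    indices, hence over k-subsets. When collisions would be frequent
    (k(k-1) > n) each row instead takes the k smallest of n random keys,
    equivalent to a uniform random permutation truncated at k.
    """
    if k * (k - 1) <= n:
        draws = rng.integers(0, n, size=(n_draws, k))
        while True:
            srt = np.sort(draws, axis=1)
            bad = np.nonzero((srt[:, 1:] == srt[:, :-1]).any(axis=1))[0]
            if bad.size == 0:
                return draws
            draws[bad] = rng.integers(0, n, size=(bad.size, k))
    keys = rng.random((n_draws, n))
    return np.argpartition(keys, k - 1, axis=1)[:, :k] if k < n else (
        np.tile(np.arange(n), (n_draws, 1))
    )


def _median_of_rows(values: np.ndarray) -> np.ndarray:
    """Row medians; even width = mean of the two central order statistics."""
    k = values.shape[1]
    if k % 2:
        return np.partition(values, k // 2, axis=1)[:, k // 2]
    part = np.partition(values, [k // 2 - 1, k // 2], axis=1)
    return 0.5 * (part[:, k // 2 - 1] + part[:, k // 2])


def permutation_median_test(
    scores: ScoreTable,
    target_group: Sequence[str],
    n_perm: int = 1_000_000,
    seed: int | None = None,
    mode: str = "montecarlo",
    exclude_target: bool = False,
) -> PermutationResult:
    """One-sided lower-tail permutation test on the group median.

    The observed statistic is the median score of ``target_group``. Background
    medians come from uniformly drawn same-size subsets of all entity ids
    (including the target group unless ``exclude_target``). In montecarlo mode
    p = max(b, 1)/n_perm where b counts background medians <= observed; in
    exhaustive mode every subset is enumerated and p = b/total.
    """
    group = list(target_group)
    if not group:
        raise ValueError("target group must be non-empty")
    if len(set(group)) != len(group):
        raise ValueError("target group contains duplicate ids")
    observed = float(np.median(scores.subset(group)))
    k = len(group)

    if exclude_target:
        pool = np.array([s for eid, s in zip(scores.ids, scores.scores)
                         if eid not in set(group)])
    else:
        pool = scores.scores
    n = pool.size
    if k > n:
        raise ValueError(f"group size {k} exceeds background pool size {n}")

    if mode == "exhaustive":
        total = comb(n, k)
        if total > MAX_EXHAUSTIVE_SUBSETS:
            raise ValueError(
                f"exhaustive enumeration of C({n},{k})={total} subsets exceeds "
                f"{MAX_EXHAUSTIVE_SUBSETS}; use mode='montecarlo'"
            )
        idx = np.fromiter(
            (i for combo in combinations(range(n), k) for i in combo),
            dtype=np.intp, count=total * k,
        ).reshape(total, k)
        b = int(np.count_nonzero(_median_of_rows(pool[idx]) <= observed))
        p = b / total
        return PermutationResult(observed, k, total, b, p, seed, "exhaustive")

    if mode != "montecarlo":
        raise ValueError(f"unknown mode {mode!r}")
    if n_perm < 1:
        raise ValueError("montecarlo mode requires n_perm >= 1")
    rng = np.random.default_rng(seed)
    b = 0
    # bound scratch memory: (chunk, k) index arrays, or (chunk, n) random keys
    chunk = 200_000 if k * (k - 1) <= n else max(1, 20_000_000 // n)
    remaining = n_perm
    while remaining:
        m = min(chunk, remaining)
        subsets = _random_subsets(rng, n, k, m)
        medians = _median_of_rows(pool[subsets])
        b += int(np.count_nonzero(medians <= observed))
        remaining -= m
    p = max(b, 1) / n_perm
    return PermutationResult(observed, k, n_perm, b, p, seed, "montecarlo",
                             p_is_floor=(b == 0))
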