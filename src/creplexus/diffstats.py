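"""Normalization and hypothesis-test statistics for perturbation experiments.

Covers the downstream quantifications of a CRE-perturbation study:

* qPCR expression normalized to a housekeeping gene (e.g. TBP) and then to
  the basal condition, reported as mean percent change;
* equal-variance two-sample Student's t test (two-sided);
* Mann-Whitney U (exact by enumeration for small tie-free samples, normal
  approximation with tie correction otherwise) for reporter assays;
* allele-specific enrichment log2 fold-changes (variant vs wild-type) with a
  t test on the log2 scale;
* Pearson correlation of editing efficiency vs expression with a t-transform
  p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .signal import pearson

__all__ = [
    "ExpressionMeasurement",
    "AlleleEnrichment",
    "RelativeExpressionResult",
    "relative_expression",
    "student_t_two_sample",
    "mann_whitney_u",
    "allele_log2fc",
    "efficiency_expression_correlation",
    "benjamini_hochberg",
    "EXACT_MWU_MAX_N",
]

#: combined-sample-size cutoff below which the U test is exact (no ties)
EXACT_MWU_MAX_N = 12

BASAL = "basal"


@dataclass(frozen=True)
class ExpressionMeasurement:
    """One qPCR replicate: target and housekeeping abundances, one condition."""

    sample_id: str
    condition: str  # "basal" or "treated:<label>"
    target_abundance: float
    housekeeping_abundance: float

    def __post_init__(self) -> None:
        if self.target_abundance <= 0 or self.housekeeping_abundance <= 0:
            raise ValueError(
                f"abundances must be positive, got target="
                f"{self.target_abundance}, housekeeping={self.housekeeping_abundance}"
            )

    @property
    def ratio(self) -> float:
        return self.target_abundance / self.housekeeping_abundance


@dataclass(frozen=True)
class AlleleEnrichment:
    """One ChIP-qPCR replicate: pulldown/input enrichment for one allele."""

    factor: str
    allele: str  # "wildtype" | "variant"
    replicate: str
    enrichment: float

    def __post_init__(self) -> None:
        if self.allele not in {"wildtype", "variant"}:
            raise ValueError(f"allele must be wildtype/variant, got {self.allele!r}")
        if self.enrichment <= 0:
            raise ValueError(f"enrichment must be positive, got {self.enrichment}")


@dataclass
class RelativeExpressionResult:
    basal_normalized: np.ndarray    # each == ratio / mean(basal ratios)
    treated_normalized: np.ndarray
    percent_change: float           # 100 * (1 - mean treated normalized)
    t_statistic: float
    p_value: float


def relative_expression(
    measurements: Sequence[ExpressionMeasurement], treated_label: str
) -> RelativeExpressionResult:
    """Housekeeping-normalized expression of a treated condition vs basal.

    Per-replicate ratios target/housekeeping are scaled by the mean basal
    ratio; the percent change is 100 x (1 - mean treated normalized), so a
    positive value is a reduction. Significance is the pooled two-sample t
    test on the normalized replicate values.
    """
    basal = [m.ratio for m in measurements if m.condition == BASAL]
    treated = [m.ratio for m in measurements
               if m.condition == f"treated:{treated_label}"]
    if not basal or not treated:
        raise ValueError(
            f"need >=1 basal and >=1 treated:{treated_label} replicate, "
            f"got {len(basal)} and {len(treated)}"
        )
    basal_mean = float(np.mean(basal))
    basal_norm = np.asarray(basal) / basal_mean
    treated_norm = np.asarray(treated) / basal_mean
    pct = 100.0 * (1.0 - float(treated_norm.mean()))
    if len(basal) >= 2 and len(treated) >= 2:
        t, p = student_t_two_sample(treated_norm, basal_norm)
    else:
        t, p = float("nan"), float("nan")
    return RelativeExpressionResult(basal_norm, treated_norm, pct, t, p)


def student_t_two_sample(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Equal-variance two-sample t test, two-sided (df = n_a + n_b - 2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >=2 replicates")
    res = stats.ttest_ind(a, b, equal_var=True)
    if not math.isfinite(res.statistic):
        raise ValueError("pooled variance is zero; t statistic undefined")
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U (two-sided); U is reported for the first sample.

    Exact p by enumeration when n_a + n_b <= 12 with no ties between or
    within groups; otherwise the normal approximation with tie correction
    (and continuity correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs >=1 value")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (a.size + b.size <= EXACT_MWU_MAX_N and no_ties) else (
        "asymptotic"
    )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AlleleLog2FCResult:
    factor: str
    log2fc: np.ndarray    # one value per replicate pairing
    mean_log2fc: float
    p_value: float
    paired: bool


def allele_log2fc(
    enrichments: Sequence[AlleleEnrichment], factor: str
) -> AlleleLog2FCResult:
    """Variant-vs-wildtype log2 fold-change of a factor's binding enrichment.

    Replicates sharing a replicate id across alleles are paired; when the
    replicate ids do not pair up, each variant replicate is compared with the
    mean wild-type enrichment. The p-value is the pooled two-sample t test on
    log2 enrichments.
    """
    wt = {e.replicate: e.enrichment for e in enrichments
          if e.factor == factor and e.allele == "wildtype"}
    var = {e.replicate: e.enrichment for e in enrichments
           if e.factor == factor and e.allele == "variant"}
    if len(wt) < 2 or len(var) < 2:
        raise ValueError(
            f"need >=2 replicates per allele for factor {factor!r}, "
            f"got {len(wt)} wildtype and {len(var)} variant"
        )
    paired = set(wt) == set(var)
    if paired:
        reps = sorted(wt)
        log2fc = np.array([math.log2(var[r] / wt[r]) for r in reps])
    else:
        wt_mean = float(np.mean(list(wt.values())))
        log2fc = np.array([math.log2(v / wt_mean)
                           for _, v in sorted(var.items())])
    log2_wt = np.log2(list(wt.values()))
    log2_var = np.log2(list(var.values()))
    try:
        _, p = student_t_two_sample(log2_var, log2_wt)
    except ValueError:  # zero pooled variance (identical replicates)
        p = 1.0 if np.isclose(log2_var.mean(), log2_wt.mean()) else 0.0
    return AlleleLog2FCResult(factor, log2fc, float(log2fc.mean()), p, paired)


def efficiency_expression_correlation(
    editing_efficiency: Sequence[float], expression: Sequence[float]
) -> tuple[float, float]:
    """Pearson r between editing efficiency and expression, with t-transform p.

    p is two-sided from t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(editing_efficiency, dtype=float)
    y = np.asarray(expression, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    r = pearson(x, y)
    if math.isnan(r):
        raise ValueError("correlation undefined (constant input)")
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (optional; tests are reported unadjusted by default)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
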