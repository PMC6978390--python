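#!/usr/bin/env python
"""Score synthetic perturbation, reporter and allele-specific experiments.

Exercises the downstream statistics on simulated replicate-level readouts
with known effects: qPCR expression after a CRE deletion (housekeeping- and
basal-normalized percent change, Student's t), luciferase reporter activity
of variant vs wild-type alleles (Mann-Whitney U), allele-specific ChIP
enrichment (log2 fold-change, t test), and editing-efficiency vs expression
correlation (Pearson with t-transform p). Writes one results table.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from creplexus.diffstats import (
    AlleleEnrichment,
    ExpressionMeasurement,
    allele_log2fc,
    efficiency_expression_correlation,
    mann_whitney_u,
    relative_expression,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

rng = np.random.default_rng(99)
rows = []

# qPCR: a deletion planted to reduce expression to ~70% of basal (n=5 each)
measurements = [
    ExpressionMeasurement(f"b{i}", "basal",
                          float(rng.normal(1.0, 0.05)) * h, h)
    for i, h in enumerate(rng.uniform(0.8, 1.2, 5))
] + [
    ExpressionMeasurement(f"t{i}", "treated:delCRE",
                          0.7 * float(rng.normal(1.0, 0.05)) * h, h)
    for i, h in enumerate(rng.uniform(0.8, 1.2, 5))
]
rel = relative_expression(measurements, "delCRE")
rows.append(("qPCR_delCRE", "percent_reduction", rel.percent_change,
             rel.p_value))

# luciferase: variant allele planted at 1.5x wild-type activity (n=5 each)
wt_rlu = rng.normal(1.0, 0.1, 5)
var_rlu = rng.normal(1.5, 0.1, 5)
u, p = mann_whitney_u(var_rlu, wt_rlu)
rows.append(("luciferase_variant_vs_wt", "U", u, p))

# allele-specific ChIP: factor binding planted at ~1.3x on the variant allele
enrich = []
for i in range(3):
    base = float(rng.uniform(2.0, 3.0))
    enrich.append(AlleleEnrichment("FOXA1", "wildtype", f"rep{i}", base))
    enrich.append(AlleleEnrichment("FOXA1", "variant", f"rep{i}",
                                   1.3 * base * float(rng.normal(1.0, 0.03))))
fc = allele_log2fc(enrich, "FOXA1")
rows.append(("chip_FOXA1_variant_vs_wt", "mean_log2fc", fc.mean_log2fc,
             fc.p_value))

# editing efficiency vs expression: planted negative linear relationship
efficiency = rng.uniform(0.2, 0.9, 8)
expression = 1.0 - 0.8 * efficiency + rng.normal(0, 0.05, 8)
r, p = efficiency_expression_correlation(efficiency, expression)
rows.append(("editing_vs_expression", "pearson_r", r, p))

table = pd.DataFrame(rows, columns=["experiment", "statistic", "value",
                                    "p_value"])
RESULTS.mkdir(exist_ok=True)
table.to_csv(RESULTS / "05_perturbation_stats.tsv", sep="\t", index=False,
             float_format="%.4f")

print(table.to_string(index=False))
print(
    f"\nPlanted effects recovered: ~{rel.percent_change:.0f}% expression "
    f"reduction (planted 30%), ChIP log2FC {fc.mean_log2fc:.2f} "
    f"(planted log2 1.3 = {np.log2(1.3):.2f}), efficiency-expression "
    f"r = {r:.2f} (planted negative)."
)
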