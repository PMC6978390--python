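# Methods

## Interval model and overlap semantics

All intervals are BED-style 0-based half-open `[start, end)`; two intervals
overlap iff they share a chromosome and `max(starts) < min(ends)`. Variant
positions are VCF-style 1-based and converted at assignment time: a SNV at
position `pos` hits a region iff `pos − 1 ∈ [start, end)`. Strand is carried
for reporting but ignored by overlap logic — every overlap the pipeline uses
is strand-agnostic. Chromosome names are matched as exact strings by
default; an opt-in normalizer reconciles the `chr14` / `14` dialects, and
`assign_variants` warns when zero assignments coincide with a dialect
mismatch, because a silent cross-convention join would otherwise look like
an empty result. A variant falling in several overlapping regions is
assigned to all of them (multi-assignment); in the cascade's tallies each
variant is counted once even if it spans two mutated regions.

## Accessibility matrix and correlation

The signal matrix holds the mean per-base accessibility of each region in
each cell type; bases without coverage contribute zero, and a region on a
chromosome absent from a source is masked (NaN) with a warning rather than
silently zeroed. Mean (rather than sum) is the default aggregation so that
regions of different widths are comparable; `statistic="sum"` is available.
Correlation is the plain product-moment coefficient on the raw aggregated
values. A correlation is *undefined* — reported as NaN, never imputed and
never thresholded — when fewer than 3 unmasked cell-type pairs remain or
either profile is constant. Constancy is detected by exact elementwise
equality, not by a variance tolerance: mean-centering roundoff on a shifted
constant row is ~1e-16 and must not manufacture a defined correlation.

## Plexus inference

Candidates are the DHS overlapping the TAD widened by `padding_bp`
(default 40,000 bp, the Hi-C map resolution) on each side, clipped at zero.
Members are candidates whose correlation with the anchor is defined and
**strictly greater** than the threshold (default 0.7); the boundary case
r = threshold is excluded, a deliberate, observable choice. The anchor is
excluded from its own candidate list. Raising the threshold can only remove
members (monotonicity, property-tested). The full correlation vector,
including undefined entries with reason codes, is retained in the output
table.

## Annotation and the filter cascade

The annotation matrix is boolean any-overlap of each window region with each
peak track, in input order. "Active" means overlap with the one designated
activity track (a histone category, e.g. primary-tumor H3K27ac); TF tracks
annotate but never filter. The cascade composes window selection → plexus
inference → activity filter → SNV assignment, and reports non-increasing
stage counts plus the SNV and distinct-tumor tallies over mutated members.
SNVs are only counted inside *active* members — a variant in an unmarked
plexus member does not reach the mutated stage, matching the filter order.
The mutated/active fraction is formatted as a percentage rounded half-up to
one decimal (6/33 → 18.2%); with zero active members it is reported as
not applicable, not as 0%.

## Permutation median test

The observed statistic is the median essentiality score (normalized *Z*;
lower = more essential) of the target group of k cell lines. Background
medians come from uniform k-subsets of **all** lines — the target group is
not excluded, matching a background built from "randomly selected cell
lines"; an `exclude_target` flag provides the leave-out variant. The test is
one-sided in the lower tail. Monte-Carlo mode reports
p = max(b, 1)/n_perm, where b counts background medians ≤ observed: the
floor makes the smallest reportable p equal 1/n_perm (1e-6 at one million
draws) and is flagged in the output (`p_is_floor`), because a zero p-value
is not reportable. Exhaustive mode enumerates all C(n, k) subsets
(refused above 10⁶ with guidance) and reports p = b/total; since the target
group is itself one subset, b ≥ 1 there. Even-size medians are the mean of
the two central order statistics.

Subset draws use one seeded `numpy` Generator per call. Rows are sampled
with replacement and any row containing a duplicate is redrawn — exactly
uniform over ordered k-tuples of distinct indices, hence over k-subsets —
which vectorizes well when k(k−1) ≤ n; beyond that collision regime each
row instead takes the k smallest of n random keys (a truncated random
permutation). Draws are processed in fixed-size chunks so memory stays
bounded at any n_perm; results are reproducible for a fixed seed and
algorithm version.

Percentile ranks use the inclusive convention,
100 × #{reference ≤ value}/N.

## Perturbation statistics

Expression readouts are normalized twice: each replicate's target abundance
by its housekeeping abundance (TBP-style), then by the mean basal ratio;
the reported percent change is 100 × (1 − mean treated normalized), so the
output is invariant to any global rescaling of abundances and to replicate
order. "Student's t test" is interpreted as the equal-variance two-sample
test, two-sided (the conventional reading of the name; Welch is not used).
Mann-Whitney U is exact by enumeration when the combined sample size is
≤ 12 with no ties — p-values near 0.05 are decision-relevant at reporter-
assay sample sizes — and the tie-corrected normal approximation otherwise.
Allele-specific enrichment fold-changes are log2(variant/wild-type) paired
by replicate id, falling back to the mean wild-type denominator when ids do
not pair, with a t test on log2 enrichments. Editing-efficiency vs
expression uses Pearson r with the exact t-transform p
(t = r·√((n−2)/(1−r²)), df = n−2). No multiple-testing correction is
applied by default; Benjamini-Hochberg is available as a helper.

## Synthetic-data generator

The generator is the package's test substrate and defines its study
conditions. The anchor profile is i.i.d. standard normal across cell types;
each planted member is ρ·anchor + √(1−ρ²)·independent noise, so its
population correlation with the anchor is exactly ρ; background profiles
are independent. The whole matrix is shifted by one global constant to
non-negative values — Pearson correlation is location/scale invariant, so
the shift is benign. Regions are fixed-width 500 bp with random 0.2-2 kbp
gaps inside a single generated TAD, plus flanking distractor regions placed
beyond the padded window so candidate selection is exercised. Activity
peaks cover exactly the marked members with jittered edges; SNV positions
are uniform within mutated regions; the first n_tumors variants are
assigned one tumor each so the realized distinct-tumor count is exact by
construction. Essentiality tables are standard normal with the designated
group shifted by −Δ, or placed strictly below the background minimum in
`force_extreme` mode. One seed drives each generator call; identical seeds
give byte-identical fixture files.

Default conditions: ρ = 0.95, 50 cell types, 10 members, 200 background
regions for the plexus panel; at those values the sampling s.d. of a
member's r is ≈ 0.014, so recovery at threshold 0.7 is essentially
deterministic, and the chance of any background region exceeding 0.7 is
negligible — planted-set recovery with zero false positives is the expected
outcome, which the acceptance checks confirm. What the generator does *not*
emulate: read-level noise, cross-cell-type normalization artifacts,
correlated background structure (co-accessibility between non-member
regions), peak-calling uncertainty, or mutational signatures. Passing tests
therefore demonstrate the correctness of the inference machinery under its
own assumptions, not the field performance of accessibility correlation on
real panels.

Problem sizes in the test suite and the acceptance script follow those
defaults; the permutation checks use a 707-line table with a group of 8 at
one million draws, and the null calibration uses exhaustive enumeration on
20-line tables (C(20,4) = 4845 subsets per seed, 200 seeds) so it is exact
per seed.

## Pipeline runs

A run validates every configured input path before any computation, executes
stages in a fixed order, and writes JSON/TSV reports plus a provenance block
(package and numeric-library versions, seed, and a sha256 of the canonical
config). No output carries a timestamp, so a rerun with the same inputs and
seed is byte-identical. Structured logs go to standard error; timings appear
only in logs, never in report files.

## Known limitations

- The correlation panel's cell-type composition is a user input; no
  reference DHS database ships with the package.
- Only SNVs are handled; indels and structural variants are out of scope, as
  is liftover and full VCF feature parsing.
- TADs are consumed as called intervals; Hi-C processing and contact-
  frequency modeling are out of scope.
- The permutation test is single-gene; batch FDR across genes is not
  provided.
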