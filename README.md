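# creplexus

Promoter-anchored inference of a gene's *cis*-regulatory plexus from
cross-cell-type chromatin accessibility, with chromatin-mark and somatic-SNV
annotation of the candidates, and the permutation / normalization statistics
used to score gene-essentiality and perturbation experiments.

## The problem

Distal cis-regulatory elements (CREs) — enhancers and interaction anchors —
control the expression of oncogenes such as *FOXA1* in prostate cancer, but
which accessible regions actually belong to a gene's regulatory plexus is not
readable from a single assay. This package implements the computational
pipeline of that style of study, for analysts who have:

- DNase I hypersensitive sites (DHS) and a TAD call around the gene of
  interest (BED),
- a region × cell-type accessibility signal matrix (or per-base signal
  tracks to aggregate into one),
- histone-mark / TF peak tracks and somatic SNV calls from tumor cohorts,
- gene essentiality or expression score tables (DEPMAP/TCGA-style).

The core inference: anchor on the gene's promoter DHS, restrict candidates
to the containing TAD padded by the Hi-C map resolution (default ± 40 kbp),
correlate every candidate's accessibility profile across cell types with the
anchor's, and keep candidates with Pearson *r* > 0.7. Members are then
filtered to those carrying an activity mark (tumor H3K27ac) and overlapped
with somatic SNVs, producing a stage-count cascade
(DHS in window → plexus members → active → mutated, with SNV and distinct-
tumor tallies). Group essentiality is tested with a one-sided permutation
test: the observed group median of normalized *Z* essentiality scores
against medians of randomly drawn same-size groups, with
*p* = max(*b*, 1)/*n*<sub>perm</sub> so that one million draws floor the
reportable *p* at 1 × 10⁻⁶.

Because the real tumor inputs live behind controlled-access repositories,
the package ships a first-class synthetic-data generator that plants known
structure (an anchor-correlated member set at target correlation ρ, marked
and mutated subsets, an essentiality-shifted group) and writes a truth
manifest, so every stage is testable end to end offline.

## Worked example

```python
from creplexus import (simulate_accessibility_panel,
                       simulate_tracks_and_variants, run_cascade)

matrix, regions, truth = simulate_accessibility_panel(
    n_background=200, n_members=10, n_celltypes=50, rho=0.95, seed=1)
tracks, variants, truth = simulate_tracks_and_variants(
    truth, regions, marked_fraction=0.6, mutated_count=3,
    variants_per_region=[2, 2, 1], n_tumors=4, seed=1)
out = run_cascade(regions, truth.tad, 40_000, matrix, "anchor", 0.7,
                  tracks[0], variants)
print(out.report.text())
```

prints

```
CRE filter cascade
  DHS in padded TAD window : 211
  plexus members (r>thr)   : 10
  active (activity-marked) : 6
  mutated (>=1 SNV)        : 3
  SNVs in mutated CREs     : 5
  distinct tumors          : 4
  mutated / active         : 50.0%
```

— all 10 planted members recovered at *r* > 0.7 with zero false positives
among the 200 background regions, then narrowed to the 6 activity-marked and
3 mutated members the generator planted (5 SNVs from 4 tumors, matching the
truth manifest exactly). The same composition is available from a shell:

```bash
creplexus simulate --seed 1 --out fixture/
creplexus cascade --matrix fixture/matrix.tsv --dhs fixture/dhs.bed \
    --tad fixture/tads.bed --anchor anchor \
    --h3k27ac fixture/tracks/H3K27ac_tumor.bed \
    --variants fixture/snvs.tsv --out run/
creplexus essentiality --scores fixture/scores.csv --group fixture/group.txt \
    --n-perm 1000000 --seed 17
```

The numbered scripts under `analysis/` run the same stages as a narrative:
`01_simulate_inputs.py` writes the fixture, `02_plexus_inference.py` scores
planted-plexus recovery, `03_annotation_cascade.py` checks the cascade
against the manifest, `04_essentiality_test.py` runs the million-draw
permutation test (the planted extreme group yields *p* = 1 × 10⁻⁶, the
floor) plus a null calibration (mean *p* ≈ 0.5), and
`05_perturbation_stats.py` exercises the expression/reporter/allele
statistics on planted effects. Each writes its tables under `results/`.

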