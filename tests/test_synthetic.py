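"""The planted-truth generator: statistical structure and determinism."""

import filecmp
import json

import numpy as np
import pytest

from creplexus.genome import read_bed
from creplexus.signal import pearson
from creplexus.synthetic import (
    PlantedTruth,
    simulate_accessibility_panel,
    simulate_essentiality,
    simulate_tracks_and_variants,
    write_fixture,
)
from creplexus.essentiality import permutation_median_test


class TestAccessibilityPanel:
    def test_rho_one_gives_perfect_sample_correlation(self):
        m, _, truth = simulate_accessibility_panel(
            n_background=5, n_members=4, n_celltypes=10, rho=1.0, seed=0
        )
        anchor = m.row("anchor")
        for rid in truth.member_ids:
            assert pearson(anchor, m.row(rid)) == pytest.approx(1.0)

    def test_sample_r_near_target_rho(self):
        """At rho=0.9 with 100 cell types the sampling s.d. of r is ~0.019,
        so every member's sample r lies within 0.06 (3 sigma) of 0.9."""
        m, _, truth = simulate_accessibility_panel(
            n_background=20, n_members=10, n_celltypes=100, rho=0.9, seed=1
        )
        anchor = m.row("anchor")
        for rid in truth.member_ids:
            assert abs(pearson(anchor, m.row(rid)) - 0.9) < 0.06

    def test_no_members(self):
        m, regions, truth = simulate_accessibility_panel(
            n_background=8, n_members=0, n_celltypes=10, rho=0.5, seed=2
        )
        assert truth.member_ids == []
        assert len(regions) == 1 + 8 + 10  # anchor + background + flanks

    def test_layout_and_nonnegativity(self):
        m, regions, truth = simulate_accessibility_panel(
            n_background=10, n_members=3, n_celltypes=8, rho=0.8, seed=3
        )
        assert np.all(m.values >= 0)
        by_id = {r.region_id: r for r in regions}
        window = truth.tad.padded(40_000)
        for rid in [truth.anchor_id, *truth.member_ids, *truth.background_ids]:
            r = by_id[rid]
            assert truth.tad.start <= r.start and r.end <= truth.tad.end
        for rid in truth.flank_ids:
            assert by_id[rid].start >= window.end  # outside the padded window

    def test_invalid_parameters(self):
        with pytest.raises(ValueError, match="rho"):
            simulate_accessibility_panel(rho=0.0, seed=0)
        with pytest.raises(ValueError, match="rho"):
            simulate_accessibility_panel(rho=1.2, seed=0)
        with pytest.raises(ValueError, match="cell types"):
            simulate_accessibility_panel(n_celltypes=3, seed=0)


@pytest.fixture(scope="module")
def panel():
    return simulate_accessibility_panel(
        n_background=20, n_members=8, n_celltypes=10, rho=0.9, seed=4
    )


class TestTracksAndVariants:

    def test_subset_chain_and_variant_placement(self, panel):
        _, regions, truth = panel
        tracks, variants, truth = simulate_tracks_and_variants(
            truth, regions, marked_fraction=0.75, mutated_count=3,
            variants_per_region=2, n_tumors=3, seed=5,
        )
        assert set(truth.mutated_ids) <= set(truth.marked_ids) <= set(truth.member_ids)
        assert len(truth.marked_ids) == 6 and len(truth.mutated_ids) == 3
        assert len(variants) == 6 and truth.n_tumors == 3
        by_id = {r.region_id: r for r in regions}
        for v in variants:
            hit = [rid for rid in truth.mutated_ids
                   if by_id[rid].start <= v.pos - 1 < by_id[rid].end]
            assert len(hit) == 1, "every SNV falls inside one mutated region"

    def test_peaks_cover_exactly_marked_members(self, panel):
        _, regions, truth = panel
        tracks, _, truth = simulate_tracks_and_variants(
            truth, regions, marked_fraction=0.5, mutated_count=2,
            n_tumors=2, seed=6,
        )
        activity = tracks[0]
        assert activity.category == "histone"
        by_id = {r.region_id: r for r in regions}
        covered = {
            rid for rid in truth.member_ids
            if any(p.start <= by_id[rid].start and by_id[rid].end <= p.end
                   for p in activity.intervals)
        }
        assert covered == set(truth.marked_ids)

    def test_parameter_validation(self, panel):
        _, regions, truth = panel
        with pytest.raises(ValueError, match="exceeds marked"):
            simulate_tracks_and_variants(truth, regions, marked_fraction=0.25,
                                         mutated_count=5, n_tumors=1, seed=0)
        with pytest.raises(ValueError, match="distinct tumors"):
            simulate_tracks_and_variants(truth, regions, marked_fraction=1.0,
                                         mutated_count=2, variants_per_region=1,
                                         n_tumors=5, seed=0)


class TestEssentialityScores:
    def test_force_extreme_floors_p(self):
        scores, group = simulate_essentiality(n_lines=50, group_size=4,
                                              seed=7, force_extreme=True)
        in_group = scores.subset(group)
        background = [s for eid, s in zip(scores.ids, scores.scores)
                      if eid not in set(group)]
        assert in_group.max() < min(background)
        res = permutation_median_test(scores, group, n_perm=1000, seed=8)
        assert res.p_value == 1 / 1000 and res.p_is_floor

    def test_group_is_whole_table(self):
        scores, group = simulate_essentiality(n_lines=6, group_size=6, seed=9)
        res = permutation_median_test(scores, group, mode="exhaustive")
        assert res.p_value == 1.0

    def test_effect_delta_shifts_group(self):
        base, group = simulate_essentiality(n_lines=300, group_size=50,
                                            effect_delta=2.0, seed=10)
        in_group = base.subset(group)
        rest = [s for eid, s in zip(base.ids, base.scores)
                if eid not in set(group)]
        assert in_group.mean() < np.mean(rest) - 1.0


class TestFixtureFiles:
    def test_same_seed_byte_identical(self, tmp_path):
        kwargs = dict(seed=13, n_background=15, n_members=5, n_celltypes=10,
                      mutated_count=2, n_tumors=2, n_lines=30, group_size=3)
        write_fixture(tmp_path / "a", **kwargs)
        write_fixture(tmp_path / "b", **kwargs)
        names = ["dhs.bed", "tads.bed", "matrix.tsv", "snvs.tsv",
                 "scores.csv", "group.txt", "truth.json"]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert mismatch == [] and errors == []

    def test_truth_manifest_roundtrip(self, tmp_path):
        truth = write_fixture(tmp_path, seed=14, n_background=10, n_members=4,
                              n_celltypes=8, mutated_count=1, n_tumors=1,
                              n_lines=20, group_size=2)
        back = PlantedTruth.from_json(tmp_path / "truth.json")
        assert back == truth
        assert back.expected_cascade() == truth.expected_cascade()
        dhs = read_bed(tmp_path / "dhs.bed")
        assert {r.region_id for r in dhs} >= set(truth.member_ids)
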