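import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from creplexus.genome import GenomicInterval, Track
from creplexus.synthetic import (
    simulate_accessibility_panel,
    simulate_tracks_and_variants,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_panel():
    """Fast accessibility panel: 5 members, 30 background, 20 cell types."""
    return simulate_accessibility_panel(
        n_background=30, n_members=5, n_celltypes=20, rho=0.95, seed=7
    )


@pytest.fixture(scope="session")
def cascade_fixture():
    """The seeded cascade fixture: 12 members, 8 marked, 3 mutated,
    5 SNVs from 4 tumors."""
    matrix, regions, truth = simulate_accessibility_panel(
        n_background=40, n_members=12, n_celltypes=30, rho=0.95, seed=1
    )
    tracks, variants, truth = simulate_tracks_and_variants(
        truth, regions, marked_fraction=8 / 12, mutated_count=3,
        variants_per_region=[2, 2, 1], n_tumors=4, seed=1,
    )
    return matrix, regions, truth, tracks, variants


def brute_force_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Independent oracle: materialize both base sets and intersect."""
    if a.chrom != b.chrom:
        return False
    return bool(set(range(a.start, a.end)) & set(range(b.start, b.end)))
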