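import numpy as np
import pytest

from complexmap import ComplexSet, generate_planted_complexes, simulate_pulldowns


@pytest.fixture(scope="session")
def small_world():
    """10 disjoint planted complexes plus background, for fast tests."""
    return generate_planted_complexes(
        10, (3, 6), overlap_fraction=0.0, n_background_proteins=30, seed=101
    )


@pytest.fixture(scope="session")
def small_experiments(small_world):
    return simulate_pulldowns(
        small_world, 150, member_detect_prob=0.9, contaminant_rate=1.0, seed=102
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_complexes(rng, n, size_lo=3, size_hi=7, universe=40) -> ComplexSet:
    """Random complex sets over a shared accession universe (overlaps allowed)."""
    proteins = [f"X{i:03d}" for i in range(universe)]
    cs = []
    for _ in range(n):
        size = int(rng.integers(size_lo, size_hi + 1))
        cs.append(frozenset(rng.choice(proteins, size=size, replace=False).tolist()))
    return ComplexSet(cs)
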