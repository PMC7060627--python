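import numpy as np
import pytest

from gametivar import ChromSpec, EffectTable, GeneticMap, HaplotypePair, SimSpec


@pytest.fixture
def coupling_pair():
    """Double heterozygote with both reference alleles on haplotype A."""
    return HaplotypePair("i1", "1", np.array([1, 1]), np.array([0, 0]))


@pytest.fixture
def repulsion_pair():
    return HaplotypePair("i1", "1", np.array([1, 0]), np.array([0, 1]))


@pytest.fixture
def three_marker_map():
    return GeneticMap("1", ["m1", "m2", "m3"],
                      positions_cM=np.array([0.0, 10.0, 60.0]))


@pytest.fixture
def three_marker_effects():
    return EffectTable(["m1", "m2", "m3"], ["t1", "t2"],
                       np.array([[1.0, 0.5], [2.0, -1.0], [3.0, 0.0]]))


def random_het_pair(rng, n_markers, chromosome="1"):
    """A haplotype pair guaranteed to carry at least one heterozygous locus."""
    while True:
        a = rng.integers(0, 2, n_markers).astype(np.int8)
        b = rng.integers(0, 2, n_markers).astype(np.int8)
        if np.any(a != b):
            return HaplotypePair("ix", chromosome, a, b)


def small_rate_spec(seed, n_markers=10, n_traits=2):
    return SimSpec(
        n_individuals=1,
        chromosomes=(ChromSpec("1", n_markers, rate_range=(0.0, 0.5)),),
        n_traits=n_traits,
        seed=seed,
    )
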