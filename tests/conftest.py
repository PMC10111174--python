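import numpy as np
import pytest

from msatpop.genotype_io import MISSING, GenotypeMatrix, LocusDef
from msatpop.synth import SynthConfig, generate_study_like


def make_matrix(calls, pops, loci=None, state_max=40):
    """Build a GenotypeMatrix from a nested list of (a, b) genotype pairs."""
    calls = np.asarray(calls, dtype=np.int64)
    n, L = calls.shape[:2]
    if loci is None:
        loci = [LocusDef(f"L{l + 1}", state_max=state_max) for l in range(L)]
    ids = [f"ind{i + 1}" for i in range(n)]
    return GenotypeMatrix(ids, list(pops), loci, calls)


def random_matrix(rng, n_pops=3, n_per_pop=5, n_loci=4, n_alleles=5, missing_rate=0.0):
    """Random genotype matrix with alleles drawn uniformly from a small pool."""
    n = n_pops * n_per_pop
    calls = rng.integers(10, 10 + n_alleles, size=(n, n_loci, 2))
    if missing_rate:
        mask = rng.random((n, n_loci)) < missing_rate
        calls[mask] = MISSING
    pops = [f"pop{p + 1}" for p in range(n_pops) for _ in range(n_per_pop)]
    return make_matrix(calls, pops)


@pytest.fixture
def toy_gm():
    """One population, one locus: genotypes 1/1, 1/2, 2/2, 1/2."""
    return make_matrix([[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)]], ["p1"] * 4)


@pytest.fixture
def two_pop_gm():
    """Two populations of 3 individuals at 2 loci, moderately distinct."""
    calls = [
        [(10, 10), (20, 21)],
        [(10, 11), (20, 20)],
        [(11, 11), (21, 21)],
        [(12, 12), (22, 22)],
        [(12, 13), (22, 23)],
        [(13, 13), (23, 23)],
    ]
    return make_matrix(calls, ["a"] * 3 + ["b"] * 3)


@pytest.fixture(scope="session")
def study_like():
    gm, sites = generate_study_like(SynthConfig(seed=3))
    return gm, sites
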