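import numpy as np
import pytest

from msatpop.core import GenotypeTable
from msatpop.simulate import (
    IslandSimConfig,
    SpatialSimConfig,
    simulate_island,
    simulate_spatial,
)


def make_random_table(rng: np.random.Generator, n_pops: int = 3,
                      n_per_pop: int = 8, n_loci: int = 4,
                      n_alleles: int = 5, missing_rate: float = 0.0,
                      regions: dict | None = None) -> GenotypeTable:
    """Random genotype table with per-population allele-frequency skew."""
    n = n_pops * n_per_pop
    alleles = np.zeros((n, n_loci, 2), dtype=np.int64)
    pops = []
    for p in range(n_pops):
        # each population gets its own Dirichlet frequency vector per locus
        for j in range(n_loci):
            freqs = rng.dirichlet(np.ones(n_alleles))
            draws = rng.choice(np.arange(1, n_alleles + 1),
                               size=(n_per_pop, 2), p=freqs)
            alleles[p * n_per_pop:(p + 1) * n_per_pop, j, :] = draws
        pops += [f"P{p + 1}"] * n_per_pop
    if missing_rate > 0:
        mask = rng.random((n, n_loci)) < missing_rate
        alleles[mask] = 0
    return GenotypeTable(
        ids=[f"i{k}" for k in range(n)],
        loci=[f"L{j + 1}" for j in range(n_loci)],
        alleles=alleles, pops=pops, regions=regions,
    )


@pytest.fixture
def toy_table() -> GenotypeTable:
    """Two populations x one locus; frequencies computable by hand."""
    alleles = np.array([[[1, 1]], [[1, 2]], [[2, 2]], [[1, 2]]])
    return GenotypeTable(ids=["a", "b", "c", "d"], loci=["L1"],
                         alleles=alleles, pops=["P1", "P1", "P2", "P2"])


@pytest.fixture(scope="session")
def island_table():
    """Two-region island-model dataset shared by the structure tests."""
    regions = {f"P{i + 1:02d}": ("HN" if i < 4 else "IC") for i in range(8)}
    cfg = IslandSimConfig(n_pops=8, pop_size=400, n_sample=10,
                          migration=2e-3, n_loci=10, regions=regions,
                          divergence_time=2000, region_divergence_time=8000,
                          seed=42)
    table, truth = simulate_island(cfg)
    return table, truth


@pytest.fixture(scope="session")
def spatial_data():
    """Spatially structured dataset with seed dispersal << pollen dispersal."""
    cfg = SpatialSimConfig(arena=200.0, capacity=80, generations=30,
                           n_loci=10, sigma_pollen=60.0, sigma_seed=2.0,
                           seed=7)
    return simulate_spatial(cfg)
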