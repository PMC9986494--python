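"""Synthetic SSR genotype generators.

Three generators cover the statistical structure the analysis stages assume:

* :func:`simulate_island` — coalescent finite-island model (optionally split
  into two regional groups with independent ancestries) with stepwise
  mutation, for F-statistics, clustering, and isolation-by-distance tests.
* :func:`simulate_bottleneck` — single population with a piecewise-constant
  size history and SMM/TPM mutation, for the heterozygosity-excess test.
* :func:`simulate_spatial` — a forward, spatially explicit individual-based
  model with clonal propagation, partial selfing with abortion of selfed
  seed, and separate Gaussian pollen and seed dispersal kernels, for the
  fine-scale spatial genetic structure stage.

All generators are seed-deterministic and return ground-truth parameter
sidecars alongside the genotype table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

from msatpop.core import CoordinateSet, GenotypeTable

__all__ = [
    "IslandSimConfig",
    "SpatialSimConfig",
    "simulate_island",
    "simulate_bottleneck",
    "simulate_spatial",
    "thin_ramets",
]

# allele-size state space for the msprime microsatellite models
_LO, _HI = 1, 400
_ROOT = (_LO + _HI) // 2


def _mutation_model(name: str, p_single: float = 0.7,
                    sigma2_geom: float = 30.0) -> msprime.MicrosatMutationModel:
    """SMM or TPM mutation model on the shared allele-size ladder.

    The TPM multi-step magnitude is geometric with variance `sigma2_geom`
    (the same parametrisation as the bottleneck test's equilibrium
    simulator, so generator and test can share one mutation model).
    """
    if name == "smm":
        return msprime.SMM(lo=_LO, hi=_HI)
    if name == "tpm":
        q = (-1.0 + np.sqrt(1.0 + 4.0 * sigma2_geom)) / (2.0 * sigma2_geom)
        return msprime.TPM(p=p_single, m=q, lo=_LO, hi=_HI)
    raise ValueError(f"unknown mutation model {name!r}")


def _genotypes_from_replicates(replicates, n_individuals: int, n_loci: int,
                               rate: float, model, seed_seq: np.random.SeedSequence
                               ) -> np.ndarray:
    """Overlay microsat mutations on each locus tree and read genotypes."""
    alleles = np.full((n_individuals, n_loci, 2), _ROOT, dtype=np.int64)
    child_seeds = seed_seq.generate_state(n_loci) % (2**31 - 1) + 1
    for j, ts in enumerate(replicates):
        mts = msprime.sim_mutations(ts, rate=rate, model=model,
                                    random_seed=int(child_seeds[j]))
        if mts.num_sites == 0:
            continue
        var = next(mts.variants())
        sizes = np.array([int(a) for a in var.alleles])[var.genotypes]
        # node order: two sample nodes per individual, individuals in order
        alleles[:, j, 0] = sizes[0::2]
        alleles[:, j, 1] = sizes[1::2]
    return alleles


# ----------------------------------------------------------------------
# island / divergence model
# ----------------------------------------------------------------------

@dataclass
class IslandSimConfig:
    """Finite-island model configuration.

    With `regions`, demes are grouped; demes within a region exchange
    migrants at `migration` and merge into a regional ancestor at
    `divergence_time`, and the regional ancestors merge at
    `region_divergence_time`.  Without regions all demes form one island
    system merging into a single ancestor at `divergence_time`.
    """

    n_pops: int = 20
    pop_size: int = 500
    n_sample: int = 16
    migration: float = 1e-3
    n_loci: int = 14
    mutation_rate: float = 5e-4
    mutation_model: str = "smm"
    regions: dict[str, str] | None = None  # pop name -> region
    divergence_time: float | None = None  # demes -> (region) ancestor
    region_divergence_time: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_pops < 2 or self.pop_size < 2 or self.n_sample < 2:
            raise ValueError("need >=2 demes with >=2 sampled diploids each")
        if not 0.0 <= self.migration <= 1.0:
            raise ValueError("migration rate must be in [0, 1]")
        if self.divergence_time is None:
            self.divergence_time = 10.0 * self.pop_size

    def pop_names(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_pops)]


def _island_demography(cfg: IslandSimConfig) -> msprime.Demography:
    dem = msprime.Demography()
    names = cfg.pop_names()
    for name in names:
        dem.add_population(name=name, initial_size=cfg.pop_size)
    if cfg.regions:
        region_of = {p: cfg.regions.get(p, "R1") for p in names}
        regions = sorted(set(region_of.values()))
        for r in regions:
            dem.add_population(name=f"ANC_{r}", initial_size=cfg.pop_size)
        if len(regions) > 1:
            dem.add_population(name="ANC", initial_size=cfg.pop_size)
        # migration only within regions
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if region_of[a] == region_of[b]:
                    dem.set_symmetric_migration_rate([a, b], cfg.migration)
        for r in regions:
            dem.add_population_split(
                time=cfg.divergence_time,
                derived=[p for p in names if region_of[p] == r],
                ancestral=f"ANC_{r}",
            )
        if len(regions) > 1:
            t2 = cfg.region_divergence_time or 2.0 * cfg.divergence_time
            dem.add_population_split(time=t2,
                                     derived=[f"ANC_{r}" for r in regions],
                                     ancestral="ANC")
    else:
        dem.add_population(name="ANC", initial_size=cfg.pop_size)
        if cfg.migration > 0:
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    dem.set_symmetric_migration_rate([a, b], cfg.migration)
        dem.add_population_split(time=cfg.divergence_time, derived=names,
                                 ancestral="ANC")
    dem.sort_events()
    return dem


def simulate_island(cfg: IslandSimConfig) -> tuple[GenotypeTable, dict]:
    """Simulate SSR genotypes under the island model; returns (table, truth)."""
    names = cfg.pop_names()
    dem = _island_demography(cfg)
    seq = np.random.SeedSequence(cfg.seed)
    anc_seed = int(seq.generate_state(1)[0] % (2**31 - 1)) + 1
    reps = msprime.sim_ancestry(
        samples={n: cfg.n_sample for n in names}, demography=dem,
        sequence_length=1, num_replicates=cfg.n_loci, random_seed=anc_seed,
    )
    n_ind = cfg.n_pops * cfg.n_sample
    model = _mutation_model(cfg.mutation_model)
    alleles = _genotypes_from_replicates(reps, n_ind, cfg.n_loci,
                                         cfg.mutation_rate, model,
                                         seq.spawn(1)[0])
    ids = [f"{p}_{i + 1:03d}" for p in names for i in range(cfg.n_sample)]
    pops = [p for p in names for _ in range(cfg.n_sample)]
    loci = [f"L{j + 1:02d}" for j in range(cfg.n_loci)]
    table = GenotypeTable(ids=ids, loci=loci, alleles=alleles, pops=pops,
                          regions=dict(cfg.regions) if cfg.regions else None)
    truth = {
        "Nm": cfg.pop_size * cfg.migration,
        "migration": cfg.migration,
        "pop_size": cfg.pop_size,
        "divergence_time": cfg.divergence_time,
        "regions": dict(cfg.regions) if cfg.regions else None,
        "seed": cfg.seed,
    }
    return table, truth


# ----------------------------------------------------------------------
# bottleneck histories
# ----------------------------------------------------------------------

def simulate_bottleneck(history: list[tuple[float, float]], n_loci: int = 10,
                        sample_size: int = 30, mutation_rate: float = 5e-4,
                        mutation_model: str = "smm", p_single: float = 0.7,
                        sigma2_geom: float = 30.0,
                        seed: int | None = None) -> tuple[GenotypeTable, dict]:
    """Single population with a piecewise-constant size history.

    `history` lists ``(time_generations_ago, diploid_size)`` with the first
    entry at time 0 (the present size); later entries change the size
    backwards in time.
    """
    if not history or history[0][0] != 0:
        raise ValueError("history must start with (0, present_size)")
    times = [t for t, _ in history]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("history times must be strictly increasing")
    dem = msprime.Demography()
    dem.add_population(name="P1", initial_size=history[0][1])
    for t, size in history[1:]:
        dem.add_population_parameters_change(time=t, population="P1",
                                             initial_size=size)
    seq = np.random.SeedSequence(seed)
    anc_seed = int(seq.generate_state(1)[0] % (2**31 - 1)) + 1
    reps = msprime.sim_ancestry(samples={"P1": sample_size}, demography=dem,
                                sequence_length=1, num_replicates=n_loci,
                                random_seed=anc_seed)
    model = _mutation_model(mutation_model, p_single, sigma2_geom)
    alleles = _genotypes_from_replicates(reps, sample_size, n_loci,
                                         mutation_rate, model, seq.spawn(1)[0])
    table = GenotypeTable(
        ids=[f"P1_{i + 1:03d}" for i in range(sample_size)],
        loci=[f"L{j + 1:02d}" for j in range(n_loci)],
        alleles=alleles, pops=["P1"] * sample_size,
    )
    return table, {"history": history, "mutation_rate": mutation_rate,
                   "mutation_model": mutation_model, "seed": seed}


# ----------------------------------------------------------------------
# spatially explicit forward model
# ----------------------------------------------------------------------

@dataclass
class SpatialSimConfig:
    """Forward individual-based model on a planar arena.

    Each (non-overlapping) generation, `capacity` offspring are produced:
    a mother is drawn uniformly; with probability `clonal_prob` the
    offspring is a ramet placed within `clonal_radius` of the mother;
    otherwise a father is drawn by the Gaussian pollen kernel (the mother
    herself with probability `selfing_rate`, and selfed seed is aborted
    with probability `self_abortion`), and the seed disperses from the
    mother by the Gaussian seed kernel.  Alleles mutate by single repeat
    steps at `mutation_rate` per gamete, reflecting at size 1.
    """

    arena: float = 300.0  # side of the square arena, metres
    capacity: int = 120
    clonal_prob: float = 0.3
    clonal_radius: float = 0.1
    selfing_rate: float = 0.3
    self_abortion: float = 0.8
    sigma_pollen: float = 50.0
    sigma_seed: float = 5.0
    n_loci: int = 14
    mutation_rate: float = 5e-4
    generations: int = 50
    n_founder_alleles: int = 8
    seed: int | None = None

    def __post_init__(self) -> None:
        for p in (self.clonal_prob, self.selfing_rate, self.self_abortion):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.sigma_pollen <= 0 or self.sigma_seed <= 0:
            raise ValueError("dispersal kernels must be positive")
        if self.generations < 1:
            raise ValueError("need at least 1 generation")


class ExtinctionError(RuntimeError):
    """Raised when the forward model fails to produce viable offspring."""

    def __init__(self, generation: int):
        super().__init__(f"population went extinct at generation {generation}")
        self.generation = generation


def _reflect(x: np.ndarray, size: float) -> np.ndarray:
    x = np.mod(x, 2 * size)
    return np.where(x > size, 2 * size - x, x)


def simulate_spatial(cfg: SpatialSimConfig
                     ) -> tuple[GenotypeTable, CoordinateSet, dict]:
    """Run the forward spatial model; returns (table, coords, truth)."""
    rng = np.random.default_rng(cfg.seed)
    n, L = cfg.capacity, cfg.n_loci
    pos = rng.uniform(0, cfg.arena, size=(n, 2))
    founder_pool = np.arange(20, 20 + cfg.n_founder_alleles)
    geno = rng.choice(founder_pool, size=(n, L, 2))

    def gamete(parent_idx: int) -> np.ndarray:
        g = geno[parent_idx, np.arange(L), rng.integers(0, 2, size=L)].copy()
        mut = rng.random(L) < cfg.mutation_rate
        if mut.any():
            g[mut] += rng.choice((-1, 1), size=int(mut.sum()))
            g[mut] = np.maximum(g[mut], 1)  # reflecting boundary at size 1
        return g

    for gen in range(cfg.generations):
        new_pos = np.empty_like(pos)
        new_geno = np.empty_like(geno)
        produced = 0
        attempts = 0
        max_attempts = 200 * n
        while produced < n:
            attempts += 1
            if attempts > max_attempts:
                raise ExtinctionError(gen)
            mother = int(rng.integers(n))
            if rng.random() < cfg.clonal_prob:
                r = cfg.clonal_radius * np.sqrt(rng.random())
                ang = rng.uniform(0, 2 * np.pi)
                new_pos[produced] = pos[mother] + r * np.array(
                    [np.cos(ang), np.sin(ang)]
                )
                new_geno[produced] = geno[mother]
            else:
                if rng.random() < cfg.selfing_rate:
                    if rng.random() < cfg.self_abortion:
                        continue  # selfed seed aborted
                    father = mother
                else:
                    d2 = ((pos - pos[mother]) ** 2).sum(axis=1)
                    w = np.exp(-d2 / (2 * cfg.sigma_pollen**2))
                    w[mother] = 0.0
                    total = w.sum()
                    if total <= 0:
                        continue
                    father = int(rng.choice(n, p=w / total))
                new_geno[produced, :, 0] = gamete(mother)
                new_geno[produced, :, 1] = gamete(father)
                new_pos[produced] = pos[mother] + rng.normal(
                    0, cfg.sigma_seed, size=2
                )
            new_pos[produced] = _reflect(new_pos[produced], cfg.arena)
            produced += 1
        pos, geno = new_pos, new_geno

    ids = [f"S{i + 1:04d}" for i in range(n)]
    table = GenotypeTable(
        ids=ids, loci=[f"L{j + 1:02d}" for j in range(L)],
        alleles=geno.astype(np.int64), pops=["SP1"] * n,
    )
    coords = CoordinateSet(labels=ids, xy=pos, mode="planar")
    truth = {"sigma_pollen": cfg.sigma_pollen, "sigma_seed": cfg.sigma_seed,
             "clonal_prob": cfg.clonal_prob, "selfing_rate": cfg.selfing_rate,
             "seed": cfg.seed}
    return table, coords, truth


def thin_ramets(table: GenotypeTable, coords: CoordinateSet,
                min_spacing: float = 0.1) -> tuple[GenotypeTable, CoordinateSet]:
    """Greedily drop individuals within `min_spacing` metres of a kept one.

    Mirrors a field protocol that avoids sampling putative ramets of the
    same genet growing on top of each other.
    """
    xy = coords.get(table.ids)
    keep: list[int] = []
    for i in range(table.n_individuals):
        if all(np.hypot(*(xy[i] - xy[j])) >= min_spacing for j in keep):
            keep.append(i)
    thinned = table.subset_individuals(keep)
    return thinned, CoordinateSet(labels=list(thinned.ids), xy=xy[keep],
                                  mode="planar")
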