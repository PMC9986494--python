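"""Heterozygosity-excess bottleneck detection under a two-phase mutation model.

A recently contracted population loses rare alleles faster than gene
diversity, so its expected heterozygosity He exceeds the equilibrium value
Heq expected for the observed number of alleles.  The test simulates, per
locus, the distribution of Heq conditional on the observed allele count and
sample size under a neutral coalescent with two-phase (TPM) microsatellite
mutation: a mutation is a single repeat step with probability ``p_single``,
otherwise a multi-step jump with geometrically distributed magnitude whose
variance is ``sigma2_geom``.  Significance across loci uses a one-sided
Wilcoxon signed-rank test on the standardised deviations
``DH = (He - E[Heq]) / SD[Heq]``; the mode-shift diagnostic checks whether
the pooled allele-frequency histogram keeps its neutral L shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from msatpop.core import MISSING, GenotypeTable

__all__ = [
    "TPMParams",
    "BottleneckResult",
    "simulate_heq",
    "heterozygosity_excess_test",
    "mode_shift",
]


@dataclass(frozen=True)
class TPMParams:
    """Two-phase mutation model settings for the equilibrium simulation.

    Parameters
    ----------
    p_single :
        Probability that a mutation changes the repeat number by exactly one
        step (the strict stepwise component).  1.0 gives a pure SMM; 0.0 a
        multi-step-only model.
    sigma2_geom :
        Variance of the geometric distribution of multi-step jump sizes.
    replicates :
        Number of accepted equilibrium genealogies per locus.
    seed :
        Seed for the simulation stream.
    """

    p_single: float = 0.7
    sigma2_geom: float = 30.0
    replicates: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_single <= 1.0:
            raise ValueError("p_single must be in [0, 1]")
        if self.sigma2_geom <= 0:
            raise ValueError("sigma2_geom must be positive")
        if self.replicates < 100:
            raise ValueError("use at least 100 replicates")

    @property
    def geom_q(self) -> float:
        """Success probability of the geometric jump-size distribution.

        For a geometric on {1, 2, ...} with success probability q the
        variance is (1-q)/q^2; q is solved from ``sigma2_geom``.
        """
        s2 = self.sigma2_geom
        return (-1.0 + np.sqrt(1.0 + 4.0 * s2)) / (2.0 * s2)


@dataclass
class BottleneckResult:
    group: str
    per_locus: pd.DataFrame  # locus, n_genes, k, He_obs, Heq_mean, Heq_sd, DH
    wilcoxon_p: float | None  # one-sided, He > Heq
    n_loci_tested: int
    params: TPMParams
    mode_shift_histogram: np.ndarray | None = None
    mode_shift_verdict: str | None = None
    notes: list[str] = field(default_factory=list)


# ----------------------------------------------------------------------
# coalescent + TPM simulation
# ----------------------------------------------------------------------

def _simulate_batch(n: int, theta: float, params: TPMParams,
                    rng: np.random.Generator, n_rep: int) -> tuple[np.ndarray, np.ndarray]:
    """Simulate `n_rep` equilibrium genealogies of `n` gene copies.

    Returns (k, He_unbiased) arrays.  Time is in units of 2N generations;
    mutations arrive on each branch at rate theta/2 per unit time.
    """
    ks = np.empty(n_rep, dtype=int)
    hes = np.empty(n_rep)
    q = params.geom_q
    for rep in range(n_rep):
        n_nodes = 2 * n - 1
        parent = np.full(n_nodes, -1, dtype=np.int64)
        node_time = np.zeros(n_nodes)
        active = list(range(n))
        t = 0.0
        nxt = n
        for j in range(n, 1, -1):
            t += rng.exponential(2.0 / (j * (j - 1)))
            i1 = active.pop(int(rng.integers(len(active))))
            i2 = active.pop(int(rng.integers(len(active))))
            parent[i1] = nxt
            parent[i2] = nxt
            node_time[nxt] = t
            active.append(nxt)
            nxt += 1
        blen = node_time[parent[:-1]] - node_time[np.arange(n_nodes - 1)]
        n_mut = rng.poisson(0.5 * theta * blen)
        total = int(n_mut.sum())
        if total:
            mag = np.ones(total, dtype=np.int64)
            multi = rng.random(total) >= params.p_single
            if multi.any():
                mag[multi] = rng.geometric(q, size=int(multi.sum()))
            steps = mag * rng.choice((-1, 1), size=total)
            per_branch = np.zeros(n_nodes - 1, dtype=np.int64)
            np.add.at(per_branch, np.repeat(np.arange(n_nodes - 1), n_mut), steps)
        else:
            per_branch = np.zeros(n_nodes - 1, dtype=np.int64)
        # propagate allele values root -> leaves (children precede parents)
        val = np.zeros(n_nodes, dtype=np.int64)
        for node in range(n_nodes - 2, -1, -1):
            val[node] = val[parent[node]] + per_branch[node]
        leaves = val[:n]
        _, counts = np.unique(leaves, return_counts=True)
        ks[rep] = len(counts)
        p = counts / n
        hes[rep] = (n / (n - 1)) * (1.0 - float(np.sum(p**2)))
    return ks, hes


def _theta_iam(n: int, k: int) -> float:
    """Closed-form infinite-alleles theta with E[k] = k (Ewens formula)."""
    lo, hi = 1e-4, 1e5
    i = np.arange(n)

    def ek(theta: float) -> float:
        return float(np.sum(theta / (theta + i)))

    for _ in range(60):
        mid = np.sqrt(lo * hi)
        if ek(mid) < k:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _calibrate_theta(n: int, k: int, params: TPMParams,
                     rng: np.random.Generator, pilot: int = 120) -> float:
    """Bisection on log(theta) so the expected allele count matches `k`.

    The infinite-alleles solution brackets the search: size homoplasy under
    stepwise mutation always demands a theta at or above the IAM value.
    """
    theta0 = _theta_iam(n, k)
    lo, hi = theta0 / 2.0, min(theta0 * 64.0, 1e5)

    def mean_k(theta: float) -> float:
        ks, _ = _simulate_batch(n, theta, params, rng, pilot)
        return float(ks.mean())

    if mean_k(hi) < k:
        return hi
    for _ in range(9):
        mid = float(np.sqrt(lo * hi))
        if mean_k(mid) < k:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_heq(n_genes: int, k_alleles: int, params: TPMParams,
                 rng: np.random.Generator | None = None,
                 max_attempts_factor: int = 200) -> np.ndarray:
    """Equilibrium He values conditional on `k_alleles` observed alleles.

    Simulates coalescent genealogies of `n_genes` gene copies with TPM
    mutations at a theta calibrated so the expected allele count matches
    `k_alleles`, then keeps replicates whose realised allele count equals it
    (rejection).  Returns at least ``params.replicates`` accepted unbiased
    He values, or raises ``RuntimeError`` after the attempt ceiling.
    """
    if not 2 <= k_alleles <= n_genes:
        raise ValueError("need 2 <= k_alleles <= n_genes")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    theta = _calibrate_theta(n_genes, k_alleles, params, rng)
    accepted: list[np.ndarray] = []
    n_acc = 0
    attempts = 0
    ceiling = max_attempts_factor * params.replicates
    batch = max(params.replicates, 500)
    while n_acc < params.replicates:
        if attempts >= ceiling:
            raise RuntimeError(
                f"could not condition on k={k_alleles} with n={n_genes}: "
                f"{n_acc} acceptances in {attempts} attempts"
            )
        ks, hes = _simulate_batch(n_genes, theta, params, rng, batch)
        hit = hes[ks == k_alleles]
        accepted.append(hit)
        n_acc += len(hit)
        attempts += batch
    return np.concatenate(accepted)[: max(params.replicates, n_acc)]


# ----------------------------------------------------------------------
# observed statistics and the test
# ----------------------------------------------------------------------

def _pooled_locus_obs(table: GenotypeTable) -> pd.DataFrame:
    """Per locus: pooled gene-copy count, allele count, unbiased He."""
    rows = []
    for j, locus in enumerate(table.loci):
        calls = table.alleles[:, j, :].ravel()
        calls = calls[calls != MISSING]
        n = len(calls)
        if n == 0:
            continue
        _, counts = np.unique(calls, return_counts=True)
        p = counts / n
        he = (n / (n - 1)) * (1.0 - float(np.sum(p**2))) if n > 1 else 0.0
        rows.append({"locus": locus, "n_genes": n, "k": len(counts), "He_obs": he})
    return pd.DataFrame(rows)


def _subset_group(table: GenotypeTable, group: str | list[str] | None) -> tuple[GenotypeTable, str]:
    if group is None:
        return table, "all"
    if isinstance(group, str):
        if table.regions and group in set(table.regions.values()):
            pops = [p for p in table.populations if table.regions[p] == group]
            return table.subset_populations(pops), group
        return table.subset_populations([group]), group
    return table.subset_populations(group), "+".join(group)


def heterozygosity_excess_test(table: GenotypeTable,
                               group: str | list[str] | None = None,
                               params: TPMParams = TPMParams(),
                               heq_cache: dict | None = None) -> BottleneckResult:
    """Bottleneck test for one group (population, region, or whole table).

    Per polymorphic locus the observed unbiased He is compared with the
    simulated equilibrium distribution conditional on that locus's allele
    count and gene-copy number; the one-sided Wilcoxon signed-rank test on
    the standardised deviations asks whether He systematically exceeds Heq.
    `heq_cache` (a dict keyed by (n, k, model settings)) lets repeated calls
    reuse conditional Heq distributions.

    The Wilcoxon p is exact for up to 25 loci, normal-approximated with
    continuity correction above.
    """
    sub, label = _subset_group(table, group)
    obs = _pooled_locus_obs(sub)
    obs = obs[obs["k"] >= 2].reset_index(drop=True)
    if obs.empty:
        raise ValueError(f"group {label!r}: all loci monomorphic, nothing to test")

    rng = np.random.default_rng(params.seed)
    means, sds = [], []
    notes: list[str] = []
    for row in obs.itertuples():
        key = (row.n_genes, row.k, params.p_single, params.sigma2_geom,
               params.replicates)
        if heq_cache is not None and key in heq_cache:
            mu, sd = heq_cache[key]
        else:
            heq = simulate_heq(row.n_genes, row.k, params, rng=rng)
            mu, sd = float(heq.mean()), float(heq.std(ddof=1))
            if heq_cache is not None:
                heq_cache[key] = (mu, sd)
        means.append(mu)
        sds.append(sd)
    obs["Heq_mean"] = means
    obs["Heq_sd"] = sds
    with np.errstate(invalid="ignore", divide="ignore"):
        obs["DH"] = (obs["He_obs"] - obs["Heq_mean"]) / obs["Heq_sd"]

    dh = obs["DH"].to_numpy()
    dh = dh[np.isfinite(dh)]
    if len(dh) < 2:
        wilcoxon_p = None
        notes.append("fewer than 2 usable loci: Wilcoxon p not computable")
    else:
        method = "exact" if len(dh) <= 25 else "approx"
        try:
            wilcoxon_p = float(
                sps.wilcoxon(dh, alternative="greater", method=method,
                             correction=(method == "approx")).pvalue
            )
        except ValueError:
            # ties/zeros force the approximate path
            wilcoxon_p = float(
                sps.wilcoxon(dh, alternative="greater", method="approx",
                             correction=True).pvalue
            )
        if len(dh) < 4:
            notes.append("fewer than 4 polymorphic loci: Wilcoxon p unreliable")

    hist, verdict = mode_shift(sub)
    return BottleneckResult(group=label, per_locus=obs, wilcoxon_p=wilcoxon_p,
                            n_loci_tested=len(dh), params=params,
                            mode_shift_histogram=hist,
                            mode_shift_verdict=verdict, notes=notes)


def mode_shift(table: GenotypeTable,
               group: str | list[str] | None = None) -> tuple[np.ndarray, str]:
    """Allele-frequency mode-shift (L-shape) diagnostic.

    Pools allele frequencies over all loci of the group, bins them into the
    ten classes (0, 0.1], ..., (0.9, 1.0], and declares the distribution
    ``L-shaped`` iff the lowest-frequency class holds the strict maximum
    count, ``shifted`` otherwise.  Returns (counts, verdict).
    """
    sub, _ = _subset_group(table, group)
    freqs: list[float] = []
    for j in range(sub.n_loci):
        calls = sub.alleles[:, j, :].ravel()
        calls = calls[calls != MISSING]
        if len(calls) == 0:
            continue
        _, counts = np.unique(calls, return_counts=True)
        freqs.extend((counts / len(calls)).tolist())
    edges = np.linspace(0.0, 1.0, 11)
    # right-closed bins (0, 0.1], ..., (0.9, 1.0]
    idx = np.clip(np.ceil(np.asarray(freqs) * 10).astype(int) - 1, 0, 9)
    hist = np.bincount(idx, minlength=10)
    verdict = "L-shaped" if hist[0] > hist[1:].max() else "shifted"
    return hist, verdict
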