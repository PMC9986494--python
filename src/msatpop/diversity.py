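"""Per-locus and per-population diversity and fixation statistics.

The estimators follow the Nei heterozygosity formulation used by classic SSR
spreadsheet workflows: per population x locus, ``Ne = 1/sum(p^2)``,
``He = 1 - sum(p^2)``, ``I = -sum(p ln p)``, and ``Ho`` the observed
heterozygote fraction.  Per-locus fixation indices are

    Fis = 1 - Ho/Hs,   Fit = 1 - Ho/Ht,   Fst = 1 - Hs/Ht,

with ``Hs`` the unweighted mean within-population He, and ``Ht`` computed
from unweighted mean allele frequencies across populations, so the
hierarchical identity ``(1 - Fit) = (1 - Fis)(1 - Fst)`` holds exactly at
every locus.  Gene flow is the island-model ``Nm = (1 - Fst)/(4 Fst)``, and
the standardised fixation index ``F'st = Fst / Fstmax`` divides by the
maximum Fst attainable given the observed within-population diversity
(computed by relabelling every allele population-uniquely and recomputing).

He is the plain ``1 - sum(p^2)`` (the spreadsheet default); the unbiased
``2N/(2N-1)`` correction is available via ``unbiased=True`` where noted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from msatpop.core import (
    MISSING,
    AlleleFreqTable,
    GenotypeTable,
    allele_frequencies,
)

__all__ = [
    "locus_summaries",
    "population_summaries",
    "hwe_exact",
    "null_allele_screen",
    "fst_standardized",
    "per_pop_locus_stats",
]


# ----------------------------------------------------------------------
# building block: per population x locus statistics
# ----------------------------------------------------------------------

def per_pop_locus_stats(table: GenotypeTable,
                        freqs: AlleleFreqTable | None = None) -> dict[str, np.ndarray]:
    """Arrays of shape (n_pops, n_loci): He, Ho, Ne, I, k (allele count), n.

    Cells with zero typed individuals are NaN (k and n are 0).
    """
    if freqs is None:
        freqs = allele_frequencies(table)
    pops, loci = freqs.pops, freqs.loci
    shape = (len(pops), len(loci))
    He = np.full(shape, np.nan)
    Ho = np.full(shape, np.nan)
    Ne = np.full(shape, np.nan)
    I = np.full(shape, np.nan)
    k = np.zeros(shape, dtype=int)
    n = np.zeros(shape, dtype=int)
    pops_arr = np.asarray(table.pops)
    for i, pop in enumerate(pops):
        sub = table.alleles[pops_arr == pop]
        for j, locus in enumerate(loci):
            f = freqs.freqs.get((pop, locus))
            if not f:
                continue
            p = np.asarray(list(f.values()))
            He[i, j] = 1.0 - np.sum(p**2)
            Ne[i, j] = 1.0 / np.sum(p**2)
            I[i, j] = float(-np.sum(p * np.log(p)))
            k[i, j] = len(p)
            n[i, j] = freqs.n[(pop, locus)]
            calls = sub[:, j, :]
            typed = calls[:, 0] != MISSING
            Ho[i, j] = float((calls[typed, 0] != calls[typed, 1]).mean())
    return {"He": He, "Ho": Ho, "Ne": Ne, "I": I, "k": k, "n": n,
            "pops": pops, "loci": loci}


def _ht_per_locus(freqs: AlleleFreqTable) -> np.ndarray:
    """Total heterozygosity from unweighted mean allele frequencies."""
    out = np.full(len(freqs.loci), np.nan)
    for j, locus in enumerate(freqs.loci):
        mat, alleles = freqs.matrix(locus)
        has_data = mat.sum(axis=1) > 0
        if not has_data.any() or not alleles:
            continue
        pbar = mat[has_data].mean(axis=0)
        out[j] = 1.0 - np.sum(pbar**2)
    return out


# ----------------------------------------------------------------------
# Table-2-shaped per-locus report
# ----------------------------------------------------------------------

_LOCUS_COLS = ["Nt", "Na", "Ne", "Ho", "He", "Ht", "I",
               "Fis", "Fit", "Fst", "Fprime_st", "Nm"]


def locus_summaries(table: GenotypeTable) -> pd.DataFrame:
    """Per-locus diversity and F-statistics plus an unweighted means row.

    Columns: Nt (total alleles pooled), Na/Ne/Ho/He/I (unweighted means of
    per-population values), Ht, Fis, Fit, Fst, F'st, Nm.  Loci monomorphic
    overall have undefined Fst-family statistics (NaN) and are excluded from
    the means row for those columns.
    """
    if len(table.populations) < 2:
        raise ValueError("F-statistics require at least 2 populations")
    freqs = allele_frequencies(table)
    stats = per_pop_locus_stats(table, freqs)
    pooled = allele_frequencies(table, level="total")
    Ht = _ht_per_locus(freqs)

    with np.errstate(invalid="ignore", divide="ignore"):
        Na = np.nanmean(np.where(stats["k"] > 0, stats["k"], np.nan), axis=0)
        Ne = np.nanmean(stats["Ne"], axis=0)
        Ho = np.nanmean(stats["Ho"], axis=0)
        Hs = np.nanmean(stats["He"], axis=0)
        I = np.nanmean(stats["I"], axis=0)
        Fis = 1.0 - Ho / Hs
        Fit = 1.0 - Ho / Ht
        Fst = 1.0 - Hs / Ht
        Nm = (1.0 - Fst) / (4.0 * Fst)
    Nt = np.array([len(pooled.freqs.get(("total", l), {})) for l in freqs.loci])

    fprime = fst_standardized(table, freqs=freqs, fst=Fst)

    df = pd.DataFrame(
        {
            "Nt": Nt.astype(float), "Na": Na, "Ne": Ne, "Ho": Ho, "He": Hs,
            "Ht": Ht, "I": I, "Fis": Fis, "Fit": Fit, "Fst": Fst,
            "Fprime_st": fprime, "Nm": Nm,
        },
        index=pd.Index(freqs.loci, name="locus"),
    )
    # a locus monomorphic overall has Ht == 0: Fst family undefined there
    mono = Ht <= 0
    if mono.any():
        df.loc[mono, ["Fis", "Fit", "Fst", "Fprime_st", "Nm"]] = np.nan
    df.loc["Mean"] = df.mean(axis=0, skipna=True)
    return df[_LOCUS_COLS]


# ----------------------------------------------------------------------
# Table-3-shaped per-population report
# ----------------------------------------------------------------------

def population_summaries(table: GenotypeTable,
                         group_means: bool = True) -> pd.DataFrame:
    """Per-population diversity metrics plus optional regional group means.

    Columns: Nt (alleles summed over loci), Np (private alleles vs. all other
    populations pooled), Na, Ne, Ho, He, I (unweighted means over loci),
    Fis (mean over polymorphic loci of (He-Ho)/He), PPL (% polymorphic loci).
    """
    freqs = allele_frequencies(table)
    stats = per_pop_locus_stats(table, freqs)
    pops, loci = stats["pops"], stats["loci"]

    # private alleles: present in this population, absent everywhere else
    Np = np.zeros(len(pops), dtype=int)
    for j, locus in enumerate(loci):
        mat, alleles = freqs.matrix(locus)
        present = mat > 0
        n_holders = present.sum(axis=0)
        for i in range(len(pops)):
            Np[i] += int((present[i] & (n_holders == 1)).sum())

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = 1.0 - stats["Ho"] / stats["He"]
    rows = {}
    for i, pop in enumerate(pops):
        k = stats["k"][i].astype(float)
        poly = stats["He"][i] > 0
        rows[pop] = {
            "Nt": float(np.sum(k[k > 0])),
            "Np": float(Np[i]),
            "Na": float(np.nanmean(np.where(k > 0, k, np.nan))),
            "Ne": float(np.nanmean(stats["Ne"][i])),
            "Ho": float(np.nanmean(stats["Ho"][i])),
            "He": float(np.nanmean(stats["He"][i])),
            "I": float(np.nanmean(stats["I"][i])),
            "Fis": float(np.nanmean(ratio[i][poly])) if poly.any() else np.nan,
            "PPL": 100.0 * float(np.mean(stats["k"][i][stats["k"][i] > 0] >= 2))
            if (stats["k"][i] > 0).any() else np.nan,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "population"

    if group_means and table.regions:
        groups: dict[str, list[str]] = {}
        for pop in pops:
            groups.setdefault(table.regions.get(pop, "ungrouped"), []).append(pop)
        for region, members in groups.items():
            df.loc[f"Mean ({region})"] = df.loc[members].mean(axis=0)
        df.loc["Overall Mean"] = df.loc[list(pops)].mean(axis=0)
    return df


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte Carlo)
# ----------------------------------------------------------------------

def _log_conditional_prob(genotypes: np.ndarray, n_a: dict[int, int]) -> float:
    """Log conditional probability of a genotype array given allele counts.

    Levene's conditional distribution: P = n! 2^h prod(n_a!) / ((2n)! prod(n_ij!)).
    """
    n = genotypes.shape[0]
    het = genotypes[:, 0] != genotypes[:, 1]
    pairs = np.sort(genotypes, axis=1)
    _, counts = np.unique(pairs, axis=0, return_counts=True)
    logp = (
        gammaln(n + 1)
        + het.sum() * np.log(2.0)
        + sum(gammaln(c + 1) for c in n_a.values())
        - gammaln(2 * n + 1)
        - np.sum(gammaln(counts + 1))
    )
    return float(logp)


@dataclass
class HWECell:
    pop: str
    locus: str
    p: float
    se: float
    n: int
    iterations: int


def hwe_exact(table: GenotypeTable, iterations: int = 10_000,
              seed: int | None = None) -> pd.DataFrame:
    """Monte-Carlo exact Hardy-Weinberg test per population x locus.

    Resamples genotype arrays by random re-pairing of the observed gene
    copies (conditioning on allele counts) and reports
    ``p = P(conditional probability <= observed)`` with the add-one
    correction, plus the Monte-Carlo standard error.  Cells with fewer than
    2 distinct alleles are reported with p = 1.
    """
    rng = np.random.default_rng(seed)
    pops_arr = np.asarray(table.pops)
    records = []
    for pop in table.populations:
        sub = table.alleles[pops_arr == pop]
        for j, locus in enumerate(table.loci):
            calls = sub[:, j, :]
            calls = calls[calls[:, 0] != MISSING]
            n = calls.shape[0]
            copies = calls.ravel()
            uniq, cnt = np.unique(copies, return_counts=True)
            if len(uniq) < 2 or n < 2:
                records.append(HWECell(pop, locus, 1.0, 0.0, n, 0))
                continue
            n_a = dict(zip(uniq.tolist(), cnt.tolist()))
            obs = _log_conditional_prob(calls, n_a)
            hits = 0
            work = copies.copy()
            for _ in range(iterations):
                rng.shuffle(work)
                sim = _log_conditional_prob(work.reshape(-1, 2), n_a)
                if sim <= obs + 1e-12:
                    hits += 1
            p = (hits + 1) / (iterations + 1)
            se = float(np.sqrt(p * (1 - p) / iterations))
            records.append(HWECell(pop, locus, p, se, n, iterations))
    return pd.DataFrame([r.__dict__ for r in records])


# ----------------------------------------------------------------------
# Null-allele screening
# ----------------------------------------------------------------------

def null_allele_screen(table: GenotypeTable,
                       hwe: pd.DataFrame | None = None,
                       hwe_iterations: int = 2_000,
                       seed: int | None = None,
                       threshold: float = 0.05) -> pd.DataFrame:
    """Closed-form null-allele frequency estimates per population x locus.

    Chakraborty's ``r = (He - Ho)/(He + Ho)`` and the Brookfield-1 estimator
    ``(He - Ho)/(1 + He)``.  A cell is flagged when the Chakraborty estimate
    exceeds `threshold` *and* the homozygote excess is significant by the
    Hardy-Weinberg exact test (p < 0.05 with Ho < He).  Pass a precomputed
    `hwe` frame (from :func:`hwe_exact`) to avoid re-running the test.
    """
    stats = per_pop_locus_stats(table)
    if hwe is None:
        hwe = hwe_exact(table, iterations=hwe_iterations, seed=seed)
    pmap = {(r.pop, r.locus): r.p for r in hwe.itertuples()}
    records = []
    for i, pop in enumerate(stats["pops"]):
        for j, locus in enumerate(stats["loci"]):
            He, Ho = stats["He"][i, j], stats["Ho"][i, j]
            if not np.isfinite(He) or (He + Ho) == 0:
                r = np.nan
                bf = np.nan
            else:
                r = (He - Ho) / (He + Ho)
                bf = (He - Ho) / (1 + He)
            flagged = bool(
                np.isfinite(r)
                and r > threshold
                and Ho < He
                and pmap.get((pop, locus), 1.0) < 0.05
            )
            records.append(
                {"pop": pop, "locus": locus, "chakraborty": r,
                 "brookfield1": bf, "flagged": flagged}
            )
    return pd.DataFrame(records)


# ----------------------------------------------------------------------
# Standardised Fst
# ----------------------------------------------------------------------

def _recode_population_unique(table: GenotypeTable) -> GenotypeTable:
    """Relabel every allele population-uniquely.

    Within-population genotype structure (hence Hs and Ho) is preserved, but
    no allele is shared between populations, which maximises Fst given the
    within-population diversity.
    """
    new = table.alleles.copy()
    pops_arr = np.asarray(table.pops)
    for j in range(table.n_loci):
        code = 1
        for pop in table.populations:
            mask = pops_arr == pop
            col = new[mask, j, :]
            mapping: dict[int, int] = {}
            for a in np.unique(col):
                if a == MISSING:
                    continue
                mapping[a] = code
                code += 1
            for a, c in mapping.items():
                col[table.alleles[mask, j, :] == a] = c
            new[mask, j, :] = col
    return GenotypeTable(ids=list(table.ids), loci=list(table.loci),
                         alleles=new, pops=list(table.pops),
                         regions=table.regions)


def fst_standardized(table: GenotypeTable,
                     freqs: AlleleFreqTable | None = None,
                     fst: np.ndarray | None = None) -> np.ndarray:
    """Per-locus F'st = Fst / Fstmax.

    Fstmax is the Fst of the same table after relabelling every allele
    population-uniquely.  Returns NaN where Fstmax is undefined or zero.
    """
    if len(table.populations) < 2:
        raise ValueError("F'st requires at least 2 populations")
    if freqs is None:
        freqs = allele_frequencies(table)
    if fst is None:
        stats = per_pop_locus_stats(table, freqs)
        Hs = np.nanmean(stats["He"], axis=0)
        Ht = _ht_per_locus(freqs)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = 1.0 - Hs / Ht

    recoded = _recode_population_unique(table)
    rfreqs = allele_frequencies(recoded)
    rstats = per_pop_locus_stats(recoded, rfreqs)
    Hs_max = np.nanmean(rstats["He"], axis=0)
    Ht_max = _ht_per_locus(rfreqs)
    with np.errstate(invalid="ignore", divide="ignore"):
        fstmax = 1.0 - Hs_max / Ht_max
        out = np.where(np.abs(fstmax) > 1e-15, fst / fstmax, np.nan)
    return out
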