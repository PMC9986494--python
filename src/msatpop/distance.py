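"""Between-population structure: distances, NJ, PCoA, AMOVA, Mantel, Delta-K.

Distances: Nei's (1972) standard genetic distance between populations (J
terms summed over loci before the ratio), squared genotypic distances
between individuals (the codominant allele-count metric), and geographic
distances (haversine km between sites, Euclidean metres within a site).

Structure: Saitou-Nei neighbour joining, principal coordinate analysis by
Gower double-centering, a two-level hierarchical AMOVA (region / population
/ individual) with permutation significance, Mantel isolation-by-distance
tests, and Evanno's Delta-K post-processing of clustering log-likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import squareform

from msatpop.core import MISSING, AlleleFreqTable, CoordinateSet, GenotypeTable

__all__ = [
    "DistanceMatrix",
    "nei_distance",
    "nj_tree",
    "pcoa",
    "amova",
    "AMOVAResult",
    "mantel",
    "MantelResult",
    "geographic_distances",
    "squared_genotypic_distance",
    "evanno_delta_k",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with labels and a metric tag."""

    labels: list[str]
    values: np.ndarray
    metric: str = "unknown"
    capped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0, atol=1e-10):
            raise ValueError("distance matrix must have a zero diagonal")
        if not np.isfinite(self.values).all():
            raise ValueError("distance matrix entries must be finite (cap infinities)")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ----------------------------------------------------------------------
# Genetic distances
# ----------------------------------------------------------------------

def nei_distance(freqs: AlleleFreqTable, cap: float = 10.0) -> DistanceMatrix:
    """Nei's (1972) standard genetic distance between populations.

    ``D = -ln( Jxy / sqrt(Jx * Jy) )`` with the identity terms summed over
    loci before the ratio.  Population pairs sharing no alleles at any locus
    have infinite D; those are capped at `cap` and recorded in ``capped``.
    """
    pops = freqs.pops
    if len(pops) < 2:
        raise ValueError("Nei distance requires at least 2 populations")
    # per-locus frequency matrices, aligned on the union of alleles
    mats = [freqs.matrix(locus)[0] for locus in freqs.loci]
    n = len(pops)
    D = np.zeros((n, n))
    capped: list[tuple[str, str]] = []
    for x in range(n):
        for y in range(x + 1, n):
            jx = sum(float(m[x] @ m[x]) for m in mats)
            jy = sum(float(m[y] @ m[y]) for m in mats)
            jxy = sum(float(m[x] @ m[y]) for m in mats)
            if jx == 0 or jy == 0:
                raise ValueError(f"population {pops[x] if jx == 0 else pops[y]} "
                                 "has no allele data")
            if jxy <= 0:
                d = cap
                capped.append((pops[x], pops[y]))
            else:
                d = -np.log(jxy / np.sqrt(jx * jy))
                d = min(max(d, 0.0), cap)
            D[x, y] = D[y, x] = d
    return DistanceMatrix(labels=pops, values=D, metric="nei_standard", capped=capped)


def squared_genotypic_distance(table: GenotypeTable) -> DistanceMatrix:
    """Squared genotypic distance between individuals (codominant metric).

    Per locus, ``d^2 = 0.5 * sum_a (c_ia - c_ja)^2`` over allele counts
    ``c`` in {0,1,2}, giving the canonical values 0 (same genotype),
    1 (ii/ij or ij/ik), 2 (ij/kl), 3 (ii/jk), 4 (ii/jj); loci are summed.
    Pairs missing at some loci are rescaled by L / L_available.
    """
    n, L = table.n_individuals, table.n_loci
    # one-hot allele counts per individual x locus
    per_locus: list[np.ndarray] = []
    typed = np.zeros((n, L), dtype=bool)
    for j in range(L):
        calls = table.alleles[:, j, :]
        alleles = np.unique(calls[calls != MISSING])
        counts = np.zeros((n, len(alleles)))
        for a_idx, a in enumerate(alleles):
            counts[:, a_idx] = (calls == a).sum(axis=1)
        per_locus.append(counts)
        typed[:, j] = calls[:, 0] != MISSING

    D = np.zeros((n, n))
    avail = np.zeros((n, n))
    for j in range(L):
        c = per_locus[j]
        t = typed[:, j].astype(float)
        both = np.outer(t, t)
        sq = ((c[:, None, :] - c[None, :, :]) ** 2).sum(axis=2) * 0.5
        D += sq * both
        avail += both
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(avail > 0, D * (L / np.maximum(avail, 1)), 0.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(labels=list(table.ids), values=D,
                          metric="squared_genotypic")


def geographic_distances(coords: CoordinateSet) -> DistanceMatrix:
    """Geographic distance matrix: haversine km (geodetic) or Euclidean m."""
    xy = coords.xy
    if coords.mode == "geodetic":
        lat = np.radians(xy[:, 0])[:, None]
        lon = np.radians(xy[:, 1])[:, None]
        dlat = lat - lat.T
        dlon = lon - lon.T
        a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
        metric = "geographic_km"
    else:
        diff = xy[:, None, :] - xy[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        metric = "euclidean_m"
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(labels=coords.labels, values=d, metric=metric)


# ----------------------------------------------------------------------
# Neighbour joining
# ----------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> str:
    """Saitou-Nei neighbour joining; returns an unrooted newick string.

    Negative branch lengths are clamped to zero with the deficit transferred
    to the sister branch, keeping the path length between the joined pair.
    """
    if dm.n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    d = dm.values.astype(float).copy()
    nodes: list[str] = [_quote(l) for l in dm.labels]
    active = list(range(dm.n))
    # grow the matrix as internal nodes are added
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        i, j = active[i_], active[j_]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = f"({nodes[i]}:{li:.17g},{nodes[j]}:{lj:.17g})"
        # distances from the new node u to every other active node
        du = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            du[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = du[:-1]
        d[:-1, -1] = du[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]
    # join the last three nodes at a single internal vertex
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return (f"({nodes[a]}:{la:.17g},{nodes[b]}:{lb:.17g},"
            f"{nodes[c]}:{lc:.17g});")


def _quote(label: str) -> str:
    if any(ch in label for ch in " (),:;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ----------------------------------------------------------------------
# Principal coordinate analysis
# ----------------------------------------------------------------------

@dataclass
class PCoAResult:
    labels: list[str]
    coordinates: np.ndarray  # (n, n_axes) for axes with positive eigenvalue
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # over positive eigenvalues only

    def to_frame(self) -> pd.DataFrame:
        cols = [f"Axis{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Principal coordinate analysis by Gower double-centering of -D^2/2.

    Axes are ordered by eigenvalue; negative eigenvalues (non-Euclidean
    input) are reported but excluded from coordinates and from the
    proportion of variance explained.
    """
    d = dm.values
    n = d.shape[0]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    vals, vecs = eigh((g + g.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-10 * abs(vals).max(), 1e-12)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    prop = vals[pos] / vals[pos].sum() if pos.any() else np.array([])
    return PCoAResult(labels=list(dm.labels), coordinates=coords,
                      eigenvalues=vals, proportion_explained=prop)


# ----------------------------------------------------------------------
# AMOVA
# ----------------------------------------------------------------------

@dataclass
class AMOVAResult:
    """Hierarchical AMOVA table and Phi-statistics.

    ``components`` are the raw (possibly negative) variance components;
    ``percentages`` use components clamped at zero.  ``p_values`` hold the
    permutation p for each Phi statistic that applies to the design.
    """

    df: dict[str, int]
    sums_of_squares: dict[str, float]
    components: dict[str, float]
    percentages: dict[str, float]
    phi: dict[str, float]
    p_values: dict[str, float]
    permutations: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.components:
            rows.append(
                {"source": name, "df": self.df.get(name, np.nan),
                 "SS": self.sums_of_squares.get(name, np.nan),
                 "variance": self.components[name],
                 "percent": self.percentages[name]}
            )
        rows.append({"source": "Total", "df": sum(self.df.values()),
                     "SS": sum(self.sums_of_squares.values()),
                     "variance": sum(max(v, 0.0) for v in self.components.values()),
                     "percent": 100.0})
        return pd.DataFrame(rows)


def _ss_within_groups(d2: np.ndarray, groups: np.ndarray) -> float:
    """Sum over groups of (sum of pairwise squared distances)/group size."""
    ss = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss


def _amova_components(d2: np.ndarray, pops: np.ndarray,
                      regions: np.ndarray | None):
    """Variance components by the standard AMOVA moment equations."""
    n_tot = d2.shape[0]
    ss_total = d2[np.triu_indices(n_tot, 1)].sum() / n_tot
    ss_wp = _ss_within_groups(d2, pops)
    pop_labels, pop_sizes = np.unique(pops, return_counts=True)
    b = len(pop_labels)
    size_of = dict(zip(pop_labels, pop_sizes))

    if regions is None:
        df_ap, df_wp = b - 1, n_tot - b
        ss_ap = ss_total - ss_wp
        ms_wp = ss_wp / df_wp if df_wp else np.nan
        ms_ap = ss_ap / df_ap if df_ap else np.nan
        n0 = (n_tot - sum(s**2 for s in pop_sizes) / n_tot) / (b - 1)
        sig_c = ms_wp
        sig_b = (ms_ap - sig_c) / n0
        return (
            {"among_populations": df_ap, "within_populations": df_wp},
            {"among_populations": ss_ap, "within_populations": ss_wp},
            {"among_populations": sig_b, "within_populations": sig_c},
        )

    region_labels = np.unique(regions)
    a = len(region_labels)
    ss_wr = _ss_within_groups(d2, regions)
    ss_ar = ss_total - ss_wr
    ss_ap = ss_wr - ss_wp
    df_ar, df_ap, df_wp = a - 1, b - a, n_tot - b
    ms_wp = ss_wp / df_wp if df_wp else np.nan
    ms_ap = ss_ap / df_ap if df_ap else np.nan
    ms_ar = ss_ar / df_ar if df_ar else np.nan

    # Excoffier's coefficients for unbalanced two-level designs
    region_of_pop: dict = {}
    for p, r in zip(pops, regions):
        region_of_pop[p] = r
    n_r = {r: int((regions == r).sum()) for r in region_labels}
    sum_np2_over_nr = sum(
        sum(size_of[p] ** 2 for p in pop_labels if region_of_pop[p] == r) / n_r[r]
        for r in region_labels
    )
    sum_np2 = sum(s**2 for s in pop_sizes)
    sum_nr2 = sum(v**2 for v in n_r.values())
    n1 = (n_tot - sum_np2_over_nr) / (b - a)
    n2 = (sum_np2_over_nr - sum_np2 / n_tot) / (a - 1)
    n3 = (n_tot - sum_nr2 / n_tot) / (a - 1)

    sig_c = ms_wp
    sig_b = (ms_ap - sig_c) / n1
    sig_a = (ms_ar - sig_c - n2 * sig_b) / n3
    return (
        {"among_regions": df_ar, "among_populations_within_regions": df_ap,
         "within_populations": df_wp},
        {"among_regions": ss_ar, "among_populations_within_regions": ss_ap,
         "within_populations": ss_wp},
        {"among_regions": sig_a, "among_populations_within_regions": sig_b,
         "within_populations": sig_c},
    )


def amova(table: GenotypeTable, permutations: int = 1000,
          seed: int | None = None,
          dm: DistanceMatrix | None = None) -> AMOVAResult:
    """Hierarchical AMOVA on squared genotypic distances between individuals.

    With regional labels the design is two-level (region / population within
    region / individual within population); without, one-level.  Permutation
    p-values: individuals among populations (overall and within regions) and
    whole populations among regions, with `permutations` draws each.
    """
    if permutations < 99:
        raise ValueError("use at least 99 permutations")
    if dm is None:
        dm = squared_genotypic_distance(table)
    d2 = dm.values
    pops = np.asarray(table.pops)
    regions = None
    if table.regions:
        regions = np.asarray([table.regions[p] for p in table.pops])
        if len(np.unique(regions)) < 2:
            regions = None

    df, ss, comp = _amova_components(d2, pops, regions)
    clamped = {k: max(v, 0.0) for k, v in comp.items()}
    total = sum(clamped.values())
    pct = {k: (100.0 * v / total if total > 0 else np.nan)
           for k, v in clamped.items()}

    phi: dict[str, float] = {}
    if regions is None:
        sig_b, sig_c = comp["among_populations"], comp["within_populations"]
        tot = sig_b + sig_c
        phi["Phi_ST"] = sig_b / tot if tot > 0 else np.nan
    else:
        sig_a = comp["among_regions"]
        sig_b = comp["among_populations_within_regions"]
        sig_c = comp["within_populations"]
        tot = sig_a + sig_b + sig_c
        phi["Phi_CT"] = sig_a / tot if tot > 0 else np.nan
        phi["Phi_SC"] = sig_b / (sig_b + sig_c) if (sig_b + sig_c) > 0 else np.nan
        phi["Phi_ST"] = (sig_a + sig_b) / tot if tot > 0 else np.nan

    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}

    def perm_p(observed, stat_fn, permuter):
        if not np.isfinite(observed):
            return np.nan
        hits = 0
        for _ in range(permutations):
            val = stat_fn(*permuter())
            if np.isfinite(val) and val >= observed - 1e-12:
                hits += 1
        return (hits + 1) / (permutations + 1)

    if regions is None:

        def phi_st(p, r):
            _, _, c = _amova_components(d2, p, None)
            t = c["among_populations"] + c["within_populations"]
            return c["among_populations"] / t if t > 0 else np.nan

        p_values["Phi_ST"] = perm_p(
            phi["Phi_ST"], phi_st, lambda: (rng.permutation(pops), None)
        )
    else:

        def phi_st2(p, r):
            _, _, c = _amova_components(d2, p, r)
            t = sum(c.values())
            num = c["among_regions"] + c["among_populations_within_regions"]
            return num / t if t > 0 else np.nan

        def phi_sc(p, r):
            _, _, c = _amova_components(d2, p, r)
            den = (c["among_populations_within_regions"] + c["within_populations"])
            return (c["among_populations_within_regions"] / den
                    if den > 0 else np.nan)

        def phi_ct(p, r):
            _, _, c = _amova_components(d2, p, r)
            t = sum(c.values())
            return c["among_regions"] / t if t > 0 else np.nan

        # individuals among all populations (keeping pop sizes)
        def permute_all():
            perm = rng.permutation(len(pops))
            return pops[perm], regions[perm]

        # individuals among populations within their region
        def permute_within_regions():
            p = pops.copy()
            for r in np.unique(regions):
                idx = np.flatnonzero(regions == r)
                p[idx] = p[rng.permutation(idx)]
            return p, regions

        # whole populations among regions
        pop_labels = np.unique(pops)
        pop_region = np.asarray([table.regions[p] for p in pop_labels])

        def permute_pops_among_regions():
            shuffled = pop_region[rng.permutation(len(pop_labels))]
            mapping = dict(zip(pop_labels, shuffled))
            return pops, np.asarray([mapping[p] for p in pops])

        p_values["Phi_ST"] = perm_p(phi["Phi_ST"], phi_st2, permute_all)
        p_values["Phi_SC"] = perm_p(phi["Phi_SC"], phi_sc, permute_within_regions)
        p_values["Phi_CT"] = perm_p(phi["Phi_CT"], phi_ct,
                                    permute_pops_among_regions)

    return AMOVAResult(df=df, sums_of_squares=ss, components=comp,
                       percentages=pct, phi=phi, p_values=p_values,
                       permutations=permutations, seed=seed)


# ----------------------------------------------------------------------
# Mantel test
# ----------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    slope: float
    intercept: float
    permutations: int
    seed: int | None


def mantel(dm1: DistanceMatrix, dm2: DistanceMatrix, permutations: int = 1000,
           seed: int | None = None) -> MantelResult:
    """One-sided Mantel test between two distance matrices.

    ``r`` is the Pearson correlation over the off-diagonal upper triangle;
    ``p`` is the proportion of label permutations of `dm2` with r at least
    the observed value (add-one corrected).  The least-squares regression of
    dm2-entries on dm1-entries (slope, intercept) is also returned.
    """
    if dm1.labels != dm2.labels:
        raise ValueError("distance matrices must share the same labels in order")
    if permutations < 99:
        raise ValueError("use at least 99 permutations")
    n = dm1.n
    iu = np.triu_indices(n, 1)
    x = dm1.values[iu]
    y = dm2.values[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Mantel r undefined for a constant distance matrix")
    xc = (x - x.mean()) / x.std()

    def corr(yv: np.ndarray) -> float:
        return float(np.mean(xc * (yv - yv.mean()) / yv.std()))

    r_obs = corr(y)
    slope, intercept = np.polyfit(x, y, 1)
    rng = np.random.default_rng(seed)
    hits = 0
    vals = dm2.values
    for _ in range(permutations):
        perm = rng.permutation(n)
        yp = vals[np.ix_(perm, perm)][iu]
        if corr(yp) >= r_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return MantelResult(r=r_obs, p=p, slope=float(slope),
                        intercept=float(intercept),
                        permutations=permutations, seed=seed)


# ----------------------------------------------------------------------
# Evanno Delta-K
# ----------------------------------------------------------------------

def evanno_delta_k(lk_table: pd.DataFrame | dict[int, list[float]]) -> pd.DataFrame:
    """Evanno's Delta-K from replicate clustering log-likelihoods.

    `lk_table` maps K -> replicate L(K) values (a dict, or a DataFrame with
    columns ``K`` and ``logL``).  For each interior K,
    ``DeltaK = mean_r |L_r(K+1) - 2 L_r(K) + L_r(K-1)| / sd(L(K))``.
    Returns a frame indexed by K with columns ``mean_L``, ``sd_L``,
    ``delta_K``, and attribute-style best K in ``.attrs['best_K']``.
    A zero replicate SD yields an infinite Delta-K, which is flagged.
    """
    if isinstance(lk_table, pd.DataFrame):
        grouped: dict[int, list[float]] = {
            int(k): g["logL"].tolist() for k, g in lk_table.groupby("K")
        }
    else:
        grouped = {int(k): list(v) for k, v in lk_table.items()}
    ks = sorted(grouped)
    if len(ks) < 3 or any(ks[i + 1] - ks[i] != 1 for i in range(len(ks) - 1)):
        raise ValueError("need at least 3 consecutive K values")
    if any(len(grouped[k]) < 2 for k in ks):
        raise ValueError("need at least 2 replicates per K")
    n_rep = min(len(grouped[k]) for k in ks)

    rows = []
    for k in ks:
        reps = np.asarray(grouped[k][:n_rep], dtype=float)
        mean_l, sd_l = float(reps.mean()), float(reps.std(ddof=1))
        if k == ks[0] or k == ks[-1]:
            delta = np.nan
        else:
            second = np.abs(
                np.asarray(grouped[k + 1][:n_rep])
                - 2 * reps
                + np.asarray(grouped[k - 1][:n_rep])
            )
            delta = float(second.mean() / sd_l) if sd_l > 0 else np.inf
        rows.append({"K": k, "mean_L": mean_l, "sd_L": sd_l, "delta_K": delta})
    out = pd.DataFrame(rows).set_index("K")
    finite = out["delta_K"].replace(np.inf, np.nan).dropna()
    interior = out["delta_K"].dropna()
    best = int(interior.idxmax()) if len(interior) else None
    out.attrs["best_K"] = best
    out.attrs["delta_K_infinite"] = bool(np.isinf(out["delta_K"]).any())
    _ = finite
    return out
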