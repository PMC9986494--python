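"""Core data model: genotype tables, coordinates, and allele frequencies.

Genotypes are diploid, codominant allele sizes (integer base-pair or repeat
counts).  A call at one locus is an unordered pair of positive integers; a
missing call is the pair ``(0, 0)`` — partially missing calls are invalid.
Every individual belongs to exactly one population; populations may carry an
optional regional group label (e.g. an island vs. mainland split).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Reserved allele value marking a missing call.
MISSING = 0


class ValidationError(ValueError):
    """Raised when a table or coordinate set violates its invariants."""


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele-size matrix with population labels.

    Parameters
    ----------
    ids :
        Ordered individual identifiers (unique).
    loci :
        Ordered locus names.
    alleles :
        Integer array of shape ``(n_individuals, n_loci, 2)``; allele sizes
        are positive, missing calls are ``(0, 0)``.
    pops :
        Population label per individual.
    regions :
        Optional mapping population -> regional group label.
    """

    ids: list[str]
    loci: list[str]
    alleles: np.ndarray
    pops: list[str]
    regions: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.loci = [str(l) for l in self.loci]
        self.pops = [str(p) for p in self.pops]
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        n, L = len(self.ids), len(self.loci)
        if n < 2:
            raise ValidationError("a genotype table needs at least 2 individuals")
        if self.alleles.shape != (n, L, 2):
            raise ValidationError(
                f"allele array shape {self.alleles.shape} != ({n}, {L}, 2)"
            )
        if len(self.pops) != n:
            raise ValidationError("one population label per individual required")
        if len(set(self.ids)) != n:
            raise ValidationError("individual identifiers must be unique")
        if (self.alleles < 0).any():
            raise ValidationError("allele sizes must be positive (0 reserved for missing)")
        half_missing = (self.alleles == MISSING).sum(axis=2) == 1
        if half_missing.any():
            i, j = np.argwhere(half_missing)[0]
            raise ValidationError(
                f"call for {self.ids[i]} at {self.loci[j]} is half-missing; "
                "a call is either two alleles or fully missing"
            )
        if self.regions is not None:
            missing_pops = set(self.pops) - set(self.regions)
            if missing_pops:
                raise ValidationError(
                    f"regions mapping lacks populations: {sorted(missing_pops)}"
                )

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.pops:
            seen.setdefault(p)
        return list(seen)

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {p: 0 for p in self.populations}
        for p in self.pops:
            sizes[p] += 1
        return sizes

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` array, True where the call is missing."""
        return (self.alleles == MISSING).all(axis=2)

    def missing_fraction(self) -> np.ndarray:
        """Per-individual fraction of missing loci."""
        return self.missing_mask().mean(axis=1)

    def flag_high_missing(self, threshold: float = 0.5) -> list[str]:
        """Identifiers of individuals with more than `threshold` missing loci."""
        frac = self.missing_fraction()
        return [i for i, f in zip(self.ids, frac) if f > threshold]

    # ------------------------------------------------------------------
    def subset_individuals(self, keep: Sequence[int] | np.ndarray) -> "GenotypeTable":
        keep = np.asarray(keep)
        return GenotypeTable(
            ids=[self.ids[i] for i in keep],
            loci=list(self.loci),
            alleles=self.alleles[keep],
            pops=[self.pops[i] for i in keep],
            regions=self.regions,
        )

    def subset_populations(self, pops: Iterable[str]) -> "GenotypeTable":
        wanted = set(pops)
        unknown = wanted - set(self.pops)
        if unknown:
            raise KeyError(f"unknown populations: {sorted(unknown)}")
        keep = [i for i, p in enumerate(self.pops) if p in wanted]
        return self.subset_individuals(keep)

    def region_of(self, pop: str) -> str | None:
        if self.regions is None:
            return None
        return self.regions.get(pop)

    def pooled(self, label: str = "pooled") -> "GenotypeTable":
        """Same genotypes with all individuals relabelled to one population."""
        return GenotypeTable(
            ids=list(self.ids),
            loci=list(self.loci),
            alleles=self.alleles.copy(),
            pops=[label] * self.n_individuals,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        # calls are unordered pairs: compare after sorting within the pair
        return (
            self.ids == other.ids
            and self.loci == other.loci
            and self.pops == other.pops
            and np.array_equal(np.sort(self.alleles, 2), np.sort(other.alleles, 2))
        )


@dataclass
class CoordinateSet:
    """Planar (metres) or geodetic (decimal-degree) sampling coordinates.

    Planar mode stores per-individual x/y in metres within a site; geodetic
    mode stores per-population latitude/longitude for between-site distances.
    The two modes are never mixed in one set.
    """

    labels: list[str]
    xy: np.ndarray  # (n, 2): (x, y) metres or (lat, lon) degrees
    mode: str = "planar"  # "planar" | "geodetic"

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.xy = np.asarray(self.xy, dtype=float)
        if self.mode not in ("planar", "geodetic"):
            raise ValidationError(f"unknown coordinate mode {self.mode!r}")
        if self.xy.shape != (len(self.labels), 2):
            raise ValidationError("coordinate array must be (n_labels, 2)")
        if not np.isfinite(self.xy).all():
            raise ValidationError("coordinates must be finite")
        if self.mode == "geodetic":
            lat = self.xy[:, 0]
            if (np.abs(lat) > 90).any():
                raise ValidationError("latitude outside [-90, 90]")

    def get(self, labels: Sequence[str]) -> np.ndarray:
        index = {l: i for i, l in enumerate(self.labels)}
        try:
            rows = [index[l] for l in labels]
        except KeyError as e:
            raise KeyError(f"no coordinates for {e.args[0]!r}") from None
        return self.xy[rows]


@dataclass
class AlleleFreqTable:
    """Relative allele frequencies per population x locus.

    ``freqs[(pop, locus)]`` maps allele -> relative frequency among the
    non-missing gene copies; ``n[(pop, locus)]`` is the count of non-missing
    *individuals*.  Population x locus cells with zero observations are
    absent from both maps and listed in ``empty``.
    """

    pops: list[str]
    loci: list[str]
    freqs: dict[tuple[str, str], dict[int, float]]
    n: dict[tuple[str, str], int]
    empty: list[tuple[str, str]] = field(default_factory=list)

    def alleles_at(self, locus: str) -> list[int]:
        """Sorted union of alleles observed at `locus` across populations."""
        seen: set[int] = set()
        for pop in self.pops:
            seen.update(self.freqs.get((pop, locus), {}))
        return sorted(seen)

    def matrix(self, locus: str) -> tuple[np.ndarray, list[int]]:
        """Frequencies as a (n_pops, n_alleles) array plus the allele order."""
        alleles = self.alleles_at(locus)
        out = np.zeros((len(self.pops), len(alleles)))
        col = {a: j for j, a in enumerate(alleles)}
        for i, pop in enumerate(self.pops):
            for a, f in self.freqs.get((pop, locus), {}).items():
                out[i, col[a]] = f
        return out, alleles


def allele_counts(table: GenotypeTable) -> dict[tuple[str, str], dict[int, int]]:
    """Raw allele counts (gene copies) per population x locus."""
    counts: dict[tuple[str, str], dict[int, int]] = {}
    pops = np.asarray(table.pops)
    for pop in table.populations:
        sub = table.alleles[pops == pop]
        for j, locus in enumerate(table.loci):
            calls = sub[:, j, :].ravel()
            calls = calls[calls != MISSING]
            key = (pop, locus)
            vals, cnt = np.unique(calls, return_counts=True)
            counts[key] = dict(zip(vals.tolist(), cnt.tolist()))
    return counts


def allele_frequencies(table: GenotypeTable, level: str = "population") -> AlleleFreqTable:
    """Relative allele frequencies per population (or pooled) x locus.

    Missing calls are excluded from denominators.  At ``level="total"`` the
    frequencies are computed from the pooled gene-copy counts of all
    individuals, which equals the sample-size-weighted mean of population
    frequencies.
    """
    if level not in ("population", "total"):
        raise ValueError(f"level must be 'population' or 'total', got {level!r}")
    work = table if level == "population" else table.pooled("total")
    counts = allele_counts(work)
    freqs: dict[tuple[str, str], dict[int, float]] = {}
    nmap: dict[tuple[str, str], int] = {}
    empty: list[tuple[str, str]] = []
    pops_arr = np.asarray(work.pops)
    for pop in work.populations:
        sub = work.alleles[pops_arr == pop]
        for j, locus in enumerate(work.loci):
            key = (pop, locus)
            total = sum(counts[key].values())
            if total == 0:
                empty.append(key)
                continue
            freqs[key] = {a: c / total for a, c in counts[key].items()}
            nmap[key] = int((sub[:, j, 0] != MISSING).sum())
    return AlleleFreqTable(
        pops=work.populations, loci=list(work.loci), freqs=freqs, n=nmap, empty=empty
    )
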