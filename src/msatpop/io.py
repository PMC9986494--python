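"""Readers and writers for genotype and coordinate exchange formats.

Supported formats:

* **GenAlEx-style CSV** — the de-facto spreadsheet layout for codominant SSR
  data: two count/header rows, then one row per individual with two allele
  columns per locus.  Real-world files vary, so the parser is tolerant but
  validates explicitly and names the offending line in error messages.
* **Plain long CSV** — one row per individual x locus
  (``id,pop,region,locus,allele1,allele2``); trivially diff-able and the
  format that preserves regional group labels on round-trip.
* **STRUCTURE text** — write-only export: two rows per individual, integer
  alleles, missing coded ``-9``.
* **Coordinates CSV** — ``id,x,y`` (planar metres) or ``pop,lat,lon``
  (geodetic decimal degrees), detected from the header.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from msatpop.core import MISSING, CoordinateSet, GenotypeTable, ValidationError


class FormatError(ValueError):
    """Raised when an input file does not match the declared dialect."""


# ----------------------------------------------------------------------
# GenAlEx dialect
# ----------------------------------------------------------------------

def _read_genalex(path: Path) -> GenotypeTable:
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)]
    if len(rows) < 4:
        raise FormatError(f"{path}: GenAlEx file needs >= 4 rows, found {len(rows)}")

    def ints(cells, line_no):
        out = []
        for c in cells:
            c = c.strip()
            if not c:
                break
            try:
                out.append(int(c))
            except ValueError:
                raise FormatError(
                    f"{path}: line {line_no}: expected integer count, got {c!r}"
                ) from None
        return out

    counts = ints(rows[0], 1)
    if len(counts) < 3:
        raise FormatError(
            f"{path}: line 1 must carry at least n_loci, n_samples, n_pops"
        )
    n_loci, n_samples, n_pops = counts[:3]
    pop_sizes = counts[3 : 3 + n_pops]
    # row 2: title + population names over the size columns (both optional)
    pop_names = [c.strip() for c in rows[1][3 : 3 + n_pops] if c.strip()]
    if len(pop_names) != n_pops:
        pop_names = [f"pop{i + 1}" for i in range(n_pops)]

    header = [c.strip() for c in rows[2]]
    if len(header) < 2 + 2 * n_loci:
        raise FormatError(
            f"{path}: line 3: header has {len(header)} columns, "
            f"need {2 + 2 * n_loci} for {n_loci} loci"
        )
    loci = [header[2 + 2 * j] or f"locus{j + 1}" for j in range(n_loci)]

    data = [r for r in rows[3:] if any(c.strip() for c in r)]
    if len(data) != n_samples:
        raise FormatError(
            f"{path}: header declares {n_samples} samples, found {len(data)} data rows"
        )
    if pop_sizes and sum(pop_sizes) != n_samples:
        raise FormatError(
            f"{path}: line 1: population sizes {pop_sizes} sum to "
            f"{sum(pop_sizes)}, not {n_samples}"
        )

    ids, pops = [], []
    alleles = np.zeros((n_samples, n_loci, 2), dtype=np.int64)
    # population assignment: the per-row pop column wins; the size blocks are
    # used when the column is blank
    block_pop: list[str] = []
    for name, size in zip(pop_names, pop_sizes):
        block_pop.extend([name] * size)
    for i, row in enumerate(data):
        line_no = 4 + i
        row = [c.strip() for c in row]
        if len(row) < 2 + 2 * n_loci:
            raise FormatError(
                f"{path}: line {line_no}: {len(row)} columns, need {2 + 2 * n_loci}"
            )
        ids.append(row[0] or f"ind{i + 1}")
        pops.append(row[1] or (block_pop[i] if i < len(block_pop) else "pop1"))
        for j in range(n_loci):
            for k in (0, 1):
                cell = row[2 + 2 * j + k]
                if cell in ("", "0", "-9"):
                    alleles[i, j, k] = MISSING
                else:
                    try:
                        alleles[i, j, k] = int(cell)
                    except ValueError:
                        raise FormatError(
                            f"{path}: line {line_no}: non-integer allele {cell!r}"
                        ) from None
    return GenotypeTable(ids=ids, loci=loci, alleles=alleles, pops=pops)


def _write_genalex(table: GenotypeTable, path: Path) -> None:
    pops = table.populations
    sizes = table.population_sizes()
    n_loci = table.n_loci
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([n_loci, table.n_individuals, len(pops)] + [sizes[p] for p in pops])
        w.writerow(["msatpop export", "", ""] + pops)
        header = ["Ind", "Pop"]
        for locus in table.loci:
            header += [locus, ""]
        w.writerow(header)
        # GenAlEx groups individuals by population block
        order = [i for p in pops for i, q in enumerate(table.pops) if q == p]
        for i in order:
            row = [table.ids[i], table.pops[i]]
            for j in range(n_loci):
                row += [int(table.alleles[i, j, 0]), int(table.alleles[i, j, 1])]
            w.writerow(row)


# ----------------------------------------------------------------------
# Plain long dialect
# ----------------------------------------------------------------------

_LONG_HEADER = ["id", "pop", "region", "locus", "allele1", "allele2"]


def _read_plain(path: Path) -> GenotypeTable:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = [c.strip() for c in next(reader)]
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if header != _LONG_HEADER:
            raise FormatError(
                f"{path}: line 1: expected header {','.join(_LONG_HEADER)}, "
                f"got {','.join(header)}"
            )
        rows = [r for r in reader if any(c.strip() for c in r)]

    ids: list[str] = []
    pops_of: dict[str, str] = {}
    regions: dict[str, str] = {}
    loci: list[str] = []
    calls: dict[tuple[str, str], tuple[int, int]] = {}
    for k, row in enumerate(rows):
        line_no = k + 2
        if len(row) != 6:
            raise FormatError(f"{path}: line {line_no}: expected 6 columns")
        ind, pop, region, locus, a1, a2 = [c.strip() for c in row]
        if ind not in pops_of:
            ids.append(ind)
            pops_of[ind] = pop
        elif pops_of[ind] != pop:
            raise FormatError(
                f"{path}: line {line_no}: {ind!r} assigned to two populations"
            )
        if region:
            regions[pop] = region
        if locus not in loci:
            loci.append(locus)
        try:
            calls[(ind, locus)] = (int(a1), int(a2))
        except ValueError:
            raise FormatError(
                f"{path}: line {line_no}: non-integer allele"
            ) from None

    alleles = np.zeros((len(ids), len(loci), 2), dtype=np.int64)
    for i, ind in enumerate(ids):
        for j, locus in enumerate(loci):
            alleles[i, j] = calls.get((ind, locus), (MISSING, MISSING))
    return GenotypeTable(
        ids=ids,
        loci=loci,
        alleles=alleles,
        pops=[pops_of[i] for i in ids],
        regions=regions or None,
    )


def _write_plain(table: GenotypeTable, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_LONG_HEADER)
        for i, ind in enumerate(table.ids):
            pop = table.pops[i]
            region = table.region_of(pop) or ""
            for j, locus in enumerate(table.loci):
                w.writerow(
                    [ind, pop, region, locus,
                     int(table.alleles[i, j, 0]), int(table.alleles[i, j, 1])]
                )


# ----------------------------------------------------------------------
# Public API
# ----------------------------------------------------------------------

def read_genotypes(path: str | Path, dialect: str = "genalex_csv") -> GenotypeTable:
    """Read a genotype table from `path` in the given dialect.

    Parameters
    ----------
    dialect :
        ``"genalex_csv"`` or ``"plain_csv"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "genalex_csv":
        return _read_genalex(path)
    if dialect == "plain_csv":
        return _read_plain(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotypes(table: GenotypeTable, path: str | Path,
                    dialect: str = "genalex_csv") -> None:
    """Write `table` to `path` in the given dialect."""
    path = Path(path)
    if dialect == "genalex_csv":
        _write_genalex(table, path)
    elif dialect == "plain_csv":
        _write_plain(table, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_structure(table: GenotypeTable, path: str | Path) -> None:
    """Export in STRUCTURE's two-rows-per-individual text format.

    Columns: individual id, integer population index (1-based, order of first
    appearance), then one allele per locus.  Missing alleles are coded -9.
    """
    path = Path(path)
    pop_index = {p: i + 1 for i, p in enumerate(table.populations)}
    with open(path, "w") as fh:
        fh.write("\t".join(["ind", "pop"] + list(table.loci)) + "\n")
        for i, ind in enumerate(table.ids):
            for k in (0, 1):
                cells = [ind, str(pop_index[table.pops[i]])]
                for j in range(table.n_loci):
                    a = int(table.alleles[i, j, k])
                    cells.append(str(a) if a != MISSING else "-9")
                fh.write("\t".join(cells) + "\n")


def read_coordinates(path: str | Path) -> CoordinateSet:
    """Read a coordinate CSV; mode is detected from the header.

    ``id,x,y`` gives planar metres per individual; ``pop,lat,lon`` gives
    geodetic decimal degrees per population.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = [c.strip().lower() for c in next(reader)]
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if header == ["id", "x", "y"]:
            mode = "planar"
        elif header == ["pop", "lat", "lon"]:
            mode = "geodetic"
        else:
            raise FormatError(
                f"{path}: line 1: expected 'id,x,y' or 'pop,lat,lon' header"
            )
        labels, xy = [], []
        for k, row in enumerate(reader):
            if not any(c.strip() for c in row):
                continue
            if len(row) != 3:
                raise FormatError(f"{path}: line {k + 2}: expected 3 columns")
            labels.append(row[0].strip())
            try:
                xy.append((float(row[1]), float(row[2])))
            except ValueError:
                raise FormatError(
                    f"{path}: line {k + 2}: non-numeric coordinate"
                ) from None
    return CoordinateSet(labels=labels, xy=np.asarray(xy), mode=mode)


def write_coordinates(coords: CoordinateSet, path: str | Path) -> None:
    path = Path(path)
    header = ["id", "x", "y"] if coords.mode == "planar" else ["pop", "lat", "lon"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for label, (a, b) in zip(coords.labels, coords.xy):
            w.writerow([label, repr(float(a)), repr(float(b))])
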