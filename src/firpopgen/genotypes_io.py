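"""Data model and I/O for multi-population diploid microsatellite genotypes.

The central container is :class:`GenotypeDataset`, which stores allele-size
calls (integers, in base pairs) for every individual at every locus, plus the
individual→population and population→group (taxon) assignments.  All
downstream statistics operate on :class:`AlleleCounts` tables derived from it
via :func:`tally`.

Supported exchange formats:

* GenePop 4.x (2- or 3-digit allele encoding, ``POP``-delimited blocks);
* a tidy CSV genotype table (``individual,population,locus,allele1,allele2``);
* a sidecar metadata CSV (``population,taxon,lat,lon``) carrying taxon labels
  and coordinates, since GenePop has no group concept;
* PHYLIP square / Nexus ``distances`` exports of pairwise distance matrices
  (for external split-network software).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing allele (GenePop "000"/"00").
MISSING = 0

#: Conventional exclusion lists for the fir SSR panel: loci flagged by
#: null-allele / shared-repeat screening are dropped from every analysis,
#: and the indel-prone AB15 additionally from ABC runs.  These are plain
#: config filters — no detection logic lives in this package.
EXCLUDED_LOCI_STANDARD = ("SFb04", "NFF7", "SF324")
EXCLUDED_LOCI_ABC = ("SFb04", "NFF7", "SF324", "AB15")


class GenepopFormatError(ValueError):
    """Raised when a GenePop file violates the dialect this reader accepts."""


@dataclass(frozen=True)
class PopulationMeta:
    """Per-population metadata: taxon label and geographic position."""

    population: str
    taxon: str
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not self.taxon:
            raise ValueError(f"population {self.population!r}: empty taxon label")
        if abs(self.lat) > 90:
            raise ValueError(f"population {self.population!r}: |lat| > 90")
        if abs(self.lon) > 180:
            raise ValueError(f"population {self.population!r}: |lon| > 180")


@dataclass(frozen=True)
class AlleleCounts:
    """Allele → copy-count table for one locus in one population.

    ``n`` is the number of gene copies actually observed (missing calls are
    excluded entirely, so ``n`` may be odd after partial sampling).
    """

    locus: str
    population: str
    counts: dict[int, int]

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def n_alleles(self) -> int:
        return len(self.counts)

    def frequencies(self) -> dict[int, float]:
        n = self.n
        return {a: c / n for a, c in self.counts.items()} if n else {}

    def merge(self, other: "AlleleCounts") -> "AlleleCounts":
        """Pool copies with another table at the same locus."""
        if other.locus != self.locus:
            raise ValueError("cannot pool counts across different loci")
        merged = dict(self.counts)
        for a, c in other.counts.items():
            merged[a] = merged.get(a, 0) + c
        return AlleleCounts(self.locus, f"{self.population}+{other.population}", merged)


@dataclass
class GenotypeDataset:
    """Diploid multi-locus genotypes with population and group labels.

    ``calls`` has shape ``(n_individuals, n_loci, 2)`` with positive integer
    allele states (fragment sizes in bp) and :data:`MISSING` (0) for missing.
    A call is atomic: either both alleles present or both missing; half-missing
    input is promoted to fully missing with a logged warning.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    populations: dict[str, str]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"({len(self.individuals)}, {len(self.loci)}, 2)"
            )
        if self.calls.min(initial=0) < 0:
            raise ValueError("allele states must be positive (0 = missing)")
        missing_ind = set(self.individuals) - set(self.populations)
        if missing_ind:
            raise ValueError(f"individuals without population: {sorted(missing_ind)[:5]}")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            logger.warning(
                "promoting %d half-missing calls to fully missing", int(half.sum())
            )
            self.calls[half] = MISSING

    # -- views ------------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def population_ids(self) -> list[str]:
        """Populations in order of first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.populations[ind], None)
        return list(seen)

    def population_indices(self, population: str) -> np.ndarray:
        return np.array(
            [i for i, ind in enumerate(self.individuals) if self.populations[ind] == population],
            dtype=np.intp,
        )

    def pop_index_array(self) -> np.ndarray:
        """Integer population index per individual (order of ``population_ids``)."""
        pops = {p: i for i, p in enumerate(self.population_ids())}
        return np.array([pops[self.populations[ind]] for ind in self.individuals], dtype=np.intp)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    # -- subsetting -------------------------------------------------------

    def drop_loci(self, exclude: list[str]) -> "GenotypeDataset":
        """Config-level locus exclusion filter (e.g. pre-screened loci)."""
        keep = [i for i, loc in enumerate(self.loci) if loc not in set(exclude)]
        return GenotypeDataset(
            individuals=list(self.individuals),
            loci=[self.loci[i] for i in keep],
            calls=self.calls[:, keep, :].copy(),
            populations=dict(self.populations),
            groups=dict(self.groups),
        )

    def subset_populations(self, keep: list[str]) -> "GenotypeDataset":
        keep_set = set(keep)
        idx = [i for i, ind in enumerate(self.individuals) if self.populations[ind] in keep_set]
        inds = [self.individuals[i] for i in idx]
        return GenotypeDataset(
            individuals=inds,
            loci=list(self.loci),
            calls=self.calls[idx].copy(),
            populations={ind: self.populations[ind] for ind in inds},
            groups={p: g for p, g in self.groups.items() if p in keep_set},
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
            and self.populations == other.populations
        )


def tally(dataset: GenotypeDataset, locus: str, population: str) -> AlleleCounts:
    """Count allele copies at one locus in one population.

    Missing calls are excluded entirely; an empty population yields ``n = 0``.
    """
    j = dataset.locus_index(locus)
    idx = dataset.population_indices(population)
    alleles = dataset.calls[idx, j, :].ravel()
    alleles = alleles[alleles != MISSING]
    vals, cnts = np.unique(alleles, return_counts=True)
    return AlleleCounts(locus, population, dict(zip(vals.tolist(), cnts.tolist())))


def tally_all(dataset: GenotypeDataset) -> dict[tuple[str, str], AlleleCounts]:
    """Tally every (locus, population) combination in one pass."""
    out: dict[tuple[str, str], AlleleCounts] = {}
    for pop in dataset.population_ids():
        idx = dataset.population_indices(pop)
        for j, locus in enumerate(dataset.loci):
            alleles = dataset.calls[idx, j, :].ravel()
            alleles = alleles[alleles != MISSING]
            vals, cnts = np.unique(alleles, return_counts=True)
            out[(locus, pop)] = AlleleCounts(locus, pop, dict(zip(vals.tolist(), cnts.tolist())))
    return out


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def _detect_width(entry: str) -> int:
    if len(entry) in (4, 6):
        return len(entry) // 2
    raise GenepopFormatError(
        f"genotype entry {entry!r} is neither 4 (2-digit) nor 6 (3-digit) characters"
    )


def read_genepop(path: str | Path, metadata: dict[str, PopulationMeta] | None = None) -> GenotypeDataset:
    """Parse a GenePop 4.x file (2- or 3-digit encoding, POP-delimited).

    Population names are taken from the last individual label of each POP
    block, unless ``metadata`` (a sidecar, see :func:`read_metadata_csv`)
    names them — in that case sidecar populations are matched by block order
    when the block-derived name is absent from the sidecar.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopFormatError("empty file")
    body = lines[1:]  # first line is the title

    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        chunk = body[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if not loci:
        raise GenepopFormatError("no locus names before first POP")

    blocks: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] | None = None
    for lineno, raw in enumerate(body[i:], start=i + 2):
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            current = []
            blocks.append(current)
            continue
        if current is None:
            raise GenepopFormatError(f"line {lineno}: genotype data before POP")
        if "," not in line:
            raise GenepopFormatError(f"line {lineno}: missing ',' between label and genotypes")
        label, geno = line.split(",", 1)
        entries = geno.split()
        if len(entries) != len(loci):
            raise GenepopFormatError(
                f"line {lineno}: {len(entries)} genotype entries for {len(loci)} loci"
            )
        current.append((label.strip(), entries))

    if not blocks:
        raise GenepopFormatError("no POP blocks")

    width = _detect_width(blocks[0][0][1][0])
    individuals: list[str] = []
    populations: dict[str, str] = {}
    calls = np.zeros((sum(len(b) for b in blocks), len(loci), 2), dtype=np.int64)

    sidecar_pops = list(metadata) if metadata else []
    row = 0
    for b, block in enumerate(blocks):
        pop_name = block[-1][0]
        if metadata and pop_name not in metadata and b < len(sidecar_pops):
            pop_name = sidecar_pops[b]
        for k, (label, entries) in enumerate(block):
            ind = label if label not in populations else f"{label}.{b}.{k}"
            individuals.append(ind)
            populations[ind] = pop_name
            for j, entry in enumerate(entries):
                if _detect_width(entry) != width:
                    raise GenepopFormatError(
                        f"entry {entry!r}: inconsistent allele encoding width"
                    )
                a1, a2 = int(entry[:width]), int(entry[width:])
                calls[row, j] = (a1, a2)
            row += 1

    groups = {m.population: m.taxon for m in metadata.values()} if metadata else {}
    return GenotypeDataset(individuals, loci, calls, populations, groups)


def write_genepop(dataset: GenotypeDataset, path: str | Path, title: str = "firpopgen export", digits: int = 3) -> None:
    fmt = f"{{:0{digits}d}}"
    out = [title]
    out.extend(dataset.loci)
    for pop in dataset.population_ids():
        out.append("POP")
        for i in dataset.population_indices(pop):
            entries = [
                fmt.format(int(a1)) + fmt.format(int(a2))
                for a1, a2 in dataset.calls[i]
            ]
            out.append(f"{dataset.individuals[i]} , " + " ".join(entries))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# CSV genotype table and sidecar metadata
# ---------------------------------------------------------------------------

def read_genotype_csv(path: str | Path, metadata: dict[str, PopulationMeta] | None = None) -> GenotypeDataset:
    """Read a tidy genotype table: individual,population,locus,allele1,allele2."""
    df = pd.read_csv(path, dtype={"individual": str, "population": str, "locus": str})
    individuals = list(dict.fromkeys(df["individual"]))
    loci = list(dict.fromkeys(df["locus"]))
    ind_ix = {v: i for i, v in enumerate(individuals)}
    loc_ix = {v: j for j, v in enumerate(loci)}
    calls = np.zeros((len(individuals), len(loci), 2), dtype=np.int64)
    populations: dict[str, str] = {}
    for rec in df.itertuples(index=False):
        i, j = ind_ix[rec.individual], loc_ix[rec.locus]
        calls[i, j] = (int(rec.allele1), int(rec.allele2))
        populations[rec.individual] = rec.population
    groups = {m.population: m.taxon for m in metadata.values()} if metadata else {}
    return GenotypeDataset(individuals, loci, calls, populations, groups)


def write_genotype_csv(dataset: GenotypeDataset, path: str | Path) -> None:
    rows = []
    for i, ind in enumerate(dataset.individuals):
        for j, locus in enumerate(dataset.loci):
            a1, a2 = dataset.calls[i, j]
            rows.append((ind, dataset.populations[ind], locus, int(a1), int(a2)))
    pd.DataFrame(rows, columns=["individual", "population", "locus", "allele1", "allele2"]).to_csv(
        path, index=False
    )


def read_metadata_csv(path: str | Path) -> dict[str, PopulationMeta]:
    df = pd.read_csv(path, dtype={"population": str, "taxon": str})
    return {
        rec.population: PopulationMeta(rec.population, rec.taxon, float(rec.lat), float(rec.lon))
        for rec in df.itertuples(index=False)
    }


def write_metadata_csv(metadata: dict[str, PopulationMeta], path: str | Path) -> None:
    pd.DataFrame(
        [(m.population, m.taxon, m.lat, m.lon) for m in metadata.values()],
        columns=["population", "taxon", "lat", "lon"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Distance-matrix export (PHYLIP square / Nexus distances)
# ---------------------------------------------------------------------------

def _check_square(matrix: np.ndarray, labels: list[str]) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(labels):
        raise ValueError("matrix must be square and match the label list")
    if np.abs(m - m.T).max(initial=0.0) > 1e-10:
        raise ValueError("matrix is asymmetric beyond tolerance 1e-10")
    return m


def write_distance_matrix(matrix: np.ndarray, labels: list[str], path: str | Path, format: str = "phylip") -> None:
    """Export a symmetric distance matrix for external split-network software.

    ``format`` is ``"phylip"`` (square) or ``"nexus"`` (a ``distances`` block).
    Values are written with full precision (>= 6 significant digits; exact
    decimal inputs such as 0.1371 round-trip verbatim).
    """
    m = _check_square(matrix, labels)

    def fmt(x: float) -> str:
        return format_float(x)

    if format == "phylip":
        out = [f"{len(labels)}"]
        for lab, row in zip(labels, m):
            out.append(f"{lab:<12s}" + "  ".join(fmt(x) for x in row))
        Path(path).write_text("\n".join(out) + "\n")
    elif format == "nexus":
        out = [
            "#NEXUS",
            "BEGIN taxa;",
            f"  DIMENSIONS ntax={len(labels)};",
            "  TAXLABELS " + " ".join(labels) + ";",
            "END;",
            "BEGIN distances;",
            f"  DIMENSIONS ntax={len(labels)};",
            "  FORMAT triangle=both diagonal labels;",
            "  MATRIX",
        ]
        for lab, row in zip(labels, m):
            out.append(f"    {lab:<12s}" + "  ".join(fmt(x) for x in row))
        out.extend(["  ;", "END;"])
        Path(path).write_text("\n".join(out) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def format_float(x: float) -> str:
    """Shortest decimal representation with >= 6 significant digits."""
    s = np.format_float_positional(x, precision=10, unique=True, trim="0")
    if s.endswith("."):
        s += "0"
    return s


def read_distance_matrix(path: str | Path, format: str = "phylip") -> tuple[np.ndarray, list[str]]:
    """Minimal reader for the two formats written above (round-trip checks)."""
    text = Path(path).read_text()
    if format == "phylip":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        n = int(lines[0])
        labels, rows = [], []
        for ln in lines[1 : n + 1]:
            parts = ln.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return np.array(rows), labels
    if format == "nexus":
        m = re.search(r"MATRIX(.*?);", text, re.S | re.I)
        if m is None:
            raise ValueError("no MATRIX block")
        labels, rows = [], []
        for ln in m.group(1).splitlines():
            parts = ln.split()
            if not parts:
                continue
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return np.array(rows), labels
    raise ValueError(f"unknown format {format!r}")
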