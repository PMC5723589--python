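"""Gene diversity and rarefaction allelic richness.

Implements the three standard within-population diversity measures used for
microsatellite surveys of structured tree species:

* unbiased expected heterozygosity  Ĥ = n (1 − Σ p̂ᵢ²) / (n − 1);
* allelic richness by hypergeometric rarefaction to ``g`` gene copies,
  A_g = Σᵢ [1 − C(N−Nᵢ, g) / C(N, g)];
* private allelic richness (Kalinowski): the expected number of alleles seen
  in a rarefied sample from one population but in none of the others,
  P_g(j) = Σᵢ Q_g(i,j) Πₖ≠ⱼ (1 − Q_g(i,k)),  Q_g(i,j) = 1 − C(Nⱼ−Nᵢⱼ, g)/C(Nⱼ, g).

Rarefaction puts populations of unequal sample size on a common footing:
A_g is the expected number of distinct alleles in a random draw of exactly
``g`` copies, so it is comparable across populations regardless of n.
Differences among taxa are screened with the Kruskal–Wallis rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes_io import AlleleCounts, GenotypeDataset, tally_all

logger = logging.getLogger(__name__)


def expected_heterozygosity(counts: AlleleCounts) -> float:
    """Unbiased gene diversity for one locus/population table.

    Requires n >= 2 gene copies; raises ``ValueError`` otherwise (callers
    drop such loci from population means).
    """
    n = counts.n
    if n < 2:
        raise ValueError(f"locus {counts.locus}/{counts.population}: n={n} < 2")
    p2 = sum((c / n) ** 2 for c in counts.counts.values())
    return n * (1.0 - p2) / (n - 1.0)


def allelic_richness(counts: AlleleCounts, g: int) -> float:
    """Expected number of distinct alleles in a random subsample of g copies.

    Exact hypergeometric rarefaction; equals the observed allele count at
    ``g = N``.  Raises ``ValueError`` when ``N < g`` (callers exclude and
    report such populations).
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    N = counts.n
    if N < g:
        raise ValueError(
            f"locus {counts.locus}/{counts.population}: N={N} < g={g}, excluded"
        )
    denom = comb(N, g)
    total = Fraction(0)
    for Ni in counts.counts.values():
        total += 1 - Fraction(comb(N - Ni, g), denom)
    return float(total)


def _q_present(Nj: int, Nij: int, g: int) -> Fraction:
    """Probability that allele i appears in a g-copy rarefied sample from j."""
    return 1 - Fraction(comb(Nj - Nij, g), comb(Nj, g))


def private_allelic_richness(counts_by_pop: list[AlleleCounts], g: int) -> dict[str, float]:
    """Kalinowski's rarefied private allelic richness at one locus.

    Populations with fewer than ``g`` copies are excluded from the comparison
    set with a logged notice; the returned dict covers the included ones.
    """
    included = []
    for c in counts_by_pop:
        if c.n >= g:
            included.append(c)
        else:
            logger.info(
                "locus %s: population %s excluded from P_%d (N=%d < g)",
                c.locus, c.population, g, c.n,
            )
    if not included:
        return {}
    alleles = sorted({a for c in included for a in c.counts})
    q = {
        (a, c.population): _q_present(c.n, c.counts.get(a, 0), g)
        for a in alleles
        for c in included
    }
    out: dict[str, float] = {}
    for c in included:
        total = Fraction(0)
        for a in alleles:
            term = q[(a, c.population)]
            for other in included:
                if other.population != c.population:
                    term *= 1 - q[(a, other.population)]
            total += term
        out[c.population] = float(total)
    return out


@dataclass
class DiversitySummary:
    """Per-unit (population or taxon) diversity summary averaged over loci."""

    unit: str
    n_mean: float
    he: float
    richness: float | None
    private_richness: float | None
    n_loci: int


def _pooled_by_taxon(dataset: GenotypeDataset) -> dict[tuple[str, str], AlleleCounts]:
    tallies = tally_all(dataset)
    pooled: dict[tuple[str, str], AlleleCounts] = {}
    for (locus, pop), c in tallies.items():
        taxon = dataset.groups.get(pop, pop)
        key = (locus, taxon)
        if key in pooled:
            merged = dict(pooled[key].counts)
            for a, cnt in c.counts.items():
                merged[a] = merged.get(a, 0) + cnt
            pooled[key] = AlleleCounts(locus, taxon, merged)
        else:
            pooled[key] = AlleleCounts(locus, taxon, dict(c.counts))
    return pooled


def _summaries(
    units: list[str],
    tables: dict[tuple[str, str], AlleleCounts],
    loci: list[str],
    g: int,
    sizes: dict[str, float],
) -> pd.DataFrame:
    """Shared summary engine for population- and taxon-level tables."""
    private_by_locus = [
        private_allelic_richness([tables[(loc, u)] for u in units], g) for loc in loci
    ]
    rows = []
    for unit in units:
        he_vals, rich_vals = [], []
        usable = 0
        rarefiable = all(tables[(loc, unit)].n >= g for loc in loci)
        for loc in loci:
            c = tables[(loc, unit)]
            if c.n >= 2:
                he_vals.append(expected_heterozygosity(c))
                usable += 1
            if rarefiable:
                rich_vals.append(allelic_richness(c, g))
        priv_total = sum(priv.get(unit, 0.0) for priv in private_by_locus)
        rows.append(
            DiversitySummary(
                unit=unit,
                n_mean=sizes[unit],
                he=float(np.mean(he_vals)) if he_vals else np.nan,
                richness=float(np.mean(rich_vals)) if rarefiable else None,
                private_richness=priv_total / len(loci) if rarefiable else None,
                n_loci=usable,
            )
        )
    return pd.DataFrame(
        [(r.unit, r.n_mean, r.he, r.richness, r.private_richness, r.n_loci) for r in rows],
        columns=["unit", "n_mean", "He", f"A_{g}", f"P_{g}", "n_loci"],
    )


def population_diversity(dataset: GenotypeDataset, g: int = 22) -> pd.DataFrame:
    """Per-population He, A_g and P_g (rarefaction to ``g`` gene copies)."""
    tallies = tally_all(dataset)
    pops = dataset.population_ids()
    sizes = {p: float(len(dataset.population_indices(p))) for p in pops}
    return _summaries(pops, tallies, dataset.loci, g, sizes)


def taxon_diversity(dataset: GenotypeDataset, g: int = 140) -> pd.DataFrame:
    """Taxon-level diversity on copies pooled across each taxon's populations."""
    pooled = _pooled_by_taxon(dataset)
    taxa = list(dict.fromkeys(dataset.groups.get(p, p) for p in dataset.population_ids()))
    sizes: dict[str, float] = {}
    for t in taxa:
        inds = [
            i for i, ind in enumerate(dataset.individuals)
            if dataset.groups.get(dataset.populations[ind], dataset.populations[ind]) == t
        ]
        sizes[t] = float(len(inds))
    return _summaries(taxa, pooled, dataset.loci, g, sizes)


def kruskal_wallis_by_taxon(values: dict[str, float], taxon_of: dict[str, str]) -> tuple[float, float]:
    """Kruskal–Wallis rank test of a per-population statistic across taxa.

    Returns ``(H, p)`` with tie correction and the chi-square approximation
    (k − 1 df).  All-identical values give ``H = 0, p = 1``.
    """
    groups: dict[str, list[float]] = {}
    for pop, v in values.items():
        groups.setdefault(taxon_of[pop], []).append(v)
    samples = [np.asarray(v, dtype=float) for v in groups.values() if len(v) > 0]
    if len(samples) < 2:
        raise ValueError("need >= 2 taxa with observations")
    flat = np.concatenate(samples)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)
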