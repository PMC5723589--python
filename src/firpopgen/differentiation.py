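"""F-statistics and hierarchical AMOVA for codominant diploid data.

Two complementary views of population differentiation:

* :func:`wc_theta` — the Weir & Cockerham (1984) moment estimator of F_ST.
  Per allele and per locus the among-population (a), among-individual (b)
  and within-individual (c) variance components are estimated from sample
  allele frequencies and observed heterozygote frequencies, with
  sample-size weighting; the multilocus estimate is the ratio of sums
  θ = Σa / Σ(a+b+c).  Negative estimates are legitimate (sampling noise
  around zero) and are retained.

* :func:`amova` — analysis of molecular variance on gene copies with the
  allele-identity distance (F_ST-like, not allele-size based), nested as
  groups / populations within groups / copies within populations, with
  three permutation schemes for F_ST, F_SC and F_CT.

:func:`linearize_fst` provides Slatkin's F/(1−F) transform used as the
genetic distance for isolation-by-distance and barrier analysis.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes_io import GenotypeDataset, MISSING

logger = logging.getLogger(__name__)


@dataclass
class FstResult:
    loci: list[str]
    a: np.ndarray          # per-locus among-population component
    b: np.ndarray          # per-locus among-individual component
    c: np.ndarray          # per-locus within-individual component
    theta: float           # multilocus ratio-of-sums; NaN when undefined

    @property
    def per_locus_theta(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.a / (self.a + self.b + self.c)


def _locus_components(calls: np.ndarray, pop_of: np.ndarray, n_pops: int) -> tuple[float, float, float]:
    """W&C (1984) a, b, c for one locus, summed over alleles.

    ``calls``: (n_ind, 2) allele array with 0 = missing; ``pop_of``: population
    index per individual.  Populations with < 1 complete genotype drop out.
    """
    complete = calls[:, 0] != MISSING
    calls = calls[complete]
    pop_of = pop_of[complete]
    # per-population sample sizes (diploid individuals with data)
    n_i = np.bincount(pop_of, minlength=n_pops).astype(float)
    keep = n_i > 0
    if keep.sum() < 2:
        return 0.0, 0.0, 0.0
    remap = -np.ones(n_pops, dtype=np.intp)
    remap[keep] = np.arange(keep.sum())
    pop_of = remap[pop_of]
    n_i = n_i[keep]
    r = len(n_i)

    alleles = np.unique(calls)
    n_bar = n_i.mean()
    n_total = n_i.sum()
    n_c = (n_total - (n_i**2).sum() / n_total) / (r - 1)

    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        is_al = calls == al
        cnt = np.bincount(pop_of, weights=is_al.sum(axis=1), minlength=r)
        p_i = cnt / (2 * n_i)
        het = is_al.sum(axis=1) == 1     # heterozygous for this allele
        h_i = np.bincount(pop_of, weights=het.astype(float), minlength=r) / n_i
        p_bar = (n_i * p_i).sum() / n_total
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / n_total
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def wc_theta(dataset: GenotypeDataset, populations: list[str] | None = None) -> FstResult:
    """Multilocus Weir–Cockerham θ over the given (default: all) populations.

    θ is reported as NaN (undefined, not 0) when there is no allelic
    variation at any locus.
    """
    if populations is not None:
        dataset = dataset.subset_populations(populations)
    pops = dataset.population_ids()
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    pop_of = dataset.pop_index_array()
    a = np.zeros(dataset.n_loci)
    b = np.zeros(dataset.n_loci)
    c = np.zeros(dataset.n_loci)
    for j in range(dataset.n_loci):
        a[j], b[j], c[j] = _locus_components(dataset.calls[:, j, :], pop_of, len(pops))
    denom = (a + b + c).sum()
    theta = a.sum() / denom if denom != 0 else np.nan
    if denom == 0:
        logger.warning("no allelic variation at any locus: theta undefined")
    return FstResult(list(dataset.loci), a, b, c, float(theta))


def pairwise_fst(dataset: GenotypeDataset) -> pd.DataFrame:
    """Symmetric pairwise θ matrix (zero diagonal) over all populations."""
    pops = dataset.population_ids()
    m = np.zeros((len(pops), len(pops)))
    for i, j in itertools.combinations(range(len(pops)), 2):
        res = wc_theta(dataset, [pops[i], pops[j]])
        m[i, j] = m[j, i] = res.theta
    return pd.DataFrame(m, index=pops, columns=pops)


def linearize_fst(f: float | np.ndarray, warn: bool = True) -> np.ndarray | float:
    """Slatkin's linearized F_ST, F/(1−F), truncating negative F at 0.

    Truncation is flagged with a log message; F >= 1 raises.
    """
    arr = np.asarray(f, dtype=float)
    if np.any(arr >= 1):
        raise ValueError("F >= 1 cannot be linearized")
    neg = arr < 0
    if neg.any() and warn:
        logger.info("truncated %d negative F_ST values at 0 before linearizing", int(neg.sum()))
    arr = np.where(neg, 0.0, arr)
    out = arr / (1.0 - arr)
    return float(out) if np.isscalar(f) or out.ndim == 0 else out


def linearized_fst_matrix(dataset: GenotypeDataset) -> pd.DataFrame:
    m = pairwise_fst(dataset)
    return pd.DataFrame(
        np.asarray(linearize_fst(m.to_numpy(), warn=False)), index=m.index, columns=m.columns
    )


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    df: dict[str, int]
    variance: dict[str, float]            # sigma2 among-groups / among-pops / within-pops
    percentages: dict[str, float]
    f_ct: float
    f_sc: float
    f_st: float
    p_values: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False


def _ssd_parts(copy_alleles: np.ndarray, pop_of_copy: np.ndarray, group_of_pop: np.ndarray,
               n_pops: int, n_groups: int):
    """Per-locus sums of squared deviations under the allele-identity distance.

    For a set of m copies with allele copy-counts c_a, the SSD among them is
    Σ_{i<j} d_ij / m = (m² − Σ c_a²) / (2m), since d is 0/1 identity.
    Returns (SSD_total, SSD_among_groups, SSD_among_pops_within_groups,
    SSD_within_pops, per-pop copy counts, per-group copy counts).
    """
    n_alleles = copy_alleles.max() + 1

    def ssd_of(counts_sq_sum: float, m: float) -> float:
        return (m * m - counts_sq_sum) / (2.0 * m) if m > 0 else 0.0

    pop_counts = np.zeros((n_pops, n_alleles))
    np.add.at(pop_counts, (pop_of_copy, copy_alleles), 1.0)
    m_pop = pop_counts.sum(axis=1)
    ssd_wp = sum(ssd_of((pop_counts[p] ** 2).sum(), m_pop[p]) for p in range(n_pops))

    grp_counts = np.zeros((n_groups, n_alleles))
    for p in range(n_pops):
        grp_counts[group_of_pop[p]] += pop_counts[p]
    m_grp = grp_counts.sum(axis=1)
    ssd_groups = sum(ssd_of((grp_counts[gi] ** 2).sum(), m_grp[gi]) for gi in range(n_groups))

    tot_counts = grp_counts.sum(axis=0)
    m_tot = tot_counts.sum()
    ssd_tot = ssd_of((tot_counts**2).sum(), m_tot)

    return ssd_tot, ssd_tot - ssd_groups, ssd_groups - ssd_wp, ssd_wp, m_pop, m_grp


def _amova_components(ssd_ag, ssd_ap, ssd_wp, m_pop, m_grp, group_of_pop):
    """Variance components from nested ANOVA expected mean squares."""
    n_pops = len(m_pop)
    n_groups = len(m_grp)
    N = m_pop.sum()
    df_ag = n_groups - 1
    df_ap = n_pops - n_groups
    df_wp = int(N) - n_pops
    if df_wp <= 0 or df_ag <= 0:
        raise ValueError("insufficient degrees of freedom for AMOVA")

    sum_npsq_by_group = np.zeros(n_groups)
    for p in range(n_pops):
        sum_npsq_by_group[group_of_pop[p]] += m_pop[p] ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(m_grp > 0, sum_npsq_by_group / m_grp, 0.0)
    n1 = (N - ratio.sum()) / df_ap if df_ap > 0 else 0.0
    n2 = (ratio.sum() - (m_pop**2).sum() / N) / df_ag
    n3 = (N - (m_grp**2).sum() / N) / df_ag

    ms_wp = ssd_wp / df_wp
    sigma_c = ms_wp
    if df_ap > 0 and n1 > 0:
        sigma_b = (ssd_ap / df_ap - sigma_c) / n1
    else:
        sigma_b = 0.0
    sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    return (df_ag, df_ap, df_wp), (sigma_a, sigma_b, sigma_c)


def _amova_stats(calls: np.ndarray, pop_of: np.ndarray, group_of_pop: np.ndarray,
                 n_pops: int, n_groups: int):
    """Summed-over-loci variance components and F-statistics."""
    n_loci = calls.shape[1]
    sig = np.zeros(3)
    dfs = np.zeros(3)
    for j in range(n_loci):
        col = calls[:, j, :]
        complete = col[:, 0] != MISSING
        copies = col[complete].ravel()
        pops = np.repeat(pop_of[complete], 2)
        # compact allele coding per locus
        _, coded = np.unique(copies, return_inverse=True)
        ssd_tot, ssd_ag, ssd_ap, ssd_wp, m_pop, m_grp = _ssd_parts(
            coded, pops, group_of_pop, n_pops, n_groups
        )
        (df_ag, df_ap, df_wp), (sa, sb, sc) = _amova_components(
            ssd_ag, ssd_ap, ssd_wp, m_pop, m_grp, group_of_pop
        )
        sig += (sa, sb, sc)
        dfs += (df_ag, df_ap, df_wp)
    return sig, dfs


def amova(dataset: GenotypeDataset, grouping: dict[str, str], n_perm: int = 99_999,
          seed: int | None = None) -> AmovaResult:
    """Hierarchical AMOVA (groups / populations / gene copies).

    ``grouping`` maps every population to a group label.  Significance by
    random permutation: individuals among populations anywhere (F_ST),
    individuals among populations within groups (F_SC), whole populations
    among groups (F_CT); p = (#{perm >= observed} + 1) / (n_perm + 1).
    """
    pops = dataset.population_ids()
    if any(p not in grouping for p in pops):
        raise ValueError("grouping must cover all populations")
    groups = list(dict.fromkeys(grouping[p] for p in pops))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    group_of_pop = np.array([groups.index(grouping[p]) for p in pops], dtype=np.intp)
    singles = [g for g in groups if (group_of_pop == groups.index(g)).sum() == 1]
    if singles:
        logger.info("groups with a single population (no F_SC df): %s", singles)
    pop_of = dataset.pop_index_array()
    rng = np.random.default_rng(seed)

    def stats_for(pop_of_v: np.ndarray, group_of_pop_v: np.ndarray):
        sig, dfs = _amova_stats(dataset.calls, pop_of_v, group_of_pop_v, len(pops), len(groups))
        sa, sb, sc = sig
        total = sa + sb + sc
        if total == 0:
            return sig, dfs, (np.nan, np.nan, np.nan)
        f_ct = sa / total
        f_st = (sa + sb) / total
        f_sc = sb / (sb + sc) if (sb + sc) != 0 else np.nan
        return sig, dfs, (f_ct, f_sc, f_st)

    sig, dfs, (f_ct, f_sc, f_st) = stats_for(pop_of, group_of_pop)
    total = sig.sum()
    degenerate = total == 0
    if degenerate:
        logger.warning("no genetic variation: AMOVA percentages reported as 0/0/100")
        pct = {"among_groups": 0.0, "among_pops_within_groups": 0.0, "within_pops": 100.0}
        f_ct = f_sc = f_st = np.nan
    else:
        pct = {
            "among_groups": 100 * sig[0] / total,
            "among_pops_within_groups": 100 * sig[1] / total,
            "within_pops": 100 * sig[2] / total,
        }

    p_values: dict[str, float] = {}
    if n_perm > 0 and not degenerate:
        ge = {"F_ST": 0, "F_SC": 0, "F_CT": 0}
        n_ind = dataset.n_individuals
        group_of_ind = group_of_pop[pop_of]
        for _ in range(n_perm):
            # F_ST: individuals among populations anywhere
            perm = rng.permutation(n_ind)
            _, _, (_, _, f_st_p) = stats_for(pop_of[perm], group_of_pop)
            if f_st_p >= f_st:
                ge["F_ST"] += 1
            # F_SC: individuals among populations within their group
            perm2 = np.arange(n_ind)
            for gi in range(len(groups)):
                members = np.flatnonzero(group_of_ind == gi)
                perm2[members] = members[rng.permutation(len(members))]
            _, _, (_, f_sc_p, _) = stats_for(pop_of[perm2], group_of_pop)
            if not np.isnan(f_sc) and f_sc_p >= f_sc:
                ge["F_SC"] += 1
            # F_CT: whole populations among groups
            gperm = group_of_pop[rng.permutation(len(pops))]
            _, _, (f_ct_p, _, _) = stats_for(pop_of, gperm)
            if f_ct_p >= f_ct:
                ge["F_CT"] += 1
        p_values = {k: (v + 1) / (n_perm + 1) for k, v in ge.items()}

    return AmovaResult(
        df={"among_groups": int(dfs[0]), "among_pops_within_groups": int(dfs[1]),
            "within_pops": int(dfs[2])},
        variance={"among_groups": float(sig[0]), "among_pops_within_groups": float(sig[1]),
                  "within_pops": float(sig[2])},
        percentages={k: float(v) for k, v in pct.items()},
        f_ct=float(f_ct), f_sc=float(f_sc), f_st=float(f_st),
        p_values=p_values, degenerate=degenerate,
    )
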