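"""Approximate Bayesian Computation: summary statistics, rejection,
logistic-regression model choice and local-linear parameter estimation.

The likelihood of a multi-population microsatellite dataset under a
demographic scenario is intractable; ABC replaces it by simulation.  A
reference table holds, for each candidate scenario, parameter draws from the
prior and the summary statistics of data simulated under them.  Inference
then proceeds in the classical rejection + regression style:

* **rejection** keeps the fraction of simulations whose statistics are
  closest (Euclidean after MAD standardization) to the observed vector;
* **model choice** fits a weighted multinomial logistic regression of the
  scenario indicator on the statistics over the retained simulations
  (Epanechnikov kernel weights in distance) and evaluates it at the
  observed vector, with confidence bounds from the asymptotic covariance;
* **parameter estimation** applies Beaumont's local-linear adjustment to
  log-transformed parameters, reporting the posterior mode (Gaussian KDE)
  and 2.5/97.5% quantiles.

Generations convert to calendar time with a generation turnover of
150 ± 50 years by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .differentiation import wc_theta
from .genotypes_io import GenotypeDataset, tally_all
from .coalescent_gsm import ScenarioSet, draw_locus_rates, draw_params, simulate

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def summary_stat_labels(populations: list[str]) -> list[str]:
    """Fixed ordering of the summary-statistic vector for given populations."""
    labels = []
    for p in populations:
        labels += [f"k_{p}", f"he_{p}", f"var_{p}"]
    for i in range(len(populations)):
        for j in range(i + 1, len(populations)):
            a, b = populations[i], populations[j]
            labels += [f"fst_{a}_{b}", f"dmu2_{a}_{b}", f"shared_{a}_{b}"]
    return labels


def summarize(dataset: GenotypeDataset) -> np.ndarray:
    """DIYABC-style summary statistics, in the order of
    :func:`summary_stat_labels`.

    One-sample (per population, averaged over loci): mean allele count,
    mean gene diversity, mean allele-size variance.  Two-sample (per pair):
    Weir–Cockerham θ̂, mean squared difference of mean allele sizes (δμ)²,
    and the mean proportion of shared alleles (|A∩B| / |A∪B|).  Monomorphic
    loci contribute zeros, never missing values.
    """
    pops = dataset.population_ids()
    tallies = tally_all(dataset)
    loci = dataset.loci
    out: list[float] = []
    means: dict[tuple[str, str], float] = {}
    allele_sets: dict[tuple[str, str], frozenset] = {}
    for p in pops:
        ks, hes, vars_ = [], [], []
        for loc in loci:
            c = tallies[(loc, p)]
            n = c.n
            if n == 0:
                ks.append(0.0); hes.append(0.0); vars_.append(0.0)
                means[(loc, p)] = np.nan
                allele_sets[(loc, p)] = frozenset()
                continue
            sizes = np.repeat(list(c.counts.keys()), list(c.counts.values())).astype(float)
            ks.append(float(c.n_alleles))
            hes.append(n * (1 - ((sizes[:, None] == sizes[None, :]).mean())) / max(n - 1, 1))
            vars_.append(float(sizes.var(ddof=0)))
            means[(loc, p)] = float(sizes.mean())
            allele_sets[(loc, p)] = frozenset(c.counts)
        out += [float(np.mean(ks)), float(np.mean(hes)), float(np.mean(vars_))]
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            a, b = pops[i], pops[j]
            theta = wc_theta(dataset, [a, b]).theta
            out.append(0.0 if np.isnan(theta) else float(theta))
            d2, shared = [], []
            for loc in loci:
                ma, mb = means[(loc, a)], means[(loc, b)]
                if np.isfinite(ma) and np.isfinite(mb):
                    d2.append((ma - mb) ** 2)
                sa, sb = allele_sets[(loc, a)], allele_sets[(loc, b)]
                union = sa | sb
                if union:
                    shared.append(len(sa & sb) / len(union))
            out.append(float(np.mean(d2)) if d2 else 0.0)
            out.append(float(np.mean(shared)) if shared else 0.0)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Simulated parameter draws and summary statistics per scenario."""

    scenario: np.ndarray          # scenario name per row
    params: pd.DataFrame          # parameter draws (columns = names)
    stats: np.ndarray             # (n_rows, n_stats)
    stat_labels: list[str]

    @property
    def n_rows(self) -> int:
        return len(self.scenario)


def build_reference_table(scenario_set: ScenarioSet, n_per_scenario: int,
                          n_loci: int = 7, seed: int | None = None,
                          sample_override: dict[str, int] | None = None) -> ReferenceTable:
    """Simulate the ABC reference table for every scenario in the set.

    Each row draws parameters (and per-locus mutation rates, and the GSM
    parameter) from the prior, simulates a dataset and stores its summary
    statistics.  ``sample_override`` replaces per-population diploid sample
    sizes (e.g. to match the observed data or to scale a calibration run).
    """
    rng = np.random.default_rng(seed)
    rows_scen: list[str] = []
    rows_par: list[dict[str, float]] = []
    rows_stats: list[np.ndarray] = []
    labels: list[str] | None = None
    for name in scenario_set.scenario_names:
        draws = draw_params(scenario_set.prior, n_per_scenario,
                            seed=int(rng.integers(1, 2**31)))
        for d in draws:
            mu = draw_locus_rates(scenario_set.prior, n_loci, rng)
            spec = scenario_set.build(name, d)
            if sample_override:
                spec.samples = {p: sample_override.get(p, n)
                                for p, n in spec.samples.items()}
            sim = simulate(spec, n_loci=n_loci, mu=mu, gsm_p=d["gsm_p"],
                           seed=int(rng.integers(1, 2**31)))
            stats = summarize(sim.dataset)
            if labels is None:
                labels = summary_stat_labels(sim.dataset.population_ids())
            rows_scen.append(name)
            rows_par.append(d)
            rows_stats.append(stats)
    return ReferenceTable(
        scenario=np.array(rows_scen),
        params=pd.DataFrame(rows_par),
        stats=np.vstack(rows_stats),
        stat_labels=labels or [],
    )


def reject(reference: ReferenceTable, observed: np.ndarray,
           tolerance: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Rejection step: retain the ``tolerance`` fraction of closest rows.

    Distances are Euclidean on statistics standardized by their median
    absolute deviation over the whole table; zero-MAD statistics are dropped
    from the distance with a warning.  Returns (retained row indices sorted
    by distance, their distances).
    """
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    stats = reference.stats
    mad = np.median(np.abs(stats - np.median(stats, axis=0)), axis=0)
    usable = mad > 0
    if not usable.all():
        logger.warning("dropping %d zero-MAD statistics from the distance",
                       int((~usable).sum()))
    if not usable.any():
        raise ValueError("all summary statistics are constant over the table")
    z = (stats[:, usable] - observed[usable]) / mad[usable]
    d = np.sqrt((z**2).sum(axis=1))
    n_keep = max(1, round(tolerance * reference.n_rows))
    order = np.argsort(d, kind="stable")[:n_keep]
    return order, d[order]


# ---------------------------------------------------------------------------
# Model choice
# ---------------------------------------------------------------------------

def _epanechnikov(d: np.ndarray) -> np.ndarray:
    dmax = d.max()
    if dmax == 0:
        return np.ones_like(d)
    w = 1.0 - (d / (dmax * (1 + 1e-12))) ** 2
    return np.clip(w, 1e-12, None)


def _fit_multinomial(x: np.ndarray, y: np.ndarray, w: np.ndarray, n_classes: int,
                     ridge: float = 1e-6, max_iter: int = 100):
    """Weighted multinomial logistic regression by Newton's method.

    ``x`` includes the intercept column.  Class 0 is the baseline; returns
    the stacked coefficient vector beta ((n_classes−1)·d,) and the inverse
    of the penalized Fisher information (asymptotic covariance).
    """
    n, d = x.shape
    k = n_classes - 1
    beta = np.zeros(k * d)
    indicator = np.zeros((n, k))
    for c in range(1, n_classes):
        indicator[:, c - 1] = y == c
    for _ in range(max_iter):
        eta = x @ beta.reshape(k, d).T                     # (n, k)
        m = np.maximum(eta.max(axis=1, initial=0.0), 0.0)
        denom = np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1)
        p = np.exp(eta - m[:, None]) / denom[:, None]      # (n, k)
        grad = np.empty(k * d)
        for c in range(k):
            grad[c * d:(c + 1) * d] = x.T @ (w * (indicator[:, c] - p[:, c]))
        grad -= ridge * beta
        hess = np.empty((k * d, k * d))
        for c1 in range(k):
            for c2 in range(k):
                wcc = w * (p[:, c1] * ((c1 == c2) - p[:, c2]))
                hess[c1 * d:(c1 + 1) * d, c2 * d:(c2 + 1) * d] = x.T @ (x * wcc[:, None])
        hess += ridge * np.eye(k * d)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta_new = beta + step
        if np.abs(step).max() < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    cov = np.linalg.pinv(hess)
    return beta, cov


@dataclass
class ModelChoiceResult:
    probabilities: dict[str, float]
    ci: dict[str, tuple[float, float]]
    n_retained: int
    method: str = "logistic"


def model_choice(reference: ReferenceTable, observed: np.ndarray,
                 tolerance: float = 0.01) -> ModelChoiceResult:
    """Posterior scenario probabilities at the observed statistics.

    Rejection (jointly across scenarios), then Epanechnikov-weighted
    multinomial logistic regression of the scenario indicator on the
    standardized statistics, evaluated at the observed vector; the 95% CI
    comes from the delta method on the asymptotic covariance.  Scenarios
    absent from the retained set get probability 0 (with a warning).  If the
    retained rows contain a single scenario, its probability is 1.
    """
    idx, dist = reject(reference, observed, tolerance)
    scen_names = list(dict.fromkeys(reference.scenario))
    retained_scen = reference.scenario[idx]
    present = [s for s in scen_names if (retained_scen == s).any()]
    missing = [s for s in scen_names if s not in present]
    if missing:
        logger.warning("scenarios absent from retained set: %s (probability floored at 0)",
                       missing)
    if len(present) < 2:
        probs = {s: (1.0 if s in present else 0.0) for s in scen_names}
        return ModelChoiceResult(probs, {s: (p, p) for s, p in probs.items()},
                                 len(idx), method="degenerate")

    stats = reference.stats[idx]
    mu = stats.mean(axis=0)
    sd = stats.std(axis=0)
    usable = sd > 0
    z = (stats[:, usable] - mu[usable]) / sd[usable]
    z_obs = (observed[usable] - mu[usable]) / sd[usable]
    x = np.column_stack([np.ones(len(z)), z])
    x_obs = np.concatenate([[1.0], z_obs])
    y = np.array([present.index(s) for s in retained_scen])
    w = _epanechnikov(dist)

    beta, cov = _fit_multinomial(x, y, w, len(present))
    d = x.shape[1]
    k = len(present) - 1
    eta = np.array([x_obs @ beta[c * d:(c + 1) * d] for c in range(k)])
    m = max(eta.max(initial=0.0), 0.0)
    denom = np.exp(-m) + np.exp(eta - m).sum()
    p_vec = np.concatenate([[np.exp(-m) / denom], np.exp(eta - m) / denom])

    # delta method: dp/dbeta for each class probability
    ci: dict[str, tuple[float, float]] = {}
    probs: dict[str, float] = {}
    for ci_idx, s in enumerate(present):
        grad = np.zeros(k * d)
        for c in range(k):
            indic = 1.0 if (ci_idx == c + 1) else 0.0
            grad[c * d:(c + 1) * d] = p_vec[ci_idx] * (indic - p_vec[c + 1]) * x_obs
        var = float(grad @ cov @ grad)
        half = 1.959964 * np.sqrt(max(var, 0.0))
        probs[s] = float(p_vec[ci_idx])
        ci[s] = (max(0.0, p_vec[ci_idx] - half), min(1.0, p_vec[ci_idx] + half))
    for s in missing:
        probs[s] = 0.0
        ci[s] = (0.0, 0.0)
    total = sum(probs.values())
    probs = {s: p / total for s, p in probs.items()}
    return ModelChoiceResult(probs, ci, len(idx))


# ---------------------------------------------------------------------------
# Parameter estimation
# ---------------------------------------------------------------------------

@dataclass
class ParameterEstimate:
    mode: float
    q025: float
    q975: float


@dataclass
class PosteriorSummary:
    scenario: str
    estimates: dict[str, ParameterEstimate]
    n_retained: int
    adjusted: bool = True


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v = values[order]
    cw = np.cumsum(weights[order])
    cw /= cw[-1]
    return float(np.interp(q, cw, v))


def estimate_params(reference: ReferenceTable, observed: np.ndarray, scenario: str,
                    tolerance: float = 0.01,
                    log_params: bool = True) -> PosteriorSummary:
    """Beaumont local-linear posterior for the parameters of one scenario.

    Retained rows of the given scenario are regression-adjusted:
    log-parameters are regressed (weighted least squares, Epanechnikov
    weights) on the standardized statistics, and the residuals are
    translated to the observed vector.  The mode is a weighted Gaussian KDE
    maximum; the 95% interval the weighted 2.5/97.5% quantiles.  A singular
    design falls back to the unadjusted rejection posterior (flagged).
    """
    idx, dist = reject(reference, observed, tolerance)
    mask = reference.scenario[idx] == scenario
    idx, dist = idx[mask], dist[mask]
    if len(idx) < 100:
        raise ValueError(f"only {len(idx)} retained rows for scenario {scenario!r}; "
                         "increase the table size or the tolerance")
    par_cols = [c for c in reference.params.columns
                if reference.params[c].iloc[idx].notna().all()]
    stats = reference.stats[idx]
    mu = stats.mean(axis=0)
    sd = stats.std(axis=0)
    usable = sd > 0
    z = (stats[:, usable] - mu[usable]) / sd[usable]
    z_obs = (observed[usable] - mu[usable]) / sd[usable]
    x = np.column_stack([np.ones(len(z)), z])
    x_obs = np.concatenate([[1.0], z_obs])
    w = _epanechnikov(dist)

    estimates: dict[str, ParameterEstimate] = {}
    adjusted_flag = True
    for name in par_cols:
        vals = reference.params[name].to_numpy()[idx].astype(float)
        transform = log_params and np.all(vals > 0)
        tv = np.log(vals) if transform else vals
        try:
            wx = x * w[:, None]
            coef, *_ = np.linalg.lstsq(wx.T @ x, wx.T @ tv, rcond=None)
            fitted = x @ coef
            adj = float(x_obs @ coef) + (tv - fitted)
        except np.linalg.LinAlgError:
            logger.warning("singular regression design for %s: rejection posterior", name)
            adj = tv
            adjusted_flag = False
        back = np.exp(adj) if transform else adj
        if np.ptp(back) == 0:
            mode = float(back[0])
        else:
            kde = gaussian_kde(back, weights=w)
            grid = np.linspace(back.min(), back.max(), 512)
            mode = float(grid[np.argmax(kde(grid))])
        estimates[name] = ParameterEstimate(
            mode=mode,
            q025=_weighted_quantile(back, w, 0.025),
            q975=_weighted_quantile(back, w, 0.975),
        )
    return PosteriorSummary(scenario, estimates, len(idx), adjusted=adjusted_flag)


# ---------------------------------------------------------------------------
# Calendar conversion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalendarTime:
    """A generation count converted to calendar years with its ± term."""

    years: float
    pm_years: float

    @property
    def unit(self) -> str:
        return "My" if self.years >= 1e6 else "ky"

    def _scaled(self, v: float) -> float:
        return v / (1e6 if self.unit == "My" else 1e3)

    @property
    def value(self) -> float:
        return _round_sig(self._scaled(self.years), 3)

    @property
    def plus_minus(self) -> float:
        return _round_sig(self._scaled(self.pm_years), 3)

    def __str__(self) -> str:
        def fmt(v: float) -> str:
            return f"{v:g}"
        return f"{fmt(self.value)} ± {fmt(self.plus_minus)} {self.unit}"


def _round_sig(v: float, sig: int) -> float:
    """Round to ``sig`` significant figures, half away from zero."""
    if v == 0:
        return 0.0
    from math import floor, log10
    exp = floor(log10(abs(v)))
    quant = Decimal(1).scaleb(exp - sig + 1)
    return float(Decimal(repr(v)).quantize(quant, rounding=ROUND_HALF_UP))


def to_calendar(t_generations: float, g_mean: float = 150.0, g_sd: float = 50.0) -> CalendarTime:
    """Convert generations to calendar years (default 150 ± 50 years each).

    The ± term scales the generation-time uncertainty: t·g_sd years.
    Values display in ky (<1 My) or My, rounded to 3 significant figures
    half away from zero.
    """
    if t_generations < 0:
        raise ValueError("generation count must be >= 0")
    return CalendarTime(t_generations * g_mean, t_generations * g_sd)
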