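"""Coalescent simulation of microsatellite genotypes under demographic scenarios.

A :class:`ScenarioSpec` describes a rooted demographic history over named
populations — divergences (a population merges into its ancestor, backward
in time), admixtures (looking backward, each lineage of a hybrid population
goes to one parent with probability ``r``, else the other) and stepwise Ne
changes.  Ancestry is simulated per locus with msprime (unlinked loci,
diploid samples); mutations follow the Generalized Stepwise Mutation model
(GSM): geometric step sizes with parameter P (P → 0 is the strict SMM),
applied on a bounded range of 40 contiguous allele states with reflecting
boundaries and the root allele at the range midpoint.

The same engine doubles as the synthetic-data generator: see
:func:`study_scenario` / :func:`study_dataset` for a dataset that emulates
the structure of a multi-taxon fir microsatellite survey (8 taxa,
hierarchical divergence, ~30 diploids per population, 8 loci, mean mutation
rate 2×10⁻⁴ per generation), with synthetic coordinates for the spatial
analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import msprime
import numpy as np

from .genotypes_io import GenotypeDataset, PopulationMeta

N_STATES = 40          # bounded allele range (contiguous states)
ALLELE_OFFSET = 100    # reported fragment size of state 0, in bp
ROOT_STATE = N_STATES // 2


# ---------------------------------------------------------------------------
# Scenario specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DivergenceEvent:
    time: float           # generations before present
    derived: str          # merges (backward) into ...
    ancestor: str


@dataclass(frozen=True)
class AdmixtureEvent:
    time: float
    derived: str          # hybrid population created at `time` (backward: dissolved)
    parent1: str
    parent2: str
    prob: float           # lineage goes to parent1 with this probability

    def __post_init__(self) -> None:
        if not 0 < self.prob < 1:
            raise ValueError("admixture rate must be in (0, 1)")


@dataclass(frozen=True)
class NeChangeEvent:
    time: float
    population: str
    ne: float


@dataclass
class ScenarioSpec:
    """Demographic scenario: sampled populations, sizes and ordered events."""

    name: str
    samples: dict[str, int]               # population -> diploid sample size
    ne: dict[str, float]                  # population -> (initial) diploid Ne
    events: list = field(default_factory=list)

    def validate(self) -> None:
        if any(v <= 0 for v in self.ne.values()):
            raise ValueError("Ne must be positive")
        pops = set(self.ne)
        if not set(self.samples) <= pops:
            raise ValueError("sampled populations must have an Ne")
        # every sampled population must end up in a single root lineage
        alive = set(pops)
        merged_into: dict[str, str] = {}
        last_time: dict[str, float] = {p: 0.0 for p in pops}
        for ev in sorted(self.events, key=lambda e: e.time):
            if isinstance(ev, DivergenceEvent):
                for p in (ev.derived, ev.ancestor):
                    if p not in pops:
                        raise ValueError(f"unknown population {p!r}")
                if ev.derived not in alive:
                    raise ValueError(f"{ev.derived!r} already merged before t={ev.time}")
                if ev.ancestor not in alive:
                    raise ValueError(
                        f"{ev.ancestor!r} already merged: lineages from {ev.derived!r} "
                        f"would be stranded at t={ev.time}"
                    )
                if ev.time <= last_time[ev.derived]:
                    raise ValueError("event times must be strictly ordered per lineage")
                alive.discard(ev.derived)
                merged_into[ev.derived] = ev.ancestor
                last_time[ev.ancestor] = max(last_time[ev.ancestor], ev.time)
            elif isinstance(ev, AdmixtureEvent):
                for p in (ev.derived, ev.parent1, ev.parent2):
                    if p not in pops:
                        raise ValueError(f"unknown population {p!r}")
                if ev.derived not in alive:
                    raise ValueError(f"{ev.derived!r} already dissolved")
                if ev.parent1 not in alive or ev.parent2 not in alive:
                    raise ValueError(f"admixture parents of {ev.derived!r} must be alive")
                alive.discard(ev.derived)
                for par in (ev.parent1, ev.parent2):
                    last_time[par] = max(last_time[par], ev.time)
            elif isinstance(ev, NeChangeEvent):
                if ev.population not in pops:
                    raise ValueError(f"unknown population {ev.population!r}")
                if ev.ne <= 0:
                    raise ValueError("Ne must be positive")
            else:
                raise TypeError(f"unknown event {ev!r}")
        if len(alive) != 1:
            raise ValueError(f"scenario must coalesce into one root, got {sorted(alive)}")

    def to_demography(self) -> msprime.Demography:
        self.validate()
        dem = msprime.Demography()
        for pop, ne in self.ne.items():
            dem.add_population(name=pop, initial_size=ne)
        for ev in sorted(self.events, key=lambda e: e.time):
            if isinstance(ev, DivergenceEvent):
                dem.add_mass_migration(time=ev.time, source=ev.derived,
                                       dest=ev.ancestor, proportion=1.0)
            elif isinstance(ev, AdmixtureEvent):
                dem.add_mass_migration(time=ev.time, source=ev.derived,
                                       dest=ev.parent1, proportion=ev.prob)
                dem.add_mass_migration(time=ev.time, source=ev.derived,
                                       dest=ev.parent2, proportion=1.0)
            elif isinstance(ev, NeChangeEvent):
                dem.add_population_parameters_change(
                    time=ev.time, population=ev.population, initial_size=ev.ne
                )
        dem.sort_events()
        return dem

    def n_events(self, kind) -> int:
        return sum(isinstance(ev, kind) for ev in self.events)

    def to_dict(self) -> dict:
        events = []
        for ev in self.events:
            if isinstance(ev, DivergenceEvent):
                events.append({"kind": "divergence", "time": ev.time,
                               "derived": ev.derived, "ancestor": ev.ancestor})
            elif isinstance(ev, AdmixtureEvent):
                events.append({"kind": "admixture", "time": ev.time,
                               "derived": ev.derived, "parent1": ev.parent1,
                               "parent2": ev.parent2, "prob": ev.prob})
            elif isinstance(ev, NeChangeEvent):
                events.append({"kind": "ne_change", "time": ev.time,
                               "population": ev.population, "ne": ev.ne})
        return {"name": self.name, "samples": dict(self.samples),
                "ne": dict(self.ne), "events": events}

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        events: list = []
        for ev in d.get("events", []):
            kind = ev.get("kind")
            if kind == "divergence":
                events.append(DivergenceEvent(float(ev["time"]), ev["derived"],
                                              ev["ancestor"]))
            elif kind == "admixture":
                events.append(AdmixtureEvent(float(ev["time"]), ev["derived"],
                                             ev["parent1"], ev["parent2"],
                                             float(ev["prob"])))
            elif kind == "ne_change":
                events.append(NeChangeEvent(float(ev["time"]), ev["population"],
                                            float(ev["ne"])))
            else:
                raise ValueError(f"unknown event kind {kind!r}")
        spec = cls(d["name"], {k: int(v) for k, v in d["samples"].items()},
                   {k: float(v) for k, v in d["ne"].items()}, events)
        spec.validate()
        return spec


# ---------------------------------------------------------------------------
# GSM mutation model
# ---------------------------------------------------------------------------

def _reflect(idx: int, n_states: int = N_STATES) -> int:
    period = 2 * (n_states - 1)
    m = idx % period
    return period - m if m > n_states - 1 else m


def gsm_model(p: float, n_states: int = N_STATES, root: int = ROOT_STATE) -> msprime.MatrixMutationModel:
    """msprime matrix mutation model for the bounded, reflected GSM.

    Step sizes are geometric with parameter ``p``: P(s) = (1−p) p^{s−1};
    ``p = 0`` is the strict single-step model.  Steps go up or down with
    equal probability and are folded back into [0, n_states−1] by mirror
    reflection.  The root distribution is a point mass at ``root``.
    """
    if not 0 <= p < 1:
        raise ValueError("GSM parameter must be in [0, 1)")
    max_step = 1 if p == 0 else max(1, math.ceil(math.log(1e-12) / math.log(p)))
    probs = np.array([(1 - p) * p ** (s - 1) for s in range(1, max_step + 1)])
    probs /= probs.sum()
    matrix = np.zeros((n_states, n_states))
    for i in range(n_states):
        for s, pr in enumerate(probs, start=1):
            for sign in (-1, 1):
                j = _reflect(i + sign * s, n_states)
                matrix[i, j] += pr / 2.0
    alleles = [str(i) for i in range(n_states)]
    root_dist = np.zeros(n_states)
    root_dist[root] = 1.0
    return msprime.MatrixMutationModel(alleles, root_dist, matrix)


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Prior:
    dist: str             # "uniform" | "log-uniform" | "normal"
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError("prior bounds must be finite")
        if self.low >= self.high:
            raise ValueError("prior lower bound must be < upper bound")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.dist == "uniform":
            return rng.uniform(self.low, self.high, n)
        if self.dist == "log-uniform":
            return np.exp(rng.uniform(math.log(self.low), math.log(self.high), n))
        if self.dist == "normal":
            mean = (self.low + self.high) / 2
            sd = (self.high - self.low) / 4      # bounds read as mean ± 2 sd
            return rng.normal(mean, sd, n)
        raise ValueError(f"unknown prior distribution {self.dist!r}")


@dataclass
class PriorSpec:
    """Priors for scenario parameters plus the mutation model.

    ``constraints`` lists (smaller, larger) parameter-name pairs enforced by
    rejection (e.g. a later divergence must be older than an earlier one).
    """

    params: dict[str, Prior]
    constraints: list[tuple[str, str]] = field(default_factory=list)
    mu_mean: float = 2e-4
    mu_shape: float = 2.0
    gsm_p: Prior = field(default_factory=lambda: Prior("uniform", 0.1, 0.3))


def draw_params(prior: PriorSpec, n: int, seed: int | None = None) -> list[dict[str, float]]:
    """I.i.d. prior draws honoring ordering constraints via rejection."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[dict[str, float]] = []
    attempts = 0
    while len(out) < n:
        batch = max(n - len(out), 32)
        draws = {k: p.draw(batch, rng) for k, p in prior.params.items()}
        gsm = prior.gsm_p.draw(batch, rng)
        ok = np.ones(batch, dtype=bool)
        for small, large in prior.constraints:
            ok &= draws[small] < draws[large]
        for i in np.flatnonzero(ok):
            d = {k: float(v[i]) for k, v in draws.items()}
            d["gsm_p"] = float(gsm[i])
            out.append(d)
            if len(out) == n:
                break
        attempts += batch
        if attempts > max(1000, n) and len(out) < 0.001 * attempts:
            raise RuntimeError(
                "constraint acceptance below 0.1%; revise the prior bounds"
            )
    return out


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def load_scenario(path) -> ScenarioSpec:
    """Read a scenario from a JSON config file (see ScenarioSpec.to_dict)."""
    import json
    from pathlib import Path

    return ScenarioSpec.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SimulatedDataset:
    dataset: GenotypeDataset
    params: dict[str, float] | None
    seed: int


def simulate(scenario: ScenarioSpec, n_loci: int = 8,
             mu: float | np.ndarray = 2e-4, gsm_p: float = 0.2,
             seed: int | None = None,
             params: dict[str, float] | None = None) -> SimulatedDataset:
    """Simulate a multi-population diploid microsatellite dataset.

    Each locus is an independent coalescent under the scenario's piecewise
    demography; ``mu`` is a per-locus rate (scalar or length ``n_loci``).
    Returns genotypes with allele sizes ``ALLELE_OFFSET + state`` (bp).
    Bit-exact reproducible for identical (scenario, parameters, seed).
    """
    rng = np.random.default_rng(seed)
    mu_arr = np.broadcast_to(np.asarray(mu, dtype=float), (n_loci,))
    if np.any(mu_arr < 0):
        raise ValueError("mutation rate must be >= 0")
    demography = scenario.to_demography()
    model = gsm_model(gsm_p)
    sample_sets = {pop: n for pop, n in scenario.samples.items() if n > 0}

    n_ind = sum(sample_sets.values())
    calls = np.full((n_ind, n_loci, 2), ALLELE_OFFSET + ROOT_STATE, dtype=np.int64)

    anc_seed = int(rng.integers(1, 2**31))
    mut_seeds = rng.integers(1, 2**31, n_loci)
    ind_pop: list[str] = []
    replicates = msprime.sim_ancestry(
        samples=sample_sets, demography=demography, ploidy=2,
        sequence_length=1, discrete_genome=True,
        random_seed=anc_seed, num_replicates=n_loci,
        record_provenance=False,
    )
    for j, ts in enumerate(replicates):
        mts = msprime.sim_mutations(ts, rate=float(mu_arr[j]), model=model,
                                    random_seed=int(mut_seeds[j]),
                                    record_provenance=False)
        if j == 0:
            pop_names = {p.id: p.metadata.get("name", str(p.id)) for p in ts.populations()}
            node_pop = ts.tables.nodes.population[: ts.num_samples]
            node_ind = ts.tables.nodes.individual[: ts.num_samples]
            ind_pop = [""] * n_ind
            for node in range(ts.num_samples):
                ind_pop[node_ind[node]] = pop_names[node_pop[node]]
            node_of_ind = np.full((n_ind, 2), -1, dtype=np.intp)
            fill = np.zeros(n_ind, dtype=np.intp)
            for node in range(ts.num_samples):
                node_of_ind[node_ind[node], fill[node_ind[node]]] = node
                fill[node_ind[node]] += 1
        states = np.full(ts.num_samples, ROOT_STATE, dtype=np.int64)
        for var in mts.variants():
            alleles = np.array([int(a) for a in var.alleles if a is not None])
            states = alleles[var.genotypes]
        calls[:, j, 0] = ALLELE_OFFSET + states[node_of_ind[:, 0]]
        calls[:, j, 1] = ALLELE_OFFSET + states[node_of_ind[:, 1]]

    individuals = [f"{p}_{i}" for i, p in enumerate(ind_pop)]
    dataset = GenotypeDataset(
        individuals=individuals,
        loci=[f"SSR{j+1:02d}" for j in range(n_loci)],
        calls=calls,
        populations=dict(zip(individuals, ind_pop)),
    )
    return SimulatedDataset(dataset, params, seed if seed is not None else -1)


def draw_locus_rates(prior: PriorSpec, n_loci: int, rng: np.random.Generator) -> np.ndarray:
    """Per-locus mutation rates: gamma with fixed mean ``mu_mean``, shape ``mu_shape``."""
    shape = prior.mu_shape
    return rng.gamma(shape, prior.mu_mean / shape, n_loci)


# ---------------------------------------------------------------------------
# Built-in scenario sets
# ---------------------------------------------------------------------------

#: Default priors for the built-in scenario sets: Ne uniform on [100, 1e5],
#: event times uniform on [10, 1e5] generations, GSM P uniform on [0.1, 0.3].
def _default_priors(ne_names: list[str], t_names: list[str],
                    constraints: list[tuple[str, str]]) -> PriorSpec:
    params = {f"ne_{n}": Prior("uniform", 100, 100_000) for n in ne_names}
    params.update({n: Prior("uniform", 10, 100_000) for n in t_names})
    return PriorSpec(params=params, constraints=constraints)


@dataclass
class ScenarioSet:
    """A named set of competing scenarios sharing one prior specification."""

    name: str
    builders: dict[str, callable]         # scenario name -> params dict -> ScenarioSpec
    prior: PriorSpec

    def build(self, scenario: str, params: dict[str, float]) -> ScenarioSpec:
        return self.builders[scenario](params)

    @property
    def scenario_names(self) -> list[str]:
        return list(self.builders)


def _set_olcayana() -> ScenarioSet:
    """Is the ×olcayana group a hybrid of the equi-trojani and bornmuelleriana
    lineages (scenario ``hybrid``) or a recent branch of bornmuelleriana
    (``divergence``)?"""
    samples = {"Ane": 25, "Anb": 25, "Axo": 25}

    def hybrid(p):
        return ScenarioSpec(
            "olcayana_hybrid", dict(samples),
            ne={"Ane": p["ne_Ane"], "Anb": p["ne_Anb"], "Axo": p["ne_Axo"]},
            events=[
                AdmixtureEvent(p["t1"], "Axo", "Ane", "Anb", p.get("r", 0.5)),
                DivergenceEvent(p["t2"], "Ane", "Anb"),
            ],
        )

    def divergence(p):
        return ScenarioSpec(
            "olcayana_divergence", dict(samples),
            ne={"Ane": p["ne_Ane"], "Anb": p["ne_Anb"], "Axo": p["ne_Axo"]},
            events=[
                DivergenceEvent(p["t1"], "Axo", "Anb"),
                DivergenceEvent(p["t2"], "Ane", "Anb"),
            ],
        )

    prior = _default_priors(["Ane", "Anb", "Axo"], ["t1", "t2"], [("t1", "t2")])
    prior.params["r"] = Prior("uniform", 0.05, 0.95)
    return ScenarioSet("olcayana", {"hybrid": hybrid, "divergence": divergence}, prior)


def _set_equi_trojani() -> ScenarioSet:
    """Is equi-trojani a hybrid of alba and bornmuelleriana, or a branch of
    bornmuelleriana with alba splitting off deeper in the past?"""
    samples = {"Aa": 25, "Anb": 25, "Ane": 25}

    def hybrid(p):
        return ScenarioSpec(
            "equitrojani_hybrid", dict(samples),
            ne={"Aa": p["ne_Aa"], "Anb": p["ne_Anb"], "Ane": p["ne_Ane"]},
            events=[
                AdmixtureEvent(p["t1"], "Ane", "Aa", "Anb", p.get("r", 0.5)),
                DivergenceEvent(p["t2"], "Aa", "Anb"),
            ],
        )

    def divergence(p):
        return ScenarioSpec(
            "equitrojani_divergence", dict(samples),
            ne={"Aa": p["ne_Aa"], "Anb": p["ne_Anb"], "Ane": p["ne_Ane"]},
            events=[
                DivergenceEvent(p["t1"], "Ane", "Anb"),
                DivergenceEvent(p["t2"], "Aa", "Anb"),
            ],
        )

    prior = _default_priors(["Aa", "Anb", "Ane"], ["t1", "t2"], [("t1", "t2")])
    prior.params["r"] = Prior("uniform", 0.05, 0.95)
    return ScenarioSet("equi_trojani", {"hybrid": hybrid, "divergence": divergence}, prior)


def _set_nordmanniana() -> ScenarioSet:
    """Two topologies for the whole species complex: the northern regional
    group branching from the southern one either before or after the
    equi-trojani / bornmuelleriana split."""
    samples = {"AnnN": 25, "AnnS": 25, "Anb": 25, "Ane": 25}
    ne_names = ["AnnN", "AnnS", "Anb", "Ane"]

    def topo1(p):
        return ScenarioSpec(
            "nordmanniana_topo1", dict(samples),
            ne={n: p[f"ne_{n}"] for n in ne_names},
            events=[
                DivergenceEvent(p["t1"], "AnnN", "AnnS"),
                DivergenceEvent(p["t2"], "Ane", "Anb"),
                DivergenceEvent(p["t3"], "AnnS", "Anb"),
            ],
        )

    def topo2(p):
        return ScenarioSpec(
            "nordmanniana_topo2", dict(samples),
            ne={n: p[f"ne_{n}"] for n in ne_names},
            events=[
                DivergenceEvent(p["t1"], "Ane", "Anb"),
                DivergenceEvent(p["t2"], "AnnN", "AnnS"),
                DivergenceEvent(p["t3"], "AnnS", "Anb"),
            ],
        )

    prior = _default_priors(ne_names, ["t1", "t2", "t3"],
                            [("t1", "t3"), ("t2", "t3")])
    return ScenarioSet("nordmanniana_sl", {"topo1": topo1, "topo2": topo2}, prior)


def _set_cilicica() -> ScenarioSet:
    """Subspecies split with stable sizes vs the same split plus a historical
    Ne change (bottleneck) in the isaurica lineage."""
    samples = {"Aci": 25, "Acc": 25}

    def stable(p):
        return ScenarioSpec(
            "cilicica_stable", dict(samples),
            ne={"Aci": p["ne_Aci"], "Acc": p["ne_Acc"]},
            events=[DivergenceEvent(p["t1"], "Aci", "Acc")],
        )

    def ne_change(p):
        return ScenarioSpec(
            "cilicica_bottleneck", dict(samples),
            ne={"Aci": p["ne_Aci"], "Acc": p["ne_Acc"]},
            events=[
                NeChangeEvent(p["tb"], "Aci", p["ne_Aci_old"]),
                DivergenceEvent(p["t1"], "Aci", "Acc"),
            ],
        )

    prior = _default_priors(["Aci", "Acc", "Aci_old"], ["t1", "tb"], [("tb", "t1")])
    return ScenarioSet("cilicica_sl", {"stable": stable, "ne_change": ne_change}, prior)


def builtin_scenarios() -> dict[str, ScenarioSet]:
    """The four built-in scenario sets (hybrid-origin questions, species-level
    topology, and the subspecies split with/without an Ne change)."""
    sets = [_set_olcayana(), _set_equi_trojani(), _set_nordmanniana(), _set_cilicica()]
    return {s.name: s for s in sets}


# ---------------------------------------------------------------------------
# Study-structured synthetic data
# ---------------------------------------------------------------------------

#: Synthetic per-taxon defaults: (n populations, diploid Ne, approx lat, lon).
#: Sizes follow the magnitudes a multi-taxon conifer SSR survey reports;
#: coordinates are synthetic stand-ins near each taxon's real region.
_TAXA = {
    "Aa":   (2, 26_000, 42.0, 24.0),
    "Ace":  (3, 30_000, 39.0, 22.0),
    "Ann":  (19, 50_000, 41.0, 42.0),
    "Anb":  (11, 63_000, 41.0, 32.5),
    "Ane":  (3, 27_000, 39.7, 26.9),
    "Axo":  (1, 10_000, 39.8, 27.2),
    "Acc":  (7, 40_000, 37.2, 34.5),
    "Aci":  (6, 16_000, 37.0, 31.5),
}

# taxon-level divergence events, generations before present
_TAXON_TREE = [
    ("Axo", "Anb", 700),
    ("Ane", "Anb", 4_100),
    ("Ann", "Anb", 20_500),
    ("Aa", "Ace", 8_000),
    ("Ace", "Anb", 24_900),
    ("Aci", "Acc", 4_600),
    ("Acc", "Anb", 26_000),
]


def study_scenario(pops_per_taxon: dict[str, int] | None = None,
                   n_diploid: int = 30, t_pop: float = 1500.0) -> tuple[ScenarioSpec, dict[str, PopulationMeta]]:
    """Scenario + synthetic metadata emulating the survey's population structure.

    Populations within each taxon diverge star-like from the taxon lineage at
    ``t_pop`` generations; taxa follow the hierarchical divergence tree with
    times of the order 10³–10⁴ generations.  Returns the scenario and a
    synthetic metadata dict (taxon labels, jittered coordinates).
    """
    counts = {t: _TAXA[t][0] for t in _TAXA} if pops_per_taxon is None else pops_per_taxon
    samples: dict[str, int] = {}
    ne: dict[str, float] = {}
    events: list = []
    meta: dict[str, PopulationMeta] = {}
    coord_rng = np.random.default_rng(777)   # layout only; not data randomness
    merge_time = {t: math.inf for t in _TAXA}
    for derived, _, t in _TAXON_TREE:
        merge_time[derived] = float(t)
    for taxon, (_, taxon_ne, lat0, lon0) in _TAXA.items():
        k = counts.get(taxon, 0)
        if k == 0:
            continue
        ne[taxon] = taxon_ne
        # populations must split off before their taxon lineage itself merges
        t_split = min(t_pop, merge_time[taxon] / 2.0)
        for i in range(1, k + 1):
            pop = f"{taxon}{i}"
            samples[pop] = n_diploid
            ne[pop] = taxon_ne
            events.append(DivergenceEvent(t_split, pop, taxon))
            jit = coord_rng.uniform(-1.2, 1.2, 2)
            meta[pop] = PopulationMeta(pop, taxon, lat0 + jit[0], lon0 + jit[1])
    present = {t for t in _TAXA if counts.get(t, 0) > 0}
    if len(present) > 1 and "Anb" not in present:
        raise ValueError("multi-taxon synthetic scenarios need the root lineage 'Anb'")
    parent = {d: (a, float(t)) for d, a, t in _TAXON_TREE}
    for taxon in present:
        if taxon == "Anb":
            continue
        anc, t = parent[taxon]
        while anc not in present:        # skip over excluded intermediate taxa
            anc, t_up = parent[anc]
            t = max(t, t_up)
        events.append(DivergenceEvent(t, taxon, anc))
    spec = ScenarioSpec("study_structure", samples, ne, events)
    spec.validate()
    return spec, meta


def study_dataset(seed: int, pops_per_taxon: dict[str, int] | None = None,
                  n_diploid: int = 30, n_loci: int = 8, mu: float = 2e-4,
                  gsm_p: float = 0.2, missing_rate: float = 0.02):
    """Synthetic survey-structured dataset with taxon labels and coordinates.

    Returns ``(GenotypeDataset, metadata)``.  ``missing_rate`` is the
    fraction of calls masked as missing (the survey's own rate is unstated;
    2% is a typical SSR failure rate).
    """
    scenario, meta = study_scenario(pops_per_taxon, n_diploid)
    rng = np.random.default_rng(seed)
    sim = simulate(scenario, n_loci=n_loci, mu=mu, gsm_p=gsm_p,
                   seed=int(rng.integers(1, 2**31)))
    ds = sim.dataset
    if missing_rate > 0:
        mask = rng.random((ds.n_individuals, ds.n_loci)) < missing_rate
        ds.calls[mask] = 0
    ds.groups = {m.population: m.taxon for m in meta.values()}
    return ds, meta
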