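"""Shared fixtures and synthetic-data helpers for the test suite."""

from __future__ import annotations

import numpy as np
import msprime
import pytest

from firpopgen.coalescent_gsm import gsm_model
from firpopgen.genotypes_io import GenotypeDataset


def make_dataset(calls, pops, groups=None, loci=None) -> GenotypeDataset:
    """Build a GenotypeDataset from a nested call list and population labels."""
    calls = np.asarray(calls, dtype=np.int64)
    n, n_loci, _ = calls.shape
    individuals = [f"i{k}" for k in range(n)]
    return GenotypeDataset(
        individuals=individuals,
        loci=loci or [f"L{j}" for j in range(n_loci)],
        calls=calls,
        populations={f"i{k}": pops[k] for k in range(n)},
        groups=groups or {},
    )


@pytest.fixture
def toy_dataset() -> GenotypeDataset:
    """Three individuals in one population, one in another, two loci, one
    missing call — small enough for hand-checked tallies."""
    calls = [
        [[150, 150], [200, 202]],
        [[150, 152], [200, 200]],
        [[0, 0], [202, 202]],
        [[152, 152], [200, 204]],
    ]
    return make_dataset(calls, ["P1", "P1", "P1", "P2"], {"P1": "T1", "P2": "T2"})


def stepping_stone_dataset(n_demes: int, n_diploid: int, n_loci: int,
                           migration: float, ne: float, mu: float,
                           seed: int) -> GenotypeDataset:
    """1-D chain of demes with symmetric nearest-neighbour migration.

    Synthetic helper for isolation-by-distance properties; uses msprime's
    migration matrix directly with the package's SMM mutation model.
    """
    dem = msprime.Demography()
    for i in range(n_demes):
        dem.add_population(name=f"D{i}", initial_size=ne)
    for i in range(n_demes - 1):
        dem.set_migration_rate(f"D{i}", f"D{i+1}", migration)
        dem.set_migration_rate(f"D{i+1}", f"D{i}", migration)
    model = gsm_model(0.0)
    rng = np.random.default_rng(seed)
    n_ind = n_demes * n_diploid
    calls = np.zeros((n_ind, n_loci, 2), dtype=np.int64)
    reps = msprime.sim_ancestry(
        samples={f"D{i}": n_diploid for i in range(n_demes)},
        demography=dem, ploidy=2, sequence_length=1, discrete_genome=True,
        random_seed=int(rng.integers(1, 2**31)), num_replicates=n_loci,
        record_provenance=False,
    )
    node_of_ind = None
    ind_pop = None
    for j, ts in enumerate(reps):
        mts = msprime.sim_mutations(ts, rate=mu, model=model,
                                    random_seed=int(rng.integers(1, 2**31)),
                                    record_provenance=False)
        if node_of_ind is None:
            node_ind = ts.tables.nodes.individual[: ts.num_samples]
            node_pop = ts.tables.nodes.population[: ts.num_samples]
            node_of_ind = np.zeros((n_ind, 2), dtype=np.intp)
            fill = np.zeros(n_ind, dtype=np.intp)
            ind_pop = [""] * n_ind
            for node in range(ts.num_samples):
                node_of_ind[node_ind[node], fill[node_ind[node]]] = node
                fill[node_ind[node]] += 1
                ind_pop[node_ind[node]] = f"D{node_pop[node]}"
        states = np.full(ts.num_samples, 20, dtype=np.int64)
        for var in mts.variants():
            alleles = np.array([int(a) for a in var.alleles if a is not None])
            states = alleles[var.genotypes]
        calls[:, j, 0] = 100 + states[node_of_ind[:, 0]]
        calls[:, j, 1] = 100 + states[node_of_ind[:, 1]]
    individuals = [f"{p}_{i}" for i, p in enumerate(ind_pop)]
    return GenotypeDataset(
        individuals=individuals,
        loci=[f"L{j}" for j in range(n_loci)],
        calls=calls,
        populations=dict(zip(individuals, ind_pop)),
    )
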