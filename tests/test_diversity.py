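"""Diversity statistics: closed forms, brute-force rarefaction oracles,
and the Kruskal–Wallis taxon comparison."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from firpopgen.diversity_stats import (
    allelic_richness,
    expected_heterozygosity,
    kruskal_wallis_by_taxon,
    private_allelic_richness,
    population_diversity,
)
from firpopgen.genotypes_io import AlleleCounts
from conftest import make_dataset


def brute_force_richness(counts: dict[int, int], g: int) -> float:
    """Average distinct-allele count over every g-subset of the copy multiset."""
    copies = [a for a, c in counts.items() for _ in range(c)]
    vals = [len(set(sub)) for sub in itertools.combinations(copies, g)]
    return float(np.mean(vals))


class TestHeterozygosity:
    def test_monomorphic_is_zero(self):
        assert expected_heterozygosity(AlleleCounts("L", "P", {150: 12})) == 0.0

    def test_two_even_alleles(self):
        he = expected_heterozygosity(AlleleCounts("L", "P", {150: 5, 152: 5}))
        assert he == pytest.approx(10 / 9 * 0.5)

    def test_unbiased_at_n2(self):
        assert expected_heterozygosity(AlleleCounts("L", "P", {1: 1, 2: 1})) == 1.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            expected_heterozygosity(AlleleCounts("L", "P", {1: 1}))


class TestAllelicRichness:
    def test_worked_example(self):
        a = allelic_richness(AlleleCounts("L", "P", {1: 4, 2: 2}), 2)
        assert a == pytest.approx(23 / 15)

    def test_monomorphic_is_one(self):
        assert allelic_richness(AlleleCounts("L", "P", {1: 9}), 5) == pytest.approx(1.0)

    def test_g_equals_n_gives_observed_count(self):
        c = AlleleCounts("L", "P", {1: 3, 2: 2, 3: 1})
        assert allelic_richness(c, 6) == pytest.approx(3.0)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="excluded"):
            allelic_richness(AlleleCounts("L", "P", {1: 3}), 5)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.integers(1, 5), min_size=1, max_size=4))
    def test_monotone_in_g(self, cnts):
        c = AlleleCounts("L", "P", {i: v for i, v in enumerate(cnts)})
        values = [allelic_richness(c, g) for g in range(1, c.n + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.integers(1, 4), min_size=1, max_size=3), st.integers(1, 8))
    def test_matches_enumeration(self, cnts, g):
        c = AlleleCounts("L", "P", {i: v for i, v in enumerate(cnts)})
        if g > c.n:
            return
        assert allelic_richness(c, g) == pytest.approx(
            brute_force_richness(c.counts, g), abs=1e-12
        )


class TestPrivateRichness:
    def test_fixed_private_allele_contributes_one(self):
        a = AlleleCounts("L", "A", {7: 6})
        b = AlleleCounts("L", "B", {9: 6})
        p = private_allelic_richness([a, b], 6)
        assert p["A"] == pytest.approx(1.0)
        assert p["B"] == pytest.approx(1.0)

    def test_symmetry_for_identical_tables(self):
        a = AlleleCounts("L", "A", {1: 4, 2: 2})
        b = AlleleCounts("L", "B", {1: 4, 2: 2})
        p = private_allelic_richness([a, b], 3)
        assert p["A"] == pytest.approx(p["B"])

    def test_small_population_excluded(self):
        a = AlleleCounts("L", "A", {1: 6})
        b = AlleleCounts("L", "B", {2: 2})
        p = private_allelic_richness([a, b], 4)
        assert "B" not in p and "A" in p

    def test_matches_joint_enumeration(self):
        a = AlleleCounts("L", "A", {1: 3, 2: 2})
        b = AlleleCounts("L", "B", {2: 2, 3: 3})
        g = 3
        copies_a = [x for al, c in a.counts.items() for x in [al] * c]
        copies_b = [x for al, c in b.counts.items() for x in [al] * c]
        tot_a = tot_b = 0.0
        n_pairs = 0
        for sa in itertools.combinations(copies_a, g):
            for sb in itertools.combinations(copies_b, g):
                tot_a += len(set(sa) - set(sb))
                tot_b += len(set(sb) - set(sa))
                n_pairs += 1
        p = private_allelic_richness([a, b], g)
        assert p["A"] == pytest.approx(tot_a / n_pairs, abs=1e-12)
        assert p["B"] == pytest.approx(tot_b / n_pairs, abs=1e-12)


class TestKruskalWallis:
    def test_separated_groups(self):
        values = {"p1": 1, "p2": 2, "p3": 3, "p4": 10, "p5": 11, "p6": 12}
        taxon = {f"p{i}": ("A" if i <= 3 else "B") for i in range(1, 7)}
        h, p = kruskal_wallis_by_taxon(values, taxon)
        # enumeration oracle: H of the observed split is the max over all
        # 20 equal-size relabelings
        vals = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        hs = []
        for combo in itertools.combinations(range(6), 3):
            ga = vals[list(combo)]
            gb = vals[[i for i in range(6) if i not in combo]]
            hs.append(stats.kruskal(ga, gb).statistic)
        assert h == pytest.approx(max(hs))
        assert p < 0.05

    def test_identical_values(self):
        values = {"p1": 2.0, "p2": 2.0, "p3": 2.0, "p4": 2.0}
        taxon = {"p1": "A", "p2": "A", "p3": "B", "p4": "B"}
        h, p = kruskal_wallis_by_taxon(values, taxon)
        assert h == 0.0 and p == 1.0

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(500):
            vals = rng.normal(size=16)
            values = {f"p{i}": vals[i] for i in range(16)}
            taxon = {f"p{i}": ("A" if i < 8 else "B") for i in range(16)}
            ps.append(kruskal_wallis_by_taxon(values, taxon)[1])
        assert 0.42 < np.mean(ps) < 0.58


def test_population_table_shape(toy_dataset):
    table = population_diversity(toy_dataset, g=2)
    assert list(table["unit"]) == ["P1", "P2"]
    assert {"He", "A_2", "P_2"} <= set(table.columns)
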