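"""F-statistics and AMOVA against independent textbook oracles."""

import numpy as np
import pytest

from firpopgen.differentiation import (
    amova,
    linearize_fst,
    pairwise_fst,
    wc_theta,
)
from conftest import make_dataset


def textbook_theta_2pop(genotypes_a, genotypes_b):
    """Independent Weir–Cockerham evaluation for two populations, one locus.

    Direct transcription of the moment-estimator formulas, kept deliberately
    separate from the package implementation.
    """
    pops = [np.asarray(genotypes_a), np.asarray(genotypes_b)]
    r = 2
    n_i = np.array([len(p) for p in pops], dtype=float)
    n_bar = n_i.mean()
    n_total = n_i.sum()
    n_c = (n_total - (n_i**2).sum() / n_total) / (r - 1)
    alleles = sorted({a for p in pops for g in p for a in g})
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p_i = np.array([np.mean([list(g).count(al) / 2 for g in p]) for p in pops])
        h_i = np.array([np.mean([sorted(g).count(al) == 1 for g in p]) for p in pops])
        p_bar = (n_i * p_i).sum() / n_total
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / n_total
        a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2
        a_sum, b_sum, c_sum = a_sum + a, b_sum + b, c_sum + c
    return a_sum / (a_sum + b_sum + c_sum)


class TestWcTheta:
    def test_fixed_difference_is_one(self):
        calls = [[[1, 1]]] * 6 + [[[2, 2]]] * 6
        ds = make_dataset(calls, ["A"] * 6 + ["B"] * 6)
        assert wc_theta(ds).theta == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self):
        block = [[[1, 2]], [[1, 1]], [[2, 2]]]
        ds = make_dataset(block + block, ["A"] * 3 + ["B"] * 3)
        assert wc_theta(ds).theta <= 0

    def test_no_variation_is_nan(self):
        calls = [[[5, 5]]] * 8
        ds = make_dataset(calls, ["A"] * 4 + ["B"] * 4)
        assert np.isnan(wc_theta(ds).theta)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_textbook_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ga = rng.integers(1, 3, (6, 2))
        gb = rng.integers(1, 3, (6, 2))
        ds = make_dataset(
            np.concatenate([ga, gb])[:, None, :], ["A"] * 6 + ["B"] * 6
        )
        res = wc_theta(ds)
        if np.isnan(res.theta):
            return
        assert res.theta == pytest.approx(textbook_theta_2pop(ga, gb), abs=1e-12)

    def test_pairwise_matrix_properties(self, toy_dataset):
        m = pairwise_fst(toy_dataset)
        arr = m.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.all(np.diag(arr) == 0)

    def test_locus_and_individual_order_invariance(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(1, 4, (12, 3, 2))
        pops = ["A"] * 6 + ["B"] * 6
        ds = make_dataset(calls, pops)
        perm_loci = [2, 0, 1]
        shuffled = make_dataset(calls[:, perm_loci, :], pops)
        assert wc_theta(ds).theta == pytest.approx(wc_theta(shuffled).theta)


class TestLinearize:
    def test_values(self):
        assert linearize_fst(0.0) == 0.0
        assert linearize_fst(0.5) == 1.0

    def test_negative_truncated(self):
        assert linearize_fst(-0.0027) == 0.0

    def test_f_at_least_one_rejected(self):
        with pytest.raises(ValueError):
            linearize_fst(1.0)


class TestAmova:
    @staticmethod
    def _toy():
        rng = np.random.default_rng(0)
        calls = rng.integers(1, 4, (12, 1, 2))
        pops = ["P1"] * 3 + ["P2"] * 3 + ["P3"] * 3 + ["P4"] * 3
        grouping = {"P1": "G1", "P2": "G1", "P3": "G2", "P4": "G2"}
        return make_dataset(calls, pops), grouping

    def test_components_match_ss_oracle(self):
        ds, grouping = self._toy()
        res = amova(ds, grouping, n_perm=0)
        # independent oracle: brute-force pairwise 0/1 distances among the 24
        # gene copies, SSD per nesting level, balanced-design coefficients
        copies = ds.calls[:, 0, :].reshape(-1)
        pop_of = np.repeat([0, 0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3], 2)
        grp_of = pop_of // 2
        d = (copies[:, None] != copies[None, :]).astype(float)

        def ssd(idx):
            sub = d[np.ix_(idx, idx)]
            return sub.sum() / (2 * len(idx))

        all_idx = np.arange(24)
        ssd_tot = ssd(all_idx)
        ssd_pop = sum(ssd(np.flatnonzero(pop_of == p)) for p in range(4))
        ssd_grp = sum(ssd(np.flatnonzero(grp_of == g)) for g in range(2))
        ms_wp = ssd_pop / (24 - 4)
        ms_ap = (ssd_grp - ssd_pop) / (4 - 2)
        ms_ag = (ssd_tot - ssd_grp) / (2 - 1)
        # balanced design: 6 copies per population, 12 per group
        sigma_c = ms_wp
        sigma_b = (ms_ap - sigma_c) / 6.0
        sigma_a = (ms_ag - sigma_c - 6.0 * sigma_b) / 12.0
        assert res.variance["within_pops"] == pytest.approx(sigma_c, abs=1e-12)
        assert res.variance["among_pops_within_groups"] == pytest.approx(sigma_b, abs=1e-12)
        assert res.variance["among_groups"] == pytest.approx(sigma_a, abs=1e-12)

    def test_percentages_and_f_identity(self):
        ds, grouping = self._toy()
        res = amova(ds, grouping, n_perm=0)
        assert sum(res.percentages.values()) == pytest.approx(100.0)
        assert (1 - res.f_ct) * (1 - res.f_sc) == pytest.approx(1 - res.f_st, abs=1e-9)

    def test_identical_individuals_degenerate(self):
        calls = [[[3, 3]]] * 8
        ds = make_dataset(calls, ["P1"] * 2 + ["P2"] * 2 + ["P3"] * 2 + ["P4"] * 2)
        grouping = {"P1": "G1", "P2": "G1", "P3": "G2", "P4": "G2"}
        res = amova(ds, grouping, n_perm=0)
        assert res.degenerate
        assert res.percentages["within_pops"] == 100.0

    def test_permutation_p_under_panmixia_not_degenerate(self):
        rng = np.random.default_rng(4)
        rejected = 0
        n_rep = 40
        for i in range(n_rep):
            calls = rng.integers(1, 5, (16, 2, 2))
            pops = ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4 + ["P4"] * 4
            ds = make_dataset(calls, pops)
            grouping = {"P1": "G1", "P2": "G1", "P3": "G2", "P4": "G2"}
            res = amova(ds, grouping, n_perm=99, seed=i)
            if res.p_values["F_CT"] <= 0.05:
                rejected += 1
        assert rejected <= 8  # ~5% expected; allows Monte-Carlo slack
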