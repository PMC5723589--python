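"""ABC components: summary statistics, rejection, model choice, local-linear
adjustment, and the calendar conversion."""

import numpy as np
import pandas as pd
import pytest

from firpopgen.abc_inference import (
    ReferenceTable,
    estimate_params,
    model_choice,
    reject,
    summarize,
    summary_stat_labels,
    to_calendar,
)
from conftest import make_dataset


class TestSummarize:
    @staticmethod
    def _two_identical_pops():
        block = [[[150, 152], [200, 200]], [[150, 150], [200, 202]],
                 [[152, 152], [202, 202]]]
        return make_dataset(block + block, ["A"] * 3 + ["B"] * 3)

    def test_identical_populations(self):
        ds = self._two_identical_pops()
        labels = summary_stat_labels(ds.population_ids())
        v = dict(zip(labels, summarize(ds)))
        assert v["fst_A_B"] <= 0
        assert v["shared_A_B"] == pytest.approx(1.0)

    def test_fixed_difference_delta_mu_squared(self):
        calls = [[[150, 150]]] * 3 + [[[156, 156]]] * 3
        ds = make_dataset(calls, ["A"] * 3 + ["B"] * 3)
        labels = summary_stat_labels(["A", "B"])
        v = dict(zip(labels, summarize(ds)))
        assert v["dmu2_A_B"] == pytest.approx(36.0)
        assert v["shared_A_B"] == 0.0

    def test_individual_order_invariance(self):
        ds = self._two_identical_pops()
        perm = [2, 0, 1, 5, 3, 4]
        ds2 = make_dataset(ds.calls[perm], ["A"] * 3 + ["B"] * 3)
        np.testing.assert_allclose(summarize(ds), summarize(ds2))

    def test_monomorphic_contributes_zero_not_nan(self):
        calls = [[[150, 150]]] * 6
        ds = make_dataset(calls, ["A"] * 3 + ["B"] * 3)
        v = summarize(ds)
        assert np.all(np.isfinite(v))


def _manual_table(n=600, seed=0):
    """Reference table built directly (no simulation): two scenarios whose
    statistics are shifted Gaussians, parameters correlated with stats."""
    rng = np.random.default_rng(seed)
    half = n // 2
    stats_a = rng.normal(0.0, 1.0, (half, 3))
    stats_b = rng.normal(1.5, 1.0, (half, 3))
    stats = np.vstack([stats_a, stats_b])
    params = pd.DataFrame({
        "ne": np.exp(rng.normal(8, 1, n) + 0.5 * stats[:, 0]),
        "t": np.exp(rng.normal(7, 1, n) + 0.5 * stats[:, 1]),
    })
    scen = np.array(["A"] * half + ["B"] * half)
    return ReferenceTable(scen, params, stats, ["s1", "s2", "s3"])


class TestReject:
    def test_identical_row_always_retained(self):
        ref = _manual_table()
        obs = ref.stats[17].copy()
        idx, dist = reject(ref, obs, tolerance=0.01)
        assert 17 in idx
        assert dist[0] == 0.0

    def test_tolerance_one_keeps_all(self):
        ref = _manual_table()
        idx, _ = reject(ref, ref.stats[0], tolerance=1.0)
        assert len(idx) == ref.n_rows

    def test_retained_count(self):
        ref = _manual_table()
        idx, _ = reject(ref, ref.stats[0], tolerance=0.25)
        assert len(idx) == round(0.25 * ref.n_rows)

    def test_bad_tolerance(self):
        ref = _manual_table()
        with pytest.raises(ValueError):
            reject(ref, ref.stats[0], tolerance=0.0)

    def test_tolerance_one_recovers_prior(self):
        # retained set == full table, so retained parameter draws are the prior
        ref = _manual_table()
        idx, _ = reject(ref, ref.stats[5], tolerance=1.0)
        assert sorted(idx.tolist()) == list(range(ref.n_rows))


class TestModelChoice:
    def test_probabilities_sum_to_one(self):
        ref = _manual_table()
        obs = np.array([0.75, 0.75, 0.75])
        mc = model_choice(ref, obs, tolerance=0.5)
        assert sum(mc.probabilities.values()) == pytest.approx(1.0)
        for s, (lo, hi) in mc.ci.items():
            assert lo <= mc.probabilities[s] + 1e-9
            assert mc.probabilities[s] - 1e-9 <= hi or hi == 0.0

    def test_observed_deep_inside_scenario_a(self):
        ref = _manual_table()
        mc = model_choice(ref, np.array([-1.0, -1.0, -1.0]), tolerance=0.5)
        assert mc.probabilities["A"] > 0.8

    def test_midpoint_is_uncertain(self):
        ref = _manual_table(n=2000)
        mc = model_choice(ref, np.array([0.75, 0.75, 0.75]), tolerance=0.8)
        assert 0.2 < mc.probabilities["A"] < 0.8


class TestEstimateParams:
    def test_mode_between_quantiles(self):
        ref = _manual_table()
        post = estimate_params(ref, ref.stats[3], "A", tolerance=0.5)
        for est in post.estimates.values():
            assert est.q025 <= est.mode <= est.q975

    def test_uninformative_stats_match_rejection_posterior(self):
        # stats carry no information about the parameter: the local-linear
        # slopes vanish and the adjusted draws equal the raw retained draws
        rng = np.random.default_rng(1)
        n = 400
        stats = rng.normal(size=(n, 2))
        params = pd.DataFrame({"ne": np.exp(rng.normal(8, 1, n))})
        ref = ReferenceTable(np.array(["A"] * n), params, stats, ["s1", "s2"])
        obs = np.zeros(2)
        post = estimate_params(ref, obs, "A", tolerance=1.0)
        idx, dist = reject(ref, obs, 1.0)
        raw = params["ne"].to_numpy()[idx]
        lo, hi = np.percentile(raw, [2.5, 97.5])
        assert post.estimates["ne"].q025 == pytest.approx(lo, rel=0.2)
        assert post.estimates["ne"].q975 == pytest.approx(hi, rel=0.2)

    def test_insufficient_rows_rejected(self):
        ref = _manual_table(n=100)
        with pytest.raises(ValueError, match="retained"):
            estimate_params(ref, ref.stats[0], "A", tolerance=0.05)


class TestCalendar:
    def test_zero(self):
        c = to_calendar(0)
        assert c.value == 0.0 and c.plus_minus == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            to_calendar(-1)

    def test_unit_switch(self):
        assert to_calendar(1000).unit == "ky"       # 150 ky
        assert to_calendar(10_000).unit == "My"     # 1.5 My

    def test_formatting(self):
        assert str(to_calendar(4140)) == "621 ± 207 ky"

    def test_custom_generation_time(self):
        c = to_calendar(1000, g_mean=100, g_sd=10)
        assert c.years == 100_000.0 and c.pm_years == 10_000.0
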