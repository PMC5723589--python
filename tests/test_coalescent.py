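"""Scenario engine: GSM mutation matrix, demography validation, priors,
reproducibility, and the study-structured synthetic generator."""

import numpy as np
import pytest

from firpopgen.coalescent_gsm import (
    ALLELE_OFFSET,
    N_STATES,
    AdmixtureEvent,
    DivergenceEvent,
    NeChangeEvent,
    Prior,
    PriorSpec,
    ScenarioSpec,
    builtin_scenarios,
    draw_params,
    gsm_model,
    simulate,
    study_dataset,
    study_scenario,
    _reflect,
)
from firpopgen.differentiation import wc_theta


class TestGsmModel:
    def test_rows_sum_to_one(self):
        m = gsm_model(0.25)
        np.testing.assert_allclose(m.transition_matrix.sum(axis=1), 1.0, atol=1e-12)

    def test_smm_only_single_steps(self):
        m = gsm_model(0.0)
        tm = m.transition_matrix
        for i in range(1, N_STATES - 1):
            assert tm[i, i - 1] == pytest.approx(0.5)
            assert tm[i, i + 1] == pytest.approx(0.5)

    def test_reflection_at_bounds(self):
        assert _reflect(-1) == 1
        assert _reflect(N_STATES) == N_STATES - 2
        assert _reflect(0) == 0
        m = gsm_model(0.3)
        assert m.transition_matrix[0, 1] > 0.5  # down-steps fold back up

    def test_bad_parameter_rejected(self):
        with pytest.raises(ValueError):
            gsm_model(1.0)


class TestScenarioValidation:
    def test_simple_divergence_ok(self):
        spec = ScenarioSpec("s", {"A": 5, "B": 5}, {"A": 1e3, "B": 1e3},
                            [DivergenceEvent(100, "A", "B")])
        spec.validate()

    def test_no_root_rejected(self):
        spec = ScenarioSpec("s", {"A": 5, "B": 5}, {"A": 1e3, "B": 1e3}, [])
        with pytest.raises(ValueError, match="root"):
            spec.validate()

    def test_stranded_lineage_rejected(self):
        spec = ScenarioSpec(
            "s", {"A": 5, "B": 5, "C": 5},
            {"A": 1e3, "B": 1e3, "C": 1e3},
            [DivergenceEvent(50, "B", "A"),
             DivergenceEvent(100, "C", "B")],   # B is gone by t=100
        )
        with pytest.raises(ValueError, match="stranded"):
            spec.validate()

    def test_admixture_rate_bounds(self):
        with pytest.raises(ValueError):
            AdmixtureEvent(10, "C", "A", "B", 1.5)

    def test_negative_ne_rejected(self):
        spec = ScenarioSpec("s", {"A": 5, "B": 5}, {"A": -5.0, "B": 1e3},
                            [DivergenceEvent(100, "A", "B")])
        with pytest.raises(ValueError, match="positive"):
            spec.validate()


class TestPriors:
    def test_uniform_bounds(self):
        prior = PriorSpec({"x": Prior("uniform", 10, 20)})
        draws = draw_params(prior, 200, seed=0)
        assert all(10 <= d["x"] <= 20 for d in draws)

    def test_ordering_constraint(self):
        prior = PriorSpec({"t1": Prior("uniform", 0.1, 100), "t2": Prior("uniform", 0.1, 100)},
                          constraints=[("t1", "t2")])
        draws = draw_params(prior, 300, seed=1)
        assert all(d["t1"] < d["t2"] for d in draws)

    def test_law_of_large_numbers(self):
        prior = PriorSpec({"u": Prior("uniform", 0, 1)})
        draws = draw_params(prior, 10_000, seed=2)
        assert np.mean([d["u"] for d in draws]) == pytest.approx(0.5, abs=0.02)

    def test_impossible_constraint_raises(self):
        prior = PriorSpec({"a": Prior("uniform", 10, 20), "b": Prior("uniform", 0, 1)},
                          constraints=[("a", "b")])
        with pytest.raises(RuntimeError, match="acceptance"):
            draw_params(prior, 10, seed=3)


class TestSimulate:
    SPEC = ScenarioSpec("two", {"A": 6, "B": 6}, {"A": 2e3, "B": 2e3},
                        [DivergenceEvent(1e3, "A", "B")])

    def test_bit_exact_reproducibility(self):
        a = simulate(self.SPEC, n_loci=4, mu=2e-4, seed=9)
        b = simulate(self.SPEC, n_loci=4, mu=2e-4, seed=9)
        assert a.dataset.equals(b.dataset)

    def test_zero_rate_monomorphic_at_root(self):
        sim = simulate(self.SPEC, n_loci=3, mu=0.0, seed=1)
        assert np.all(sim.dataset.calls == ALLELE_OFFSET + N_STATES // 2)

    def test_states_within_bounded_range(self):
        sim = simulate(self.SPEC, n_loci=6, mu=5e-3, gsm_p=0.29, seed=2)
        assert sim.dataset.calls.min() >= ALLELE_OFFSET
        assert sim.dataset.calls.max() <= ALLELE_OFFSET + N_STATES - 1

    def test_divergence_time_increases_theta(self):
        thetas = []
        for t_gen, seed in [(200, 3), (2_000, 4), (20_000, 5)]:
            spec = ScenarioSpec("two", {"A": 10, "B": 10}, {"A": 2e3, "B": 2e3},
                                [DivergenceEvent(t_gen, "A", "B")])
            sim = simulate(spec, n_loci=40, mu=5e-4, seed=seed)
            thetas.append(wc_theta(sim.dataset).theta)
        assert thetas[0] < thetas[1] < thetas[2]


class TestBuiltinScenarios:
    def test_all_validate_under_prior_draws(self):
        for name, sset in builtin_scenarios().items():
            for d in draw_params(sset.prior, 3, seed=5):
                for scen in sset.scenario_names:
                    sset.build(scen, d).validate()

    def test_divergence_alternative_structure(self):
        sset = builtin_scenarios()["olcayana"]
        d = draw_params(sset.prior, 1, seed=6)[0]
        spec = sset.build("divergence", d)
        assert spec.n_events(DivergenceEvent) == 2
        assert spec.n_events(AdmixtureEvent) == 0
        hyb = sset.build("hybrid", d)
        assert hyb.n_events(AdmixtureEvent) == 1

    def test_cilicica_bottleneck_has_ne_change(self):
        sset = builtin_scenarios()["cilicica_sl"]
        d = draw_params(sset.prior, 1, seed=7)[0]
        assert sset.build("ne_change", d).n_events(NeChangeEvent) == 1

    def test_hybrid_is_genetically_intermediate(self):
        sset = builtin_scenarios()["olcayana"]
        params = {"ne_Ane": 2e4, "ne_Anb": 2e4, "ne_Axo": 2e4,
                  "t1": 2_000.0, "t2": 50_000.0, "r": 0.5}
        spec = sset.build("hybrid", params)
        spec.samples = {"Ane": 12, "Anb": 12, "Axo": 12}
        sim = simulate(spec, n_loci=40, mu=3e-4, seed=8)
        ds = sim.dataset
        t_ane_anb = wc_theta(ds, ["Ane", "Anb"]).theta
        t_axo_ane = wc_theta(ds, ["Axo", "Ane"]).theta
        t_axo_anb = wc_theta(ds, ["Axo", "Anb"]).theta
        assert t_axo_ane < t_ane_anb
        assert t_axo_anb < t_ane_anb


class TestStudyGenerator:
    def test_structure_and_metadata(self):
        pops = {"Anb": 2, "Ane": 1, "Aci": 2}
        ds, meta = study_dataset(seed=3, pops_per_taxon=pops, n_diploid=8,
                                 n_loci=3, missing_rate=0.0)
        assert len(ds.population_ids()) == 5
        assert ds.n_individuals == 5 * 8
        assert set(ds.groups.values()) == {"Anb", "Ane", "Aci"}
        for m in meta.values():
            assert abs(m.lat) <= 90 and abs(m.lon) <= 180

    def test_missing_rate_applied(self):
        ds, _ = study_dataset(seed=4, pops_per_taxon={"Anb": 2, "Ane": 2},
                              n_diploid=15, n_loci=6, missing_rate=0.1)
        frac = (ds.calls[:, :, 0] == 0).mean()
        assert 0.05 < frac < 0.16

    def test_scenario_validates(self):
        spec, meta = study_scenario({"Anb": 2, "Axo": 1, "Acc": 1})
        spec.validate()
        assert len(meta) == 4


class TestScenarioConfig:
    def test_dict_round_trip(self):
        spec = ScenarioSpec(
            "rt", {"A": 5, "B": 5, "C": 4},
            {"A": 1e3, "B": 2e3, "C": 1.5e3},
            [AdmixtureEvent(50, "C", "A", "B", 0.3),
             DivergenceEvent(500, "A", "B"),
             NeChangeEvent(200, "B", 5e2)],
        )
        again = ScenarioSpec.from_dict(spec.to_dict())
        assert again.to_dict() == spec.to_dict()

    def test_file_round_trip(self, tmp_path):
        import json
        from firpopgen.coalescent_gsm import load_scenario

        spec = ScenarioSpec("f", {"A": 3, "B": 3}, {"A": 1e3, "B": 1e3},
                            [DivergenceEvent(100, "A", "B")])
        p = tmp_path / "scen.json"
        p.write_text(json.dumps(spec.to_dict()))
        assert load_scenario(p).to_dict() == spec.to_dict()

    def test_unknown_event_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            ScenarioSpec.from_dict({"name": "x", "samples": {"A": 2},
                                    "ne": {"A": 1e3},
                                    "events": [{"kind": "meteor", "time": 1}]})
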