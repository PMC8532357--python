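"""Toy wine network and the planted multi-strain fermentation generator."""

import numpy as np
import pytest

from vinoflux import enology, rates, synthetic
from vinoflux.model import build_stoichiometric_system, find_exchange_reactions
from vinoflux.synthetic import (
    ToyNetworkSpec,
    build_toy_wine_network,
    make_benchmark_scenario,
    phase_exchange_fluxes,
    phase_of,
    simulate_strain_timeseries,
    toy_anaerobic_recipe,
)


class TestToyNetwork:
    def test_feasible_with_exchanges_open(self, toy_model):
        feasible, _ = enology.check_feasibility(
            enology.apply_anaerobic_modifications(toy_model, toy_anaerobic_recipe())
        )
        assert feasible

    def test_internal_metabolites_producible_and_consumable(self, toy_model):
        """Metabolites without a boundary exchange must have S-row entries of
        both signs; exchange-touched species get their relief valve from the
        exchange itself (the sterol one only after the anaerobic recipe)."""
        sys_ = build_stoichiometric_system(toy_model)
        boundary = {
            next(iter(toy_model.reaction(rid).stoichiometry))
            for rid in find_exchange_reactions(toy_model)
        }
        internal = [m for m in sys_.metabolite_ids if m not in boundary]
        assert internal  # the chain actually has internal species
        for mid in internal:
            row = sys_.S[sys_.metabolite_ids.index(mid)]
            assert np.any(row > 0), f"{mid} has no producer"
            assert np.any(row < 0), f"{mid} has no consumer"

    def test_deterministic_construction(self):
        a = build_toy_wine_network(ToyNetworkSpec(seed=3))
        b = build_toy_wine_network(ToyNetworkSpec(seed=3))
        assert [r.id for r in a.reactions] == [r.id for r in b.reactions]
        for ra, rb in zip(a.reactions, b.reactions):
            assert ra.stoichiometry == rb.stoichiometry

    def test_size_scales_with_voc_branches(self):
        base = build_toy_wine_network(ToyNetworkSpec(n_branch_vocs=1))
        more = build_toy_wine_network(ToyNetworkSpec(n_branch_vocs=3))
        assert len(more.reactions) == len(base.reactions) + 6
        assert len(base.reactions) in range(15, 30)

    def test_ehrlich_branch_optional(self):
        m = build_toy_wine_network(ToyNetworkSpec(include_ehrlich=False))
        assert not m.has_reaction("TA1") and m.has_reaction("VOC1")

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ToyNetworkSpec(n_branch_vocs=0)

    def test_subsystems_and_gprs_populated(self, toy_model):
        internal = [r for r in toy_model.reactions if r.id not in find_exchange_reactions(toy_model)]
        assert all(r.subsystem for r in internal)
        assert any("Ehrlich" in r.subsystem for r in internal)


class TestPhaseFluxes:
    def test_planted_vector_is_steady_state(self, toy_model):
        fluxes = phase_exchange_fluxes(0.05, -2.5, 0.25, 0.4, 0.05, {2: 0.2})
        m = enology.apply_anaerobic_modifications(toy_model, toy_anaerobic_recipe())
        cs = enology.ConstraintSet("s", 0.0, fluxes, growth_rate=0.05)
        constrained = enology.fix_exchange_fluxes(m, cs, 0.0)
        feasible, v = enology.check_feasibility(constrained)
        assert feasible

    def test_infeasible_primitives_rejected(self):
        with pytest.raises(ValueError):
            phase_exchange_fluxes(0.05, -0.001, 0.25, 0.4, 0.05)

    def test_phase_boundaries(self):
        assert phase_of(0) == "exponential"
        assert phase_of(35.9) == "exponential"
        assert phase_of(36) == "deceleration"
        assert phase_of(58) == "stationary"
        assert phase_of(144) == "stationary"


class TestSimulation:
    def test_noise_free_round_trip_recovers_planted_rate(self):
        model, scenario, _ = make_benchmark_scenario(seed=0, noise_cv=0.0)
        series = simulate_strain_timeseries(model, scenario)
        s1 = next(s for s in series if s.strain == "S1")
        planted = scenario.exchange_fluxes["S1"]["exponential"]["EX_glc"]
        mu = scenario.growth_rates["S1"]["exponential"]
        got = rates.estimate_specific_flux(s1, "glucose", 24.0)
        # central difference on an exponential segment: relative error (mu dt)^2/6
        assert got == pytest.approx(planted, rel=2 * (mu * scenario.dt_h) ** 2 / 6)

    def test_constant_biomass_segment_is_exact(self):
        model, scenario, _ = make_benchmark_scenario(seed=0, noise_cv=0.0)
        series = simulate_strain_timeseries(model, scenario)
        s1 = series[0]
        planted = scenario.exchange_fluxes["S1"]["stationary"]["EX_glc"]
        # stationary phase: mu = 0, X constant, concentration exactly linear
        assert rates.estimate_specific_flux(s1, "glucose", 100.0) == pytest.approx(planted, abs=1e-12)

    def test_growth_rate_recovered_within_one_percent(self):
        model, scenario, _ = make_benchmark_scenario(seed=0, noise_cv=0.0)
        series = simulate_strain_timeseries(model, scenario)
        got = rates.estimate_growth_rate(series[0], 24.0)
        assert got == pytest.approx(0.05, rel=0.01)

    def test_same_seed_identical_series(self):
        model, scenario, _ = make_benchmark_scenario(seed=5)
        a = simulate_strain_timeseries(model, scenario)
        b = simulate_strain_timeseries(model, scenario)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.biomass, sb.biomass)
            for comp in sa.concentrations:
                assert np.array_equal(sa.concentrations[comp], sb.concentrations[comp])

    def test_series_well_formed_under_noise(self):
        model, scenario, _ = make_benchmark_scenario(seed=8)
        for s in simulate_strain_timeseries(model, scenario):
            assert np.all(np.diff(s.times) > 0)
            assert np.all(s.biomass > 0)
            for comp, c in s.concentrations.items():
                assert np.all(c >= 0), comp


class TestBenchmarkScenario:
    def test_all_constraint_sets_feasible_noise_free_at_band_zero(self, benchmark_noise_free):
        model, scenario, _, table = benchmark_noise_free
        m = enology.apply_anaerobic_modifications(model, toy_anaerobic_recipe())
        assert len(table.rows) == 12
        for cs in table.rows:
            constrained = enology.fix_exchange_fluxes(m, cs, 0.0)
            feasible, _ = enology.check_feasibility(constrained)
            assert feasible, f"{cs.strain}@{cs.time_h}"

    def test_all_constraint_sets_feasible_with_noise_via_band_ladder(self):
        from vinoflux.pipeline import DEFAULT_BAND_LADDER, fix_with_band_ladder

        model, scenario, _ = make_benchmark_scenario(seed=0)
        series = simulate_strain_timeseries(model, scenario)
        table = rates.build_flux_table(series, [24.0, 58.0, 144.0], scenario.compound_to_exchange)
        m = enology.apply_anaerobic_modifications(model, toy_anaerobic_recipe())
        for cs in table.rows:
            _, band = fix_with_band_ladder(m, cs, DEFAULT_BAND_LADDER)
            assert band <= DEFAULT_BAND_LADDER[-1]

    def test_ground_truth_declares_planted_design(self):
        _, scenario, truth = make_benchmark_scenario(seed=0)
        assert truth.similar_pair == ("S1", "S2")
        assert scenario.exchange_fluxes["S1"] == scenario.exchange_fluxes["S2"]
        base = scenario.exchange_fluxes["S1"]["exponential"]["EX_fusel"]
        high = scenario.exchange_fluxes["S3"]["exponential"]["EX_fusel"]
        assert high / base == pytest.approx(truth.ehrlich_fold)
        for rid in truth.planted_reactions:
            assert rid in [r.id for r in build_toy_wine_network().reactions]
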