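"""Unit and property tests of the single-cell metabolic automaton."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spherosim.metabolism import (
    CellEvent, Phase, advance_cycle_phase, carrier_ph_factor,
    death_probability, divide_cell, intracellular_rhs,
    membrane_transport_flux, step_fixed_environment, synthesis_rate_double_mm,
    update_live_volumes, advance_population_events, Population,
    IATP, IAL, IO2, IG, IPROT,
)
from spherosim.engine import perform_divisions

from conftest import make_cell

STANDARD_EXT = np.array([6.4e-3, 2.7, 0.3, 0.0])  # O2, glucose, glutamine, lactate


class TestMembraneTransport:
    @given(c=st.floats(0, 50), ph=st.floats(5.6, 7.9))
    @settings(max_examples=50, deadline=None)
    def test_equal_concentrations_give_zero_flux(self, c, ph):
        from spherosim.params import MetabolicParams
        params = MetabolicParams()
        for species in ("O2", "glucose", "glutamine", "lactate"):
            assert membrane_transport_flux(species, c, c, ph, params) == 0.0

    @given(c_out=st.floats(0, 50), c_in=st.floats(0, 50), ph=st.floats(5.6, 7.9))
    @settings(max_examples=100, deadline=None)
    def test_carrier_antisymmetry_is_exact(self, c_out, c_in, ph):
        from spherosim.params import MetabolicParams
        params = MetabolicParams()
        f = membrane_transport_flux("glucose", c_out, c_in, ph, params)
        g = membrane_transport_flux("glucose", c_in, c_out, ph, params)
        assert f == -g

    def test_half_saturation_at_km(self, params):
        f = membrane_transport_flux("glucose", params.km_glucose, 0.0, 7.4, params)
        vmax_eff = params.vmax_glucose * carrier_ph_factor(7.4, params)
        assert f == pytest.approx(vmax_eff / 2)

    def test_saturation_limit(self, params):
        f = membrane_transport_flux("glucose", 1e9, 0.0, 7.4, params)
        vmax_eff = params.vmax_glucose * carrier_ph_factor(7.4, params)
        assert f == pytest.approx(vmax_eff, rel=1e-6)

    def test_oxygen_flux_linear_in_difference(self, params):
        f1 = membrane_transport_flux("O2", 4e-3, 1e-3, 7.4, params)
        f2 = membrane_transport_flux("O2", 7e-3, 4e-3, 7.4, params)
        assert f1 == pytest.approx(f2)

    def test_ph_sensitivity_is_monotone(self, params):
        fluxes = [membrane_transport_flux("glucose", 2.7, 0.0, ph, params)
                  for ph in (6.0, 6.5, 7.0, 7.5)]
        assert np.all(np.diff(fluxes) > 0)

    def test_invalid_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            membrane_transport_flux("glucose", -1.0, 0.0, 7.4, params)
        with pytest.raises(ValueError):
            membrane_transport_flux("caffeine", 1.0, 0.0, 7.4, params)
        with pytest.raises(ValueError):
            membrane_transport_flux("glucose", 1.0, 0.0, 9.0, params)


class TestDoubleSubstrateMM:
    def test_zero_substrate_gives_zero(self):
        assert synthesis_rate_double_mm(0.0, 5.0, 2.0, 1.0, 1.0) == 0.0
        assert synthesis_rate_double_mm(5.0, 0.0, 2.0, 1.0, 1.0) == 0.0

    def test_quarter_vmax_at_both_km(self):
        assert synthesis_rate_double_mm(1.0, 2.0, 8.0, 1.0, 2.0) == pytest.approx(2.0)

    def test_saturates_at_vmax(self):
        assert synthesis_rate_double_mm(1e9, 1e9, 8.0, 1.0, 2.0) == pytest.approx(8.0, rel=1e-6)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            synthesis_rate_double_mm(-1.0, 1.0, 1.0, 1.0, 1.0)


class TestIntracellularRhs:
    def test_no_substrates_no_activity(self, params):
        cell = make_cell(params, G_in=0.0, G6P=0.0, store=0.0, A_in=0.0,
                         AL_in=0.0, O2_in=0.0, ATPp=0.0, protein=0.0)
        d = intracellular_rhs(cell, np.zeros(4), params)
        # no uptake, no synthesis: every derivative vanishes
        assert np.allclose(d, 0.0, atol=1e-30)

    def test_pasteur_like_switch(self, params):
        """With abundant oxygen, less glycolytic flux is routed to lactate."""
        oxic = make_cell(params)
        anoxic = make_cell(params, O2_in=0.0)
        d_oxic = intracellular_rhs(oxic, STANDARD_EXT, params)
        d_anoxic = intracellular_rhs(anoxic, STANDARD_EXT, params)
        assert d_oxic[IAL] < d_anoxic[IAL]

    def test_fresh_cell_charges_atp_in_standard_environment(self, params):
        cell = make_cell(params, ATPp=0.5 * make_cell(params).ATPp)
        d = intracellular_rhs(cell, STANDARD_EXT, params)
        assert d[IATP] > 0

    def test_dead_cell_is_frozen(self, params):
        cell = make_cell(params, phase=Phase.DEAD)
        d = intracellular_rhs(cell, STANDARD_EXT, params)
        assert np.all(d == 0.0)

    def test_nan_state_rejected(self, params):
        cell = make_cell(params, ATPp=float("nan"))
        with pytest.raises(ValueError):
            intracellular_rhs(cell, STANDARD_EXT, params)


class TestDeathProbability:
    def test_no_lactate_no_death(self, params):
        p, starved = death_probability(0.0, 1e-15, 50.0, params)
        assert p == 0.0
        assert not starved

    def test_half_probability_at_log2_hazard(self, params):
        # lambda dt = ln 2  =>  p = 1/2
        al = params.lactate_death_threshold \
            + math.log(2) / 50.0 * params.lactate_death_scale / params.lambda0_death
        p, _ = death_probability(al, 1e-15, 50.0, params)
        assert p == pytest.approx(0.5)

    def test_hazard_monotone_in_lactate(self, params):
        ps = [death_probability(al, 1e-15, 50.0, params)[0]
              for al in np.linspace(0, 20, 15)]
        assert np.all(np.diff(ps) >= 0)

    def test_starvation_flag(self, params):
        v = 4 / 3 * math.pi * params.radius_birth**3
        _, starved = death_probability(0.0, 0.5 * params.atp_starvation * v,
                                       50.0, params, volume=v)
        assert starved

    def test_monte_carlo_frequency_matches(self, params, rng):
        """Sampled death frequency agrees with p within 3 binomial sigma."""
        al, dt, n = 5.0, 3600.0, 100_000
        p, _ = death_probability(al, 1e-15, dt, params)
        assert 0.01 < p < 0.99
        deaths = int((rng.random(n) < p).sum())
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(deaths - n * p) < 3 * sigma

    def test_nonpositive_dt_rejected(self, params):
        with pytest.raises(ValueError):
            death_probability(0.0, 1e-15, 0.0, params)


class TestCyclePhase:
    def test_dead_cell_unchanged(self, params, rng):
        cell = make_cell(params, phase=Phase.DEAD)
        out, event = advance_cycle_phase(cell, 50.0, rng, params)
        assert event is CellEvent.NONE
        assert out.phase is Phase.DEAD

    def test_energetic_checkpoint_blocks_g1m_exit(self, params, rng):
        """ATP below the checkpoint: no G1m->G1p transition, however long."""
        v = 4 / 3 * math.pi * params.radius_birth**3
        cell = make_cell(params, ATPp=0.5 * params.atp_checkpoint * v,
                         cyclinE=10 * params.theta_cyclin_e,
                         protein=2 * params.protein_ref)
        for dt in (50.0, 3600.0, 864000.0):
            out, _ = advance_cycle_phase(cell, dt, rng, params,
                                         allow_death=False)
            assert out.phase is Phase.G1M

    def test_mitosis_flag_requires_complete_genome(self, params, rng):
        cell = make_cell(params, phase=Phase.M, DNA=1.0,
                         age_in_phase=2 * params.t_m)
        _, event = advance_cycle_phase(cell, 50.0, rng, params)
        assert event is CellEvent.MITOSIS_DUE

    def test_mean_cycle_time_near_20_hours(self, config, rng):
        """Isolated cells in the standard fixed environment divide with a
        mean cycle time within 10% of the 20 h calibration target."""
        params = config.metabolic
        env = np.asarray(config.environment.concentrations())
        ff = config.diffusion.free_volume_fraction
        pop = Population.standard_newborn(40, params, env, ff)
        dt = config.dt
        birth = {int(i): 0.0 for i in pop.ids}
        cycles = []
        t = 0.0
        # ~5.5 simulated days: every cell completes several cycles
        for _ in range(int(5.5 * 86400 / dt)):
            step_fixed_environment(pop, params, env, 7.4, ff, dt)
            update_live_volumes(pop, params)
            mit, _ = advance_population_events(pop, params, ff, dt, rng,
                                               allow_death=False)
            idx = np.nonzero(mit)[0]
            for i in idx:
                old = int(pop.ids[i])
                if old in birth:
                    cycles.append(t - birth.pop(old))
            perform_divisions(pop, mit, rng, params, constant_count=True)
            for i in idx:
                birth[int(pop.ids[i])] = t
            t += dt
        mean_h = np.mean(cycles) / 3600.0
        assert len(cycles) > 100
        assert abs(mean_h - 20.0) / 20.0 < 0.10


class TestDivision:
    def test_requires_m_phase(self, params, rng):
        with pytest.raises(ValueError):
            divide_cell(make_cell(params, phase=Phase.S, DNA=1.0), rng, params)

    def test_conservation_to_machine_precision(self, params, rng):
        mother = make_cell(params, phase=Phase.M, DNA=1.0,
                           protein=2.1e-13, mtDNA=201.7, n_mito=201,
                           radius=6.3e-6)
        d1, d2 = divide_cell(mother, rng, params)
        assert d1.n_mito + d2.n_mito == mother.n_mito
        assert d1.mtDNA + d2.mtDNA == pytest.approx(mother.mtDNA, rel=1e-14)
        for attr in ("G_in", "G6P", "store", "A_in", "AL_in", "O2_in",
                     "ATPp", "protein"):
            total = getattr(d1, attr) + getattr(d2, attr)
            assert total == pytest.approx(getattr(mother, attr), rel=1e-14)
        # the volume map is linear in (protein, n_mito): volumes add exactly
        assert d1.volume + d2.volume == pytest.approx(
            _map_volume(mother, params), rel=1e-12)

    def test_daughter_center_separation_is_0p4_r0(self, params, rng):
        mother = make_cell(params, phase=Phase.M, DNA=1.0, radius=6.3e-6)
        d1, d2 = divide_cell(mother, rng, params)
        sep = np.linalg.norm(d1.position - d2.position)
        assert sep / mother.radius == pytest.approx(0.4, abs=1e-12)

    def test_daughters_reset_to_g1m(self, params, rng):
        mother = make_cell(params, phase=Phase.M, DNA=1.0)
        d1, d2 = divide_cell(mother, rng, params)
        for d in (d1, d2):
            assert d.phase is Phase.G1M
            assert d.DNA == 0.0
            assert d.cyclinE == 0.0 and d.cyclinB == 0.0

    def test_volume_split_is_symmetric_on_average(self, params, rng):
        """Mean daughter-1 volume fraction over many divisions is 1/2."""
        fractions = []
        for _ in range(4000):
            mother = make_cell(params, phase=Phase.M, DNA=1.0,
                               protein=2e-13, mtDNA=200.0, n_mito=200)
            d1, d2 = divide_cell(mother, rng, params)
            fractions.append(d1.volume / (d1.volume + d2.volume))
        fractions = np.asarray(fractions)
        sigma = fractions.std() / math.sqrt(len(fractions))
        assert abs(fractions.mean() - 0.5) < 3 * sigma + 1e-4


def _map_volume(cell, params):
    vb = 4 / 3 * math.pi * params.radius_birth**3
    return vb * (params.w_protein * cell.protein / params.protein_ref
                 + params.w_mito * cell.n_mito / params.n_mito_ref)


def test_dead_cell_state_frozen_through_integration(config, rng):
    """No intracellular variable of a dead cell changes during integration."""
    params = config.metabolic
    env = np.asarray(config.environment.concentrations())
    pop = Population.standard_newborn(3, params, env, 0.15)
    pop.phase[1] = int(Phase.DEAD)
    before = pop.X[1].copy()
    for _ in range(20):
        step_fixed_environment(pop, params, env, 7.4, 0.15, 50.0)
        advance_population_events(pop, params, 0.15, 50.0, rng)
    assert np.array_equal(pop.X[1], before)
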