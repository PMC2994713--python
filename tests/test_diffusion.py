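"""Diffusion network construction and the implicit Euler / Newton solve."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from spherosim.diffusion import (
    GlobalStateVector, NewtonSolver, ReactionDiffusionSystem,
    assemble_residual, build_diffusion_network, geometric_factor,
    newton_solve_step, ph_from_lactate, N_EXTRACELLULAR,
)
from spherosim.geometry import ContactNetwork, build_contact_network
from spherosim.metabolism import Phase, Population
from spherosim.params import DiffusionParams, Environment, SolverParams

from conftest import make_population


def _system(config, positions, phases=None, env_mode="fixed",
            surface=None):
    pop = make_population(config, positions, phases=phases)
    if surface is None:
        net_c = build_contact_network(pop.position, pop.radius)
    else:
        net_c = build_contact_network(pop.position, pop.radius)
        net_c.is_surface = np.asarray(surface, dtype=bool)
    env = Environment(mode=env_mode)
    net = build_diffusion_network(pop, net_c, config.diffusion)
    return pop, ReactionDiffusionSystem(pop, net, env, config.metabolic,
                                        config.diffusion)


def _closed_two_node_system(config, conc=(1.0, 2.0)):
    """Two dead cells (inert compartments) linked to each other with no
    environment exchange: pure two-compartment diffusion."""
    positions = [[0, 0, 0], [9e-6, 0, 0]]
    pop, system = _system(config, positions,
                          phases=[Phase.DEAD, Phase.DEAD],
                          env_mode="fixed", surface=[False, False])
    vf = config.diffusion.free_volume_fraction * pop.volume
    for s in range(4):
        pop.E[0, s] = conc[0] * vf[0]
        pop.E[1, s] = conc[1] * vf[1]
    net_c = build_contact_network(pop.position, pop.radius)
    net_c.is_surface = np.array([False, False])
    net = build_diffusion_network(pop, net_c, config.diffusion)
    system = ReactionDiffusionSystem(pop, net, Environment(mode="fixed"),
                                     config.metabolic, config.diffusion)
    return pop, system


class TestNetworkConstruction:
    def test_tetrahedron_link_counts(self, config):
        a = 9e-6
        positions = np.array([[0, 0, 0], [a, 0, 0], [a / 2, a * 0.87, 0],
                              [a / 2, a * 0.29, a * 0.82]])
        pop, system = _system(config, positions)
        assert len(system.net.cell_links) == 6
        assert len(system.net.env_cells) == 4  # all four are surface

    def test_single_cell_has_only_environment_link(self, config):
        pop, system = _system(config, [[0, 0, 0]])
        assert len(system.net.cell_links) == 0
        assert len(system.net.env_cells) == 1

    def test_geometric_factor_symmetric_and_cutoff(self, config):
        g1 = geometric_factor(9e-6, 5e-6, 6e-6, 1.4)
        g2 = geometric_factor(9e-6, 6e-6, 5e-6, 1.4)
        assert g1 == g2 > 0
        assert geometric_factor(20e-6, 5e-6, 6e-6, 1.4) == 0.0

    def test_missing_surface_classification_rejected(self, config):
        pop = make_population(config, [[0, 0, 0]])
        net_c = build_contact_network(pop.position, pop.radius)
        net_c.is_surface = np.zeros(5, dtype=bool)  # wrong length
        with pytest.raises(ValueError):
            build_diffusion_network(pop, net_c, config.diffusion)

    def test_link_records_include_environment(self, config):
        _, system = _system(config, [[0, 0, 0], [9e-6, 0, 0]])
        links = system.net.links()
        env_links = [l for l in links if l.node_b == -1]
        assert len(env_links) == 2


class TestGlobalStateVector:
    def test_round_trip_is_lossless(self, config, rng):
        pop = make_population(config, rng.random((5, 3)) * 4e-5)
        pop.X[:] = rng.random(pop.X.shape) * 1e-15
        pop.E[:] = rng.random(pop.E.shape) * 1e-16
        gsv = GlobalStateVector(len(pop))
        env_masses = rng.random(4)
        x = gsv.pack(pop, env_masses)
        assert x.shape == (19 * 5 + 4,)
        X0, E0 = pop.X.copy(), pop.E.copy()
        pop.X[:] = 0
        pop.E[:] = 0
        env_back = gsv.write_back(x, pop)
        assert np.array_equal(pop.X, X0)
        assert np.array_equal(pop.E, E0)
        assert np.array_equal(env_back, env_masses)


class TestResidual:
    def test_zero_dt_residual_is_difference(self, config, rng):
        pop, system = _system(config, [[0, 0, 0], [9e-6, 0, 0]])
        x_now = system.pack_state()
        x_next = x_now * (1 + 0.01 * rng.random(x_now.size))
        r = assemble_residual(system, x_next, x_now, 0.0)
        assert np.allclose(r, x_next - x_now)

    def test_dimension_mismatch_rejected(self, config):
        pop, system = _system(config, [[0, 0, 0]])
        x = system.pack_state()
        with pytest.raises(ValueError):
            assemble_residual(system, x[:-1], x, 50.0)

    def test_fixed_point_of_dynamics_has_zero_residual(self, config):
        # dead, isolated, closed compartments: F = 0 identically
        pop, system = _closed_two_node_system(config, conc=(1.0, 1.0))
        x = system.gsv.pack(pop, np.zeros(4))
        r = assemble_residual(system, x, x, 500.0)
        assert np.allclose(r, 0.0)


class TestClosedSystemDiffusion:
    def test_mass_conserved_over_1000_steps(self, config):
        pop, system = _closed_two_node_system(config)
        x = system.gsv.pack(pop, np.zeros(4))
        solver = NewtonSolver(system)
        e_slots = system.gsv.cell_blocks(x)[:, 15:19]
        total0 = e_slots.sum(axis=0).copy()
        for _ in range(1000):
            x = solver.solve_step(x, 50.0)
        total = system.gsv.cell_blocks(x)[:, 15:19].sum(axis=0)
        assert np.allclose(total, total0, rtol=1e-12, atol=0)

    def test_reaches_diffusive_equilibrium(self, config):
        pop, system = _closed_two_node_system(config)
        x = system.gsv.pack(pop, np.zeros(4))
        solver = NewtonSolver(system)
        for _ in range(200):
            x = solver.solve_step(x, 50.0)
        blocks = system.gsv.cell_blocks(x)
        c0 = blocks[0, 15:19] / system.vfree[0]
        c1 = blocks[1, 15:19] / system.vfree[1]
        assert np.allclose(c0, c1, rtol=1e-6)

    def test_relaxation_rate_matches_closed_form(self, config):
        """The concentration difference decays with the analytic
        two-compartment rate k = D g (1/V1 + 1/V2) (within 1%, using a step
        small compared to the relaxation time)."""
        pop, system = _closed_two_node_system(config)
        d_s = system.d_species[1]  # glucose
        g = system.net.g[0]
        k = d_s * g * (1 / system.vfree[0] + 1 / system.vfree[1])
        dt = 0.001 / k
        x = system.gsv.pack(pop, np.zeros(4))
        solver = NewtonSolver(system, SolverParams(rel_tol=1e-8))
        def dc(xv):
            b = system.gsv.cell_blocks(xv)
            return b[0, 16] / system.vfree[0] - b[1, 16] / system.vfree[1]
        d0 = dc(x)
        n_steps = 50
        for _ in range(n_steps):
            x = solver.solve_step(x, dt)
        d1 = dc(x)
        k_measured = -math.log(d1 / d0) / (n_steps * dt)
        assert k_measured == pytest.approx(k, rel=0.01)


class TestNewtonSolve:
    def test_warm_started_step_converges_quickly(self, config):
        pop, system = _system(config, [[0, 0, 0], [9e-6, 0, 0]])
        x = system.pack_state()
        solver = NewtonSolver(system)
        solver.solve_step(x, 50.0)
        assert solver.diagnostics.iterations <= 10

    def test_positivity_after_steps(self, config):
        pop, system = _system(config, [[0, 0, 0], [9e-6, 0, 0]])
        # start from a depleted extracellular state
        pop.E[:] *= 1e-3
        x = system.pack_state()
        solver = NewtonSolver(system)
        for _ in range(50):
            x = solver.solve_step(x, 50.0)
        assert np.all(x >= 0)

    def test_stability_at_50s_despite_microsecond_filling_times(self, config):
        """The extracellular compartments fill within ~ms-us, yet the
        implicit step remains stable and accurate at dt = 50 s (the stiffness
        bridge between molecular transport and macroscopic growth)."""
        # shrink free volumes 1000x: filling times ~ tens of microseconds
        config.diffusion.free_volume_fraction = 1.5e-4
        pop, system = _system(config, [[0, 0, 0], [9e-6, 0, 0]])
        x = system.pack_state()
        solver = NewtonSolver(system)
        for _ in range(20):
            x = solver.solve_step(x, 50.0)
        assert np.all(np.isfinite(x))
        assert np.all(x >= 0)

    def test_oracle_dense_ode_agreement_on_small_cluster(self, config):
        """100 implicit steps on a 5-cell chain agree with a high-accuracy
        adaptive integration of the same right-hand side to <= 1% per
        variable (relative to the per-slot scale)."""
        positions = [[i * 9e-6, 0, 0] for i in range(5)]
        pop, system = _system(config, positions, env_mode="fixed")
        x0 = system.pack_state()
        dt = 3.0  # small enough that first-order discretization error < 1%
        n_steps = 100
        solver = NewtonSolver(system, SolverParams(rel_tol=1e-6))
        x = x0.copy()
        for _ in range(n_steps):
            x = solver.solve_step(x, dt)

        env0 = x0[:N_EXTRACELLULAR].copy()

        def rhs(t, y):
            dy = system.rhs(y)
            dy[:N_EXTRACELLULAR] = 0.0  # fixed environment
            return dy

        sol = solve_ivp(rhs, (0, n_steps * dt), x0, method="LSODA",
                        rtol=1e-9, atol=1e-26)
        y_ref = sol.y[:, -1]
        assert np.allclose(y_ref[:N_EXTRACELLULAR], env0)
        blocks_num = system.gsv.cell_blocks(x)
        blocks_ref = system.gsv.cell_blocks(y_ref)
        scale = np.maximum(np.abs(blocks_ref), np.abs(blocks_ref).mean(axis=0))
        rel = np.abs(blocks_num - blocks_ref) / np.maximum(scale, 1e-30)
        assert rel.max() < 0.01

    def test_nonfinite_state_rejected(self, config):
        pop, system = _system(config, [[0, 0, 0]])
        x = system.pack_state()
        x[5] = np.nan
        with pytest.raises(ValueError):
            newton_solve_step(system, x, 50.0)


class TestPhFromLactate:
    def test_baseline_at_zero_lactate(self):
        assert ph_from_lactate(0.0) == pytest.approx(7.4)

    def test_monotone_non_increasing(self):
        c = np.linspace(0, 30, 100)
        ph = ph_from_lactate(c)
        assert np.all(np.diff(ph) <= 0)

    def test_calibration_point(self):
        """Documented curve: pH(K) = pH0 - dpH_max/2 at the half-saturation
        lactate concentration."""
        p = DiffusionParams()
        assert ph_from_lactate(p.k_ph, p) == pytest.approx(p.ph0 - p.ph_drop_max / 2)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            ph_from_lactate(-0.1)
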