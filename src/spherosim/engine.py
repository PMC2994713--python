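"""Simulation engine: initialization, the main program loop, termination.

Each macro step (default 50 s) performs, in order: (1) the implicit
metabolism-transport-diffusion solve plus cell volume growth, (2) mechanical
relaxation in stability-bounded sub-steps, (3) discrete cellular events
(deaths first, then mitoses, ties broken by array order = cell id order),
(4) refresh of the cluster geometry and topology (Delaunay adjacency, alpha
shape surface), and (5) summary statistics / snapshot output.  The loop runs
until all cells are dead or the requested number of steps has executed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import analysis_io
from .diffusion import NewtonSolver, ReactionDiffusionSystem, build_diffusion_network
from .geometry import ContactNetwork, build_contact_network
from .mechanics import relax_mechanics, shrink_dead_population
from .metabolism import (
    IPROT, Phase, Population, _split_population_row,
    advance_population_events, step_fixed_environment, update_live_volumes,
)
from .params import SimulationConfig

logger = logging.getLogger("spherosim")

#: exit codes of the two stop conditions
STOP_MAX_STEPS = "max_steps"
STOP_ALL_DEAD = "all_dead"


@dataclass
class SimulationState:
    pop: Population
    time: float
    step: int
    env_masses: np.ndarray
    network: ContactNetwork
    rng: np.random.Generator
    n_divisions: int = 0
    n_deaths: int = 0
    solver: NewtonSolver | None = None


# ---------------------------------------------------------------------------
# Population surgery (division)


def _append_rows(pop: Population, rows: list[dict]) -> None:
    if not rows:
        return
    k = len(rows)
    pop.ids = np.concatenate([pop.ids, [r["id"] for r in rows]])
    pop.position = np.vstack([pop.position, [r["position"] for r in rows]])
    pop.velocity = np.vstack([pop.velocity, [r["velocity"] for r in rows]])
    pop.radius = np.concatenate([pop.radius, [r["radius"] for r in rows]])
    pop.phase = np.concatenate([pop.phase,
                                np.full(k, int(Phase.G1M), dtype=np.int8)])
    pop.age_in_phase = np.concatenate([pop.age_in_phase, np.zeros(k)])
    pop.X = np.vstack([pop.X, [r["X"] for r in rows]])
    pop.E = np.vstack([pop.E, [r["E"] for r in rows]])
    pop.n_mito = np.concatenate([pop.n_mito,
                                 np.array([r["n_mito"] for r in rows], dtype=np.int64)])
    pop.time_of_death = np.concatenate([pop.time_of_death, np.full(k, np.nan)])
    pop.radius_at_death = np.concatenate([pop.radius_at_death, np.full(k, np.nan)])


def perform_divisions(pop: Population, mitosis_due: np.ndarray,
                      rng: np.random.Generator, params,
                      constant_count: bool = False) -> int:
    """Divide every flagged cell (in index order).

    The first daughter overwrites the mother's row; the second is appended —
    unless ``constant_count`` is set (initialization protocol), in which case
    the second daughter is discarded and the population size stays fixed.
    """
    indices = np.nonzero(mitosis_due)[0]
    appended: list[dict] = []
    for i in indices:
        d1, d2 = _split_population_row(pop, int(i), params, rng)
        mother_vel = pop.velocity[i].copy()
        pop.X[i] = d1["X"]
        pop.E[i] = d1["E"]
        pop.n_mito[i] = d1["n_mito"]
        pop.position[i] = d1["position"]
        pop.radius[i] = d1["radius"]
        pop.phase[i] = int(Phase.G1M)
        pop.age_in_phase[i] = 0.0
        pop.ids[i] = pop.next_id
        pop.next_id += 1
        if not constant_count:
            appended.append(dict(
                id=pop.next_id, position=d2["position"], velocity=mother_vel,
                radius=d2["radius"], X=d2["X"], E=d2["E"], n_mito=d2["n_mito"]))
            pop.next_id += 1
    _append_rows(pop, appended)
    return len(indices)


# ---------------------------------------------------------------------------
# Initialization protocol


def run_fixed_environment(
    pop: Population,
    config: SimulationConfig,
    rng: np.random.Generator,
    total_time: float,
    record_every: float = 3600.0,
    constant_count: bool = True,
    allow_death: bool = False,
) -> dict:
    """Evolve a population under a fixed environment with no spatial solve.

    Implements the initialization protocol: cells grow and proliferate
    freely, the environment is held fixed, and (if ``constant_count``) one
    daughter of every mitosis is discarded so the population size never
    changes.  Cells may transiently enter lethal parameter regions without
    dying when ``allow_death`` is False.  Returns recorded time series of
    cell-cycle phase fractions and mean intracellular state.
    """
    mp = config.metabolic
    env_conc = np.asarray(config.environment.concentrations())
    from .diffusion import ph_from_lactate
    ph_env = float(ph_from_lactate(env_conc[3], config.diffusion))
    dt = config.dt
    n_steps = int(round(total_time / dt))
    rec_stride = max(1, int(round(record_every / dt)))
    times = []
    phase_fractions = []
    mean_protein = []
    n_cells = []
    for k in range(n_steps):
        step_fixed_environment(pop, mp, env_conc, ph_env,
                               config.diffusion.free_volume_fraction, dt)
        update_live_volumes(pop, mp)
        mitosis_due, died = advance_population_events(
            pop, mp, config.diffusion.free_volume_fraction, dt, rng,
            allow_death=allow_death)
        perform_divisions(pop, mitosis_due, rng, mp,
                          constant_count=constant_count)
        if k % rec_stride == 0:
            alive = pop.alive
            n_alive = max(int(alive.sum()), 1)
            fr = np.array([np.sum(pop.phase[alive] == p) / n_alive
                           for p in range(5)])
            times.append((k + 1) * dt)
            phase_fractions.append(fr)
            mean_protein.append(float(pop.X[alive, IPROT].mean()) if alive.any() else 0.0)
            n_cells.append(int(alive.sum()))
    return dict(times=np.array(times),
                phase_fractions=np.array(phase_fractions),
                mean_protein=np.array(mean_protein),
                n_cells=np.array(n_cells))


def desynchronization_time(times: np.ndarray, phase_fractions: np.ndarray,
                           n_cells: int, cycle_time: float = 72000.0,
                           noise_mult: float = 2.0) -> float | None:
    """First time at which the cell-cycle phase-fraction oscillations fall
    below the binomial sampling noise floor.

    In a sliding window of one nominal cycle, the oscillation amplitude of
    each phase fraction is ``(max - min)/2``; the noise floor is
    ``noise_mult * sqrt(p(1-p)/n)`` with ``p`` the window-mean fraction.
    Returns the right edge (s) of the first window where every phase is
    below the floor, or None if never.
    """
    if len(times) < 3:
        return None
    dt_rec = times[1] - times[0]
    w = max(3, int(round(cycle_time / dt_rec)))
    for k in range(w, len(times)):
        win = phase_fractions[k - w:k]
        amp = (win.max(axis=0) - win.min(axis=0)) / 2.0
        p = win.mean(axis=0)
        floor = noise_mult * np.sqrt(np.clip(p * (1 - p), 1e-12, None) / n_cells)
        if np.all(amp <= floor):
            return float(times[k])
    return None


def initialize_population(config: SimulationConfig,
                          rng: np.random.Generator,
                          max_days: float = 50.0) -> Population:
    """Grow a metabolically stationary, desynchronized seed population.

    Cells start as synchronized standard newborns and evolve under the fixed
    environment, constant-count protocol.  Small populations (< 10 cells)
    run for ``config.init_days``; larger ones run until the phase-fraction
    oscillations drop below the sampling noise floor, raising an error if
    that does not happen within ``max_days``.
    """
    config.validate()
    n = config.n_initial
    mp = config.metabolic
    pop = Population.standard_newborn(
        n, mp, config.environment.concentrations(),
        config.diffusion.free_volume_fraction,
        positions=_seed_positions(n, mp.radius_birth, rng))
    if n < 10:
        run_fixed_environment(pop, config, rng, config.init_days * 86400.0,
                              record_every=86400.0)
        return pop
    chunk = 5.0 * 86400.0
    all_times: list[np.ndarray] = []
    all_fr: list[np.ndarray] = []
    elapsed = 0.0
    while elapsed < max_days * 86400.0:
        rec = run_fixed_environment(pop, config, rng, chunk,
                                    record_every=3600.0)
        all_times.append(rec["times"] + elapsed)
        all_fr.append(rec["phase_fractions"])
        elapsed += chunk
        t_desync = desynchronization_time(
            np.concatenate(all_times), np.vstack(all_fr), n)
        if t_desync is not None:
            logger.info("initialization: desynchronized after %.1f days",
                        t_desync / 86400.0)
            return pop
    raise RuntimeError(
        f"population failed to desynchronize within {max_days} simulated days")


def _seed_positions(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Loose ball of seed positions (spacing ~ 2 cell radii)."""
    if n == 1:
        return np.zeros((1, 3))
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    r = 2.0 * radius * (n ** (1 / 3)) * rng.random(n) ** (1 / 3)
    return pts * r[:, None]


# ---------------------------------------------------------------------------
# Main loop


def _network_builder(pop: Population, seed: int):
    # mechanics sub-steps only need the adjacency, not the alpha shape
    def build() -> ContactNetwork:
        return build_contact_network(pop.position, pop.radius, seed=seed,
                                     compute_surface=False)
    return build


def simulation_step(state: SimulationState, config: SimulationConfig) -> SimulationState:
    """One pass of the program loop (biochemistry, mechanics, events,
    geometry, statistics bookkeeping)."""
    pop = state.pop
    dt = config.dt
    any_alive = bool(pop.alive.any())

    # (1) metabolism + transport + diffusion, then volume growth
    if len(pop):
        net = build_diffusion_network(pop, state.network, config.diffusion)
        system = ReactionDiffusionSystem(pop, net, config.environment,
                                         config.metabolic, config.diffusion)
        if state.solver is None:
            state.solver = NewtonSolver(system, config.solver)
        else:
            # reuse the solver (and its factorization cache) on new geometry
            state.solver.system = system
            if state.solver._lu_size != system.gsv.size:
                state.solver._lu = None
            state.solver.note_step()
        x_now = system.gsv.pack(pop, state.env_masses)
        x_next = state.solver.solve_step(x_now, dt, config.solver.rel_tol)
        state.env_masses = system.gsv.write_back(x_next, pop).copy()
        update_live_volumes(pop, config.metabolic)
        shrink_dead_population(pop, dt, config.forces)

    # (2) mechanics sub-steps (decoupled from the biochemical update)
    if any_alive or len(pop) > 1:
        state.network = relax_mechanics(
            pop, _network_builder(pop, config.seed), dt, config.forces)

    # (3) cellular events: deaths first, then mitoses, in cell order
    mitosis_due, died = advance_population_events(
        pop, config.metabolic, config.diffusion.free_volume_fraction,
        dt, state.rng, allow_death=True)
    if np.any(died):
        pop.time_of_death[died] = state.time + dt
        state.n_deaths += int(died.sum())
    n_div = perform_divisions(pop, mitosis_due, state.rng, config.metabolic)
    state.n_divisions += n_div

    # (4) geometry and topology refresh
    state.network = build_contact_network(pop.position, pop.radius,
                                          seed=config.seed)

    state.time += dt
    state.step += 1
    return state


def new_state(pop: Population, config: SimulationConfig,
              rng: np.random.Generator) -> SimulationState:
    network = build_contact_network(pop.position, pop.radius, seed=config.seed)
    env_masses = np.asarray(config.environment.concentrations()) \
        * config.environment.volume
    return SimulationState(pop=pop, time=0.0, step=0, env_masses=env_masses,
                           network=network, rng=rng)


def run(config: SimulationConfig,
        pop: Population | None = None,
        progress: bool = False) -> tuple[list["analysis_io.SnapshotRecord"], str]:
    """Full simulation: initialization, loop, termination.

    Returns the snapshot trajectory and the stop condition
    (:data:`STOP_MAX_STEPS` or :data:`STOP_ALL_DEAD`).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if pop is None:
        pop = initialize_population(config, rng)
    state = new_state(pop, config, rng)
    snapshots = [analysis_io.snapshot_from_state(state, config)]
    stop = STOP_MAX_STEPS
    for k in range(config.max_steps):
        state = simulation_step(state, config)
        if (state.step % config.snapshot_every == 0
                or state.step == config.max_steps):
            snapshots.append(analysis_io.snapshot_from_state(state, config))
        if progress and state.step % 50 == 0:
            alive = int(state.pop.alive.sum())
            logger.info("step %d t=%.2f d N=%d (alive %d)", state.step,
                        state.time / 86400.0, len(state.pop), alive)
        if not state.pop.alive.any():
            stop = STOP_ALL_DEAD
            if snapshots[-1].time != state.time:
                snapshots.append(analysis_io.snapshot_from_state(state, config))
            break
    if snapshots[-1].time != state.time:
        snapshots.append(analysis_io.snapshot_from_state(state, config))
    return snapshots, stop
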