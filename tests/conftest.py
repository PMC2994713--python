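import math

import numpy as np
import pandas as pd
import pytest

from spherosim.analysis_io import SnapshotRecord, CELL_COLUMNS
from spherosim.metabolism import CellState, Phase, Population
from spherosim.params import SimulationConfig


@pytest.fixture
def config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture
def params(config):
    return config.metabolic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_cell(params, phase=Phase.G1M, radius=None, **overrides) -> CellState:
    """A standard newborn cell record, optionally overridden per-field."""
    r = params.radius_birth if radius is None else radius
    v = 4.0 / 3.0 * math.pi * r**3
    fields = dict(
        id=0, position=np.zeros(3), velocity=np.zeros(3), radius=r,
        phase=phase, age_in_phase=0.0,
        G_in=0.3 * v, G6P=0.15 * v, store=0.1 * v, A_in=0.1 * v,
        AL_in=0.05 * v, O2_in=5.8e-3 * v, ATPp=1.5 * v,
        protein=params.protein_ref, DNA=0.0, mtDNA=float(params.n_mito_ref),
        n_mito=params.n_mito_ref, cyclinE=0.0, cyclinB=0.0,
    )
    fields.update(overrides)
    return CellState(**fields)


def make_population(config, positions, phases=None) -> Population:
    positions = np.asarray(positions, dtype=float)
    pop = Population.standard_newborn(
        len(positions), config.metabolic,
        config.environment.concentrations(),
        config.diffusion.free_volume_fraction,
        positions=positions)
    if phases is not None:
        pop.phase[:] = [int(p) for p in phases]
    return pop


def synthetic_snapshot(positions_um, radii_um=6.0, alive=None, velocities=None,
                       ext_lactate_conc=0.0, ext_o2_conc=6.4e-3,
                       phases=None, time=0.0) -> SnapshotRecord:
    """Hand-built snapshot for testing the observables (synthetic fixture)."""
    pts = np.asarray(positions_um, dtype=float)
    n = len(pts)
    radii = np.broadcast_to(np.asarray(radii_um, dtype=float), (n,))
    alive = np.ones(n, dtype=bool) if alive is None else np.asarray(alive, bool)
    v = np.zeros((n, 3)) if velocities is None else np.asarray(velocities, float)
    vol = 4.0 / 3.0 * math.pi * (radii * 1e-6) ** 3
    vfree = 0.15 * vol
    al = np.broadcast_to(np.asarray(ext_lactate_conc, float), (n,)) * vfree
    o2 = np.broadcast_to(np.asarray(ext_o2_conc, float), (n,)) * vfree
    phases = (["G1M" if a else "DEAD" for a in alive]
              if phases is None else list(phases))
    df = pd.DataFrame({
        "id": np.arange(n), "x_um": pts[:, 0], "y_um": pts[:, 1],
        "z_um": pts[:, 2],
        "vx_m_s": v[:, 0], "vy_m_s": v[:, 1], "vz_m_s": v[:, 2],
        "radius_um": radii, "phase": phases,
        "age_in_phase_s": np.zeros(n), "alive": alive,
        "n_mito": np.full(n, 100), "time_of_death_s": np.full(n, np.nan),
        "radius_at_death_um": np.full(n, np.nan),
        "m_glucose_in_kg": 0.3 * vol, "m_g6p_kg": 0.15 * vol,
        "m_store_kg": 0.1 * vol, "m_glutamine_in_kg": 0.1 * vol,
        "m_lactate_in_kg": 0.05 * vol, "m_o2_in_kg": 5.8e-3 * vol,
        "m_atp_kg": 1.5 * vol, "m_protein_kg": np.full(n, 1e-13),
        "dna_fraction": np.zeros(n), "mtdna_units": np.full(n, 100.0),
        "cyclin_e": np.zeros(n), "cyclin_b": np.zeros(n),
        "m_o2_ext_kg": o2, "m_glucose_ext_kg": 2.7 * vfree,
        "m_glutamine_ext_kg": 0.3 * vfree, "m_lactate_ext_kg": al,
    })[CELL_COLUMNS]
    return SnapshotRecord(
        time=time, cells=df,
        env_concentrations=np.array([6.4e-3, 2.7, 0.3, 0.0]),
        env_volume=1e-7, env_mode="fixed",
        summary={"step": 0, "n_live": int(alive.sum()),
                 "n_dead": int(n - alive.sum()),
                 "total_volume_m3": float(vol.sum()),
                 "centroid_um": pts.mean(axis=0).tolist(),
                 "n_divisions": 0, "n_deaths": 0},
        seed=0)
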