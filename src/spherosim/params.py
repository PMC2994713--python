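"""Model parameters and simulation configuration.

All quantities are SI internally (kg, m, s); concentrations are kg/m^3.
Micrometers and mmHg appear only at I/O boundaries (snapshots, profiles),
with oxygen concentration converted to partial pressure through Henry's law.

The defaults below constitute one concrete, versioned instantiation of the
single-cell metabolic network and of the biomechanical force law; they are
mirrored in ``data/default_params.yaml`` (schema_version 1), which can be
edited and passed back through :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

PARAMS_SCHEMA_VERSION = 1

#: Henry-law solubility of O2 in aqueous medium, kg m^-3 per mmHg
#: (1.3 uM/mmHg * 32 g/mol).
O2_SOLUBILITY_KG_M3_PER_MMHG = 4.16e-5


def po2_from_concentration(c_o2: float) -> float:
    """Convert an O2 concentration (kg/m^3) to partial pressure (mmHg)."""
    return c_o2 / O2_SOLUBILITY_KG_M3_PER_MMHG


def concentration_from_po2(po2_mmhg: float) -> float:
    """Convert an O2 partial pressure (mmHg) to concentration (kg/m^3)."""
    return po2_mmhg * O2_SOLUBILITY_KG_M3_PER_MMHG


@dataclass
class MetabolicParams:
    """Rate constants of the single-cell metabolic / cell-cycle automaton.

    Transport steps are Michaelis–Menten carriers (glucose, glutamine,
    lactate) or passive permeation (oxygen).  Biosynthesis of protein,
    nuclear DNA and mitochondrial DNA follows double-substrate
    Michaelis–Menten kinetics in (glutamine, ATP).  The oxygen sensor is a
    Hill switch between fermentative and oxidative ATP yield; the ATP
    sensor is a threshold gate on the G1 energetic checkpoint.
    """

    # --- membrane transport -------------------------------------------------
    perm_o2: float = 3.0e-6            # m/s, passive O2 permeability
    vmax_glucose: float = 2.9e-8       # kg m^-2 s^-1, GLUT carrier
    km_glucose: float = 1.5            # kg/m^3 (~8 mM)
    vmax_glutamine: float = 1.2e-8     # kg m^-2 s^-1
    km_glutamine: float = 0.3          # kg/m^3 (~2 mM)
    vmax_lactate: float = 2.8e-8      # kg m^-2 s^-1, MCT carrier
    km_lactate: float = 1.0            # kg/m^3 (~11 mM)
    # logistic pH sensitivity of the three carriers: Vmax_eff = Vmax * f(pH),
    # f(pH) = 1 / (1 + exp(-(pH - ph_half)/ph_width))
    ph_half_carrier: float = 6.2
    ph_width_carrier: float = 0.35

    # --- glycolysis / storage ----------------------------------------------
    v_hexokinase: float = 2.0e-2       # kg m^-3 s^-1 (per cell volume)
    km_hexokinase: float = 0.5         # kg/m^3, intracellular glucose
    v_glycolysis: float = 1.9e-2       # kg m^-3 s^-1, G6P consumption
    km_glycolysis: float = 0.25        # kg/m^3, G6P
    v_store: float = 1.4e-3            # kg m^-3 s^-1, glycogen deposition
    km_store: float = 0.25             # kg/m^3, G6P
    store_inhibition: float = 2.0      # kg/m^3, glycogen conc. damping deposition
    v_release: float = 5.0e-5          # s^-1, glycogen mobilization rate
    km_release_inhibition: float = 0.05  # kg/m^3, G6P conc. suppressing release

    # --- oxygen sensor (fermentative vs oxidative switch) -------------------
    k_o2_sensor: float = 1.0e-4        # kg/m^3 (~2.4 mmHg) half-switch
    hill_o2_sensor: float = 3.0
    # Warburg shift: even at full oxygenation at most this fraction of the
    # glycolytic flux is oxidized; the rest ferments to lactate
    ox_fraction_max: float = 0.15

    # --- glutamine oxidation -----------------------------------------------
    v_glutaminolysis: float = 7.2e-4   # kg m^-3 s^-1
    km_glutaminolysis: float = 0.15    # kg/m^3

    # --- stoichiometric / yield coefficients (mass based) --------------------
    y_lactate_per_glucose: float = 0.9   # kg lactate per kg glucose fermented
    y_o2_per_glucose: float = 1.07       # kg O2 per kg glucose oxidized
    y_o2_per_glutamine: float = 0.9      # kg O2 per kg glutamine oxidized
    atp_yield_ferm: float = 0.167        # kg ATP-pool per kg glucose, fermentative
    atp_yield_ox: float = 1.4            # kg ATP-pool per kg glucose, oxidative
    atp_yield_glutamine: float = 3.0     # kg ATP-pool per kg glutamine, oxidative
    atp_turnover_time: float = 600.0     # s, maintenance turnover of the ATP pool
    atp_cost_protein: float = 0.3        # kg ATP per kg protein synthesized
    n_mito_ref: int = 100                # mitochondria of a standard newborn cell

    # --- biosynthesis (double-substrate MM in glutamine, ATP) ----------------
    v_protein: float = 7.3e-3          # kg m^-3 s^-1
    km_protein_gln: float = 0.15       # kg/m^3
    km_protein_atp: float = 0.5        # kg/m^3
    y_gln_per_protein: float = 0.5     # kg glutamine consumed per kg protein
    protein_degradation: float = 1.0e-6  # s^-1
    v_dna: float = 1.35e-4              # genome fraction s^-1 at saturation
    km_dna_gln: float = 0.15
    km_dna_atp: float = 0.5
    v_mito: float = 3.2e-5             # s^-1 per mitochondrion at saturation
    km_mito_gln: float = 0.15
    km_mito_atp: float = 0.5

    # --- cell-cycle checkpoints ----------------------------------------------
    v_cyclin_e: float = 1.15e-4         # a.u. s^-1 at ATP saturation (G1m)
    km_cyclin_e_atp: float = 1.0       # kg/m^3
    theta_cyclin_e: float = 1.0        # a.u., G1m exit threshold
    v_cyclin_b: float = 1.54e-4        # a.u. s^-1 at ATP saturation (G2)
    km_cyclin_b_atp: float = 1.0
    theta_cyclin_b: float = 1.0
    cyclin_decay: float = 1.0e-4       # s^-1 outside the accumulating phase
    atp_checkpoint: float = 0.9        # kg/m^3, energetic checkpoint gate (G1m)
    g1_size_factor: float = 1.3        # G1m exit also needs protein >= factor * protein_ref
    checkpoint_exit_rate_g1m: float = 2.78e-4  # s^-1 (mean stochastic delay 1 h)
    checkpoint_exit_rate_g2: float = 3.70e-4   # s^-1 (mean stochastic delay 45 min)
    t_g1p: float = 10800.0              # s, nutrient-insensitive G1 subphase
    t_m: float = 3600.0                # s, mitosis duration

    # --- death ----------------------------------------------------------------
    lambda0_death: float = 1.0e-4      # s^-1, cytotoxicity rate at the lactate scale
    lactate_death_threshold: float = 0.9  # kg/m^3 (~10 mM) tolerated tissue lactate
    lactate_death_scale: float = 1.8   # kg/m^3 (~20 mM)
    atp_starvation: float = 0.15       # kg/m^3, certain death below this ATP conc.

    # --- mitosis ----------------------------------------------------------------
    daughter_separation_frac: float = 0.4   # center distance / mother radius
    volume_split_sd: float = 0.05
    volume_split_bounds: tuple[float, float] = (0.35, 0.65)

    # --- volume map -------------------------------------------------------------
    # V = v_birth * (w_protein * protein/protein_ref + w_mito * n_mito/n_mito_ref)
    radius_birth: float = 5.0e-6       # m
    protein_ref: float = 1.0e-13       # kg, protein mass of a standard newborn cell
    w_protein: float = 0.7
    w_mito: float = 0.3


@dataclass
class DiffusionParams:
    """Extracellular compartments and the Delaunay diffusion network."""

    free_volume_fraction: float = 0.15   # extracellular free volume / cell volume
    # effective diffusion coefficients in the spheroid interstitium, m^2/s
    d_o2: float = 2.0e-9
    d_glucose: float = 1.3e-10
    d_glutamine: float = 1.3e-10
    d_lactate: float = 2.0e-10
    link_cutoff_mult: float = 1.4        # g_ab = 0 beyond this multiple of r_a+r_b
    env_link_scale: float = 0.5          # surface-cell to environment conductance scale
    # phenomenological pH map: pH = ph0 - ph_drop_max * c_AL/(c_AL + k_ph)
    ph0: float = 7.4
    ph_drop_max: float = 2.0
    k_ph: float = 2.0                    # kg/m^3 lactate


@dataclass
class ForceLawParams:
    """Pairwise viscoelastic interaction and overdamped motion."""

    hertz_prefactor: float = 1333.0      # N m^-2: F = k * sqrt(R*) * delta^{3/2}
    f_saturation: float = 1.0e-8         # N, cap on the repulsive branch
    adhesion_peak: float = 2.0e-10       # N, maximum attractive force
    detachment_mult: float = 1.2         # detachment distance / (r_a + r_b)
    viscosity_eff: float = 500.0         # Pa s, drag gamma = 6*pi*eta*r
    shrink_rate: float = 5.8e-6          # s^-1, dead-cell radius decay
    residual_radius_fraction: float = 0.5
    dt_mech_max: float = 25.0            # s, mechanics sub-step cap
    max_substeps: int = 40


@dataclass
class SolverParams:
    """Implicit-Euler/Newton settings for the stiff biochemical solve."""

    rel_tol: float = 0.01
    max_newton_iter: int = 40
    jacobian_refresh_every: int = 10     # steps between Jacobian refactorizations
    max_step_halvings: int = 4
    fd_eps: float = 1.0e-6               # relative finite-difference perturbation


@dataclass
class Environment:
    """External nourishing medium.

    ``fixed`` mode pins the concentrations (used during initialization);
    ``evolving`` mode gives the environment a finite volume whose species
    masses change through exchange with surface cells.
    """

    c_o2: float = 6.4e-3        # kg/m^3 (~154 mmHg)
    c_glucose: float = 2.7      # kg/m^3 (15 mM)
    c_glutamine: float = 0.3    # kg/m^3 (~2 mM)
    c_lactate: float = 0.0
    volume: float = 1.0e-7      # m^3 (0.1 mL of medium)
    mode: str = "evolving"      # "fixed" | "evolving"

    def concentrations(self) -> list[float]:
        return [self.c_o2, self.c_glucose, self.c_glutamine, self.c_lactate]


@dataclass
class SimulationConfig:
    """Everything needed to reproduce a run."""

    metabolic: MetabolicParams = field(default_factory=MetabolicParams)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    forces: ForceLawParams = field(default_factory=ForceLawParams)
    solver: SolverParams = field(default_factory=SolverParams)
    environment: Environment = field(default_factory=Environment)
    dt: float = 50.0                  # s, biochemical macro time step
    seed: int = 0
    n_initial: int = 1
    max_steps: int = 1000
    snapshot_every: int = 100
    init_days: float = 5.0            # free-growth warm-up of the seed population
    output_dir: str = "out"

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.solver.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.environment.mode not in ("fixed", "evolving"):
            raise ValueError(f"unknown environment mode {self.environment.mode!r}")


# --------------------------------------------------------------------------
# YAML round trip

_SECTIONS = {
    "metabolic": MetabolicParams,
    "diffusion": DiffusionParams,
    "forces": ForceLawParams,
    "solver": SolverParams,
    "environment": Environment,
}


def config_to_dict(config: SimulationConfig) -> dict:
    out: dict = {"schema_version": PARAMS_SCHEMA_VERSION}
    for name in _SECTIONS:
        section = dataclasses.asdict(getattr(config, name))
        for k, v in section.items():
            if isinstance(v, tuple):
                section[k] = list(v)
        out[name] = section
    for f in dataclasses.fields(SimulationConfig):
        if f.name not in _SECTIONS:
            out[f.name] = getattr(config, f.name)
    return out


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    version = data.pop("schema_version", PARAMS_SCHEMA_VERSION)
    if version != PARAMS_SCHEMA_VERSION:
        raise ValueError(
            f"parameter schema version {version} not supported "
            f"(expected {PARAMS_SCHEMA_VERSION})"
        )
    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        section = dict(data.pop(name, {}))
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section) - valid
        if unknown:
            raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
        if "volume_split_bounds" in section:
            section["volume_split_bounds"] = tuple(section["volume_split_bounds"])
        kwargs[name] = cls(**section)
    valid_top = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - valid_top
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs.update(data)
    config = SimulationConfig(**kwargs)
    config.validate()
    return config


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def default_params_path() -> Path:
    return Path(__file__).parent / "data" / "default_params.yaml"
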