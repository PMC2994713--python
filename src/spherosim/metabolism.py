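"""Single-cell metabolic / cell-cycle automaton.

Each cell is a partly stochastic automaton with a minimal metabolic network:
glucose, glutamine and lactate cross the membrane through saturable,
pH-sensitive carriers, oxygen by passive permeation; glucose-6-phosphate
branches into glycolysis and a glycogen store; an oxygen-sensing Hill switch
partitions glycolytic flux between fermentation (lactate production, low ATP
yield) and oxidative phosphorylation (high ATP yield, scaled by the number of
mitochondria); protein, nuclear DNA and mitochondrial DNA are synthesized by
double-substrate Michaelis-Menten kinetics in (glutamine, ATP).  The cell
cycle is G1m -> G1p -> S -> G2 -> M with an energetic checkpoint between the
two G1 subphases; death occurs either through Poissonian lactate cytotoxicity
or deterministically by ATP starvation.

The module exposes both a per-cell record (:class:`CellState`) and a
vectorized population container (:class:`Population`) on which the simulation
engine operates.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .params import MetabolicParams

# ---------------------------------------------------------------------------
# Species layout.
# Intracellular columns of Population.X:
IG, IG6P, ISTORE, IA, IAL, IO2, IATP, IPROT, IDNA, IMT, ICE, ICB = range(12)
N_INTRACELLULAR = 12
# Extracellular columns of Population.E (masses in the cell's free volume):
EO2, EG, EA, EAL = range(4)
N_EXTRACELLULAR = 4

SPECIES_NAMES = ("O2", "glucose", "glutamine", "lactate")

INTRACELLULAR_NAMES = (
    "G_in", "G6P", "store", "A_in", "AL_in", "O2_in",
    "ATPp", "protein", "DNA", "mtDNA", "cyclinE", "cyclinB",
)


class Phase(enum.IntEnum):
    G1M = 0
    G1P = 1
    S = 2
    G2 = 3
    M = 4
    DEAD = 5


LIVE_PHASES = (Phase.G1M, Phase.G1P, Phase.S, Phase.G2, Phase.M)


class CellEvent(enum.Enum):
    NONE = "none"
    MITOSIS_DUE = "mitosis_due"
    DIED = "died"


@dataclass
class CellState:
    """Full per-cell record (masses in kg, lengths in m, times in s)."""

    id: int
    position: np.ndarray
    velocity: np.ndarray
    radius: float
    phase: Phase
    age_in_phase: float
    G_in: float
    G6P: float
    store: float
    A_in: float
    AL_in: float
    O2_in: float
    ATPp: float
    protein: float
    DNA: float
    mtDNA: float
    n_mito: int
    cyclinE: float
    cyclinB: float
    time_of_death: float | None = None

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3

    @property
    def alive(self) -> bool:
        return self.phase != Phase.DEAD


# ---------------------------------------------------------------------------
# Elementary rate laws


def michaelis_menten(c: float | np.ndarray, km: float) -> float | np.ndarray:
    return c / (km + c)


def synthesis_rate_double_mm(s1, s2, vmax, k1, k2):
    """Double-substrate Michaelis-Menten rate vmax*s1*s2/((k1+s1)(k2+s2)).

    Used for protein, nuclear DNA and mitochondrial DNA synthesis with
    (glutamine, ATP) as the two substrates.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if np.any(s1 < 0) or np.any(s2 < 0):
        raise ValueError("substrate concentrations must be non-negative")
    if k1 <= 0 or k2 <= 0:
        raise ValueError("Michaelis constants must be positive")
    out = vmax * s1 * s2 / ((k1 + s1) * (k2 + s2))
    return float(out) if out.ndim == 0 else out


def carrier_ph_factor(ph_out, params: MetabolicParams):
    """Smooth logistic modulation of carrier Vmax by extracellular pH."""
    return 1.0 / (1.0 + np.exp(-(ph_out - params.ph_half_carrier) / params.ph_width_carrier))


def membrane_transport_flux(
    species: str,
    c_out: float,
    c_in: float,
    ph_out: float,
    params: MetabolicParams,
    area: float = 1.0,
) -> float:
    """Signed trans-membrane mass flux (kg/s), positive into the cell.

    Oxygen permeates passively (flux linear in the concentration
    difference); glucose, glutamine and lactate use facilitated carriers:
    ``Vmax_eff(pH) * [c_out/(Km+c_out) - c_in/(Km+c_in)]``, with
    ``Vmax_eff`` a smooth monotone (logistic) function of extracellular pH.

    ``area`` is the membrane area (m^2); with the default area of 1 the
    returned value is a flux density.
    """
    if c_out < 0 or c_in < 0:
        raise ValueError("concentrations must be non-negative")
    if not (5.5 < ph_out < 8.0):
        raise ValueError(f"extracellular pH {ph_out} outside the model's (5.5, 8) range")
    if species == "O2":
        return params.perm_o2 * area * (c_out - c_in)
    try:
        vmax, km = {
            "glucose": (params.vmax_glucose, params.km_glucose),
            "glutamine": (params.vmax_glutamine, params.km_glutamine),
            "lactate": (params.vmax_lactate, params.km_lactate),
        }[species]
    except KeyError:
        raise ValueError(f"unknown species {species!r}") from None
    vmax_eff = vmax * carrier_ph_factor(ph_out, params)
    return float(vmax_eff * area * (c_out / (km + c_out) - c_in / (km + c_in)))


def death_probability(
    AL_local: float,
    ATPp: float,
    dt: float,
    params: MetabolicParams,
    volume: float | None = None,
) -> tuple[float, bool]:
    """Per-step death probability and ATP-starvation flag.

    The Poissonian cytotoxicity hazard rises linearly once the local
    (tissue) lactate concentration exceeds the tolerated threshold,
    ``lambda = lambda0 * max(AL - AL_thr, 0) / AL_scale``, giving
    ``p = 1 - exp(-lambda dt)``.  The flag is True when the ATP pool
    concentration falls below the starvation threshold (certain death).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if AL_local < 0:
        raise ValueError("lactate concentration must be non-negative")
    lam = params.lambda0_death * max(AL_local - params.lactate_death_threshold,
                                     0.0) / params.lactate_death_scale
    p = 1.0 - math.exp(-lam * dt)
    if volume is None:
        volume = 4.0 / 3.0 * math.pi * params.radius_birth**3
    starved = ATPp < params.atp_starvation * volume
    return p, starved


def volume_from_composition(protein, n_mito, params: MetabolicParams):
    """Monotone map from biosynthetic content to cell volume.

    ``V = V_birth * (w_p * protein/protein_ref + w_m * n_mito/n_mito_ref)``.
    The map is linear, so total volume is conserved exactly when protein and
    mitochondria are partitioned between daughters at mitosis.
    """
    v_birth = 4.0 / 3.0 * math.pi * params.radius_birth**3
    return v_birth * (
        params.w_protein * np.asarray(protein) / params.protein_ref
        + params.w_mito * np.asarray(n_mito) / params.n_mito_ref
    )


def radius_from_volume(volume):
    return (3.0 * np.asarray(volume) / (4.0 * math.pi)) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# Vectorized population container


@dataclass
class Population:
    """Struct-of-arrays container for all cells of a simulation.

    ``X`` holds the 12 continuously evolving intracellular variables (kg,
    except DNA = genome fraction, mtDNA = mitochondria units, cyclins in
    arbitrary concentration units); ``E`` the 4 extracellular masses (kg) in
    each cell's free volume.
    """

    ids: np.ndarray
    position: np.ndarray           # (N, 3) m
    velocity: np.ndarray           # (N, 3) m/s
    radius: np.ndarray             # (N,) m
    phase: np.ndarray              # (N,) int8, Phase values
    age_in_phase: np.ndarray       # (N,) s
    X: np.ndarray                  # (N, 12)
    E: np.ndarray                  # (N, 4)
    n_mito: np.ndarray             # (N,) int64
    time_of_death: np.ndarray      # (N,) s, NaN while alive
    radius_at_death: np.ndarray    # (N,) m, NaN while alive
    next_id: int = 0

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def alive(self) -> np.ndarray:
        return self.phase != int(Phase.DEAD)

    @property
    def volume(self) -> np.ndarray:
        return 4.0 / 3.0 * math.pi * self.radius**3

    def free_volume(self, free_fraction: float) -> np.ndarray:
        return free_fraction * self.volume

    # -- construction -------------------------------------------------------

    @classmethod
    def empty(cls) -> "Population":
        return cls(
            ids=np.zeros(0, dtype=np.int64),
            position=np.zeros((0, 3)),
            velocity=np.zeros((0, 3)),
            radius=np.zeros(0),
            phase=np.zeros(0, dtype=np.int8),
            age_in_phase=np.zeros(0),
            X=np.zeros((0, N_INTRACELLULAR)),
            E=np.zeros((0, N_EXTRACELLULAR)),
            n_mito=np.zeros(0, dtype=np.int64),
            time_of_death=np.zeros(0),
            radius_at_death=np.zeros(0),
        )

    @classmethod
    def standard_newborn(
        cls,
        n: int,
        params: MetabolicParams,
        env_conc: np.ndarray | list[float],
        free_fraction: float,
        positions: np.ndarray | None = None,
    ) -> "Population":
        """A population of n standard newborn cells at the start of G1m.

        Intracellular species start at approximate standard concentrations;
        extracellular compartments start in equilibrium with the environment.
        """
        v_birth = 4.0 / 3.0 * math.pi * params.radius_birth**3
        X = np.zeros((n, N_INTRACELLULAR))
        X[:, IG] = 0.3 * v_birth
        X[:, IG6P] = 0.15 * v_birth
        X[:, ISTORE] = 0.1 * v_birth
        X[:, IA] = 0.1 * v_birth
        X[:, IAL] = 0.05 * v_birth
        X[:, IO2] = 5.8e-3 * v_birth
        X[:, IATP] = 1.5 * v_birth
        X[:, IPROT] = params.protein_ref
        X[:, IMT] = float(params.n_mito_ref)
        env_conc = np.asarray(env_conc, dtype=float)
        E = np.outer(np.ones(n), env_conc) * (free_fraction * v_birth)
        if positions is None:
            positions = np.zeros((n, 3))
        return cls(
            ids=np.arange(n, dtype=np.int64),
            position=np.array(positions, dtype=float),
            velocity=np.zeros((n, 3)),
            radius=np.full(n, params.radius_birth),
            phase=np.zeros(n, dtype=np.int8),
            age_in_phase=np.zeros(n),
            X=X,
            E=E,
            n_mito=np.full(n, params.n_mito_ref, dtype=np.int64),
            time_of_death=np.full(n, np.nan),
            radius_at_death=np.full(n, np.nan),
            next_id=n,
        )

    # -- per-cell record interface ------------------------------------------

    def get_cell(self, i: int) -> CellState:
        return CellState(
            id=int(self.ids[i]),
            position=self.position[i].copy(),
            velocity=self.velocity[i].copy(),
            radius=float(self.radius[i]),
            phase=Phase(int(self.phase[i])),
            age_in_phase=float(self.age_in_phase[i]),
            G_in=float(self.X[i, IG]),
            G6P=float(self.X[i, IG6P]),
            store=float(self.X[i, ISTORE]),
            A_in=float(self.X[i, IA]),
            AL_in=float(self.X[i, IAL]),
            O2_in=float(self.X[i, IO2]),
            ATPp=float(self.X[i, IATP]),
            protein=float(self.X[i, IPROT]),
            DNA=float(self.X[i, IDNA]),
            mtDNA=float(self.X[i, IMT]),
            n_mito=int(self.n_mito[i]),
            cyclinE=float(self.X[i, ICE]),
            cyclinB=float(self.X[i, ICB]),
            time_of_death=(None if np.isnan(self.time_of_death[i])
                           else float(self.time_of_death[i])),
        )

    def set_cell(self, i: int, cell: CellState) -> None:
        self.ids[i] = cell.id
        self.position[i] = cell.position
        self.velocity[i] = cell.velocity
        self.radius[i] = cell.radius
        self.phase[i] = int(cell.phase)
        self.age_in_phase[i] = cell.age_in_phase
        self.X[i] = [cell.G_in, cell.G6P, cell.store, cell.A_in, cell.AL_in,
                     cell.O2_in, cell.ATPp, cell.protein, cell.DNA, cell.mtDNA,
                     cell.cyclinE, cell.cyclinB]
        self.n_mito[i] = cell.n_mito
        self.time_of_death[i] = (np.nan if cell.time_of_death is None
                                 else cell.time_of_death)

    def cells(self) -> list[CellState]:
        return [self.get_cell(i) for i in range(len(self))]


def _cell_to_arrays(cell: CellState, free_fraction: float,
                    ext_conc: np.ndarray) -> Population:
    pop = Population(
        ids=np.array([cell.id], dtype=np.int64),
        position=cell.position.reshape(1, 3).astype(float),
        velocity=cell.velocity.reshape(1, 3).astype(float),
        radius=np.array([cell.radius]),
        phase=np.array([int(cell.phase)], dtype=np.int8),
        age_in_phase=np.array([cell.age_in_phase]),
        X=np.array([[cell.G_in, cell.G6P, cell.store, cell.A_in, cell.AL_in,
                     cell.O2_in, cell.ATPp, cell.protein, cell.DNA, cell.mtDNA,
                     cell.cyclinE, cell.cyclinB]]),
        E=(np.asarray(ext_conc, dtype=float)
           * (free_fraction * cell.volume)).reshape(1, 4),
        n_mito=np.array([cell.n_mito], dtype=np.int64),
        time_of_death=np.array([np.nan if cell.time_of_death is None
                                else cell.time_of_death]),
        radius_at_death=np.array([np.nan]),
        next_id=cell.id + 1,
    )
    return pop


# ---------------------------------------------------------------------------
# Local (within-cell) right-hand side


def population_local_rhs(
    pop: Population,
    params: MetabolicParams,
    free_fraction: float,
    ph_out: np.ndarray,
    X: np.ndarray | None = None,
    E: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives of intracellular variables and of the extracellular
    masses from membrane exchange (diffusion between compartments is added
    separately by the network solver).

    Dead cells contribute exactly zero rows: their intracellular state is
    frozen and they neither consume nor release anything.
    """
    X = pop.X if X is None else X
    E = pop.E if E is None else E
    n = len(pop)
    dX = np.zeros((n, N_INTRACELLULAR))
    dE = np.zeros((n, N_EXTRACELLULAR))
    if n == 0:
        return dX, dE

    alive = pop.alive
    vol = pop.volume
    vfree = free_fraction * vol
    area = 4.0 * math.pi * pop.radius**2

    with np.errstate(invalid="ignore", divide="ignore"):
        ci = X / vol[:, None]          # intracellular concentrations
        co = E / vfree[:, None]        # extracellular concentrations
    ci = np.clip(ci, 0.0, None)
    co = np.clip(co, 0.0, None)

    fph = carrier_ph_factor(ph_out, params)

    # membrane fluxes, positive into the cell (kg/s)
    j_o2 = params.perm_o2 * area * (co[:, EO2] - ci[:, IO2])
    j_g = params.vmax_glucose * fph * area * (
        co[:, EG] / (params.km_glucose + co[:, EG])
        - ci[:, IG] / (params.km_glucose + ci[:, IG]))
    j_a = params.vmax_glutamine * fph * area * (
        co[:, EA] / (params.km_glutamine + co[:, EA])
        - ci[:, IA] / (params.km_glutamine + ci[:, IA]))
    j_al = params.vmax_lactate * fph * area * (
        co[:, EAL] / (params.km_lactate + co[:, EAL])
        - ci[:, IAL] / (params.km_lactate + ci[:, IAL]))

    # glycolysis and glycogen store
    r_hk = params.v_hexokinase * vol * michaelis_menten(ci[:, IG], params.km_hexokinase)
    r_gly = params.v_glycolysis * vol * michaelis_menten(ci[:, IG6P], params.km_glycolysis)
    r_sto = (params.v_store * vol
             * michaelis_menten(ci[:, IG6P], params.km_store)
             / (1.0 + ci[:, ISTORE] / params.store_inhibition))
    r_rel = (params.v_release * X[:, ISTORE].clip(0.0)
             * params.km_release_inhibition
             / (params.km_release_inhibition + ci[:, IG6P]))

    # oxygen sensor: fraction of glycolytic flux routed to oxidation
    h = ci[:, IO2] ** params.hill_o2_sensor / (
        ci[:, IO2] ** params.hill_o2_sensor + params.k_o2_sensor ** params.hill_o2_sensor)
    # Warburg shift: the oxidized fraction of glycolytic flux is capped
    # below 1 even at full oxygenation; the remainder always ferments
    route = params.ox_fraction_max * h

    # glutamine oxidation (requires oxygen)
    r_gx = params.v_glutaminolysis * vol * michaelis_menten(
        ci[:, IA], params.km_glutaminolysis) * h

    # biosynthesis, double-substrate MM in (glutamine, ATP)
    r_prot = vol * synthesis_rate_double_mm(
        ci[:, IA], ci[:, IATP], params.v_protein,
        params.km_protein_gln, params.km_protein_atp)
    in_s = pop.phase == int(Phase.S)
    r_dna = np.where(in_s & (X[:, IDNA] < 1.0), synthesis_rate_double_mm(
        ci[:, IA], ci[:, IATP], params.v_dna,
        params.km_dna_gln, params.km_dna_atp), 0.0)
    # mitochondria self-replicate: per-unit rate gated by (glutamine, ATP)
    r_mt = synthesis_rate_double_mm(
        ci[:, IA], ci[:, IATP], params.v_mito,
        params.km_mito_gln, params.km_mito_atp) * X[:, IMT].clip(0.0)

    # ATP pool: production switched by the oxygen sensor, oxidative part
    # scaled by the mitochondria density relative to a standard newborn
    # (count alone would let large cells inflate their pool concentration);
    # maintenance as first-order turnover.
    v_birth = 4.0 / 3.0 * math.pi * params.radius_birth**3
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = (pop.n_mito / params.n_mito_ref) * np.where(vol > 0, v_birth / vol, 0.0)
    atp_prod = (params.atp_yield_ferm * (1.0 - route)
                + params.atp_yield_ox * route * mu) * r_gly \
        + params.atp_yield_glutamine * h * mu * r_gx
    atp_cons = params.atp_cost_protein * r_prot + X[:, IATP].clip(0.0) / params.atp_turnover_time

    # cyclins (concentration units): accumulate in their phase, decay elsewhere
    in_g1m = pop.phase == int(Phase.G1M)
    in_g2 = pop.phase == int(Phase.G2)
    d_ce = np.where(
        in_g1m,
        params.v_cyclin_e * michaelis_menten(ci[:, IATP], params.km_cyclin_e_atp),
        -params.cyclin_decay * X[:, ICE])
    d_cb = np.where(
        in_g2,
        params.v_cyclin_b * michaelis_menten(ci[:, IATP], params.km_cyclin_b_atp),
        -params.cyclin_decay * X[:, ICB])

    dX[:, IG] = j_g - r_hk
    dX[:, IG6P] = r_hk - r_gly - r_sto + r_rel
    dX[:, ISTORE] = r_sto - r_rel
    dX[:, IA] = j_a - params.y_gln_per_protein * r_prot - r_gx
    dX[:, IAL] = params.y_lactate_per_glucose * (1.0 - route) * r_gly + j_al
    dX[:, IO2] = j_o2 - params.y_o2_per_glucose * route * r_gly \
        - params.y_o2_per_glutamine * r_gx
    dX[:, IATP] = atp_prod - atp_cons
    dX[:, IPROT] = r_prot - params.protein_degradation * X[:, IPROT].clip(0.0)
    dX[:, IDNA] = r_dna
    dX[:, IMT] = r_mt
    dX[:, ICE] = d_ce
    dX[:, ICB] = d_cb

    dE[:, EO2] = -j_o2
    dE[:, EG] = -j_g
    dE[:, EA] = -j_a
    dE[:, EAL] = -j_al

    dead = ~alive
    dX[dead] = 0.0
    dE[dead] = 0.0
    return dX, dE


def intracellular_rhs(cell: CellState, ext_conc, params: MetabolicParams,
                      free_fraction: float = 0.15,
                      ph_out: float | None = None) -> np.ndarray:
    """Derivative vector of the 12 intracellular species of a single cell.

    ``ext_conc`` is the [O2, glucose, glutamine, lactate] concentration
    vector (kg/m^3) in the cell's extracellular compartment.  Dead cells
    return the zero vector.
    """
    ext_conc = np.asarray(ext_conc, dtype=float)
    if np.any(np.isnan(ext_conc)):
        raise ValueError("NaN in extracellular concentrations")
    state = np.array([cell.G_in, cell.G6P, cell.store, cell.A_in, cell.AL_in,
                      cell.O2_in, cell.ATPp, cell.protein, cell.DNA, cell.mtDNA,
                      cell.cyclinE, cell.cyclinB])
    if np.any(np.isnan(state)):
        raise ValueError("NaN in intracellular state")
    if not cell.alive:
        return np.zeros(N_INTRACELLULAR)
    if ph_out is None:
        from .diffusion import ph_from_lactate  # local import; no cycle at call time
        ph_out = ph_from_lactate(float(ext_conc[EAL]))
    pop = _cell_to_arrays(cell, free_fraction, ext_conc)
    dX, _ = population_local_rhs(pop, params, free_fraction,
                                 np.array([ph_out]))
    return dX[0]


# ---------------------------------------------------------------------------
# Discrete cellular events


def advance_population_events(
    pop: Population,
    params: MetabolicParams,
    free_fraction: float,
    dt: float,
    rng: np.random.Generator,
    allow_death: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one step of stochastic cell-cycle / death events to all cells.

    Returns ``(mitosis_due, died)`` boolean masks.  Order of evaluation:
    deaths are sampled first (a cell that dies this step does not divide),
    then phase transitions; each checkpoint exit is a memoryless Bernoulli
    trial once its gate condition holds.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = len(pop)
    mitosis_due = np.zeros(n, dtype=bool)
    died = np.zeros(n, dtype=bool)
    if n == 0:
        return mitosis_due, died
    alive = pop.alive
    vol = pop.volume
    vfree = free_fraction * vol
    with np.errstate(invalid="ignore", divide="ignore"):
        # cytotoxicity senses the local tissue lactate: everything in the
        # cell's territory (cytoplasm + its extracellular space)
        c_al = np.where(vol > 0, (pop.X[:, IAL].clip(0.0)
                                  + pop.E[:, EAL].clip(0.0)) / (vol + vfree), 0.0)
        ci_atp = pop.X[:, IATP] / vol

    pop.age_in_phase[alive] += dt

    if allow_death:
        lam = params.lambda0_death * np.clip(
            c_al - params.lactate_death_threshold, 0.0, None) / params.lactate_death_scale
        p_death = 1.0 - np.exp(-lam * dt)
        u = rng.random(n)
        died = alive & ((u < p_death) | (ci_atp < params.atp_starvation))
    else:
        rng.random(n)  # keep the stream aligned regardless of the death switch

    # G1m -> G1p: energetic checkpoint (ATP gate + cyclin E threshold),
    # then memoryless exit.
    g1m = alive & ~died & (pop.phase == int(Phase.G1M))
    # energetic checkpoint (ATP gate + cyclin E) plus a protein sizer that
    # enforces size homeostasis across generations
    gate = (g1m & (ci_atp >= params.atp_checkpoint)
            & (pop.X[:, ICE] >= params.theta_cyclin_e)
            & (pop.X[:, IPROT] >= params.g1_size_factor * params.protein_ref))
    u = rng.random(n)
    go = gate & (u < 1.0 - np.exp(-params.checkpoint_exit_rate_g1m * dt))
    pop.phase[go] = int(Phase.G1P)
    pop.age_in_phase[go] = 0.0
    pop.X[go, ICE] = 0.0

    # G1p -> S: fixed-duration, nutrient-insensitive subphase.
    g1p = alive & ~died & (pop.phase == int(Phase.G1P))
    go = g1p & (pop.age_in_phase >= params.t_g1p)
    pop.phase[go] = int(Phase.S)
    pop.age_in_phase[go] = 0.0
    pop.X[go, IDNA] = np.clip(pop.X[go, IDNA], 0.0, None)

    # S -> G2: genome fully replicated (snap to exactly 1, so later
    # solver rounding cannot un-complete the genome).
    s = alive & ~died & (pop.phase == int(Phase.S))
    go = s & (pop.X[:, IDNA] >= 1.0 - 1e-9)
    pop.X[:, IDNA] = np.clip(pop.X[:, IDNA], 0.0, 1.0)
    pop.X[go, IDNA] = 1.0
    pop.phase[go] = int(Phase.G2)
    pop.age_in_phase[go] = 0.0

    # G2 -> M: cyclin B threshold, memoryless exit.
    g2 = alive & ~died & (pop.phase == int(Phase.G2))
    gate = g2 & (pop.X[:, ICB] >= params.theta_cyclin_b)
    u = rng.random(n)
    go = gate & (u < 1.0 - np.exp(-params.checkpoint_exit_rate_g2 * dt))
    pop.phase[go] = int(Phase.M)
    pop.age_in_phase[go] = 0.0
    pop.X[go, ICB] = 0.0

    # M completion raises the mitosis flag (division handled by the caller);
    # tolerance on DNA guards against linear-solver rounding
    m = alive & ~died & (pop.phase == int(Phase.M))
    mitosis_due = m & (pop.age_in_phase >= params.t_m) \
        & (pop.X[:, IDNA] >= 1.0 - 1e-6)

    # mitochondria count follows the continuous mtDNA variable
    live = alive & ~died
    pop.n_mito[live] = np.floor(pop.X[live, IMT]).astype(np.int64)

    if np.any(died):
        pop.phase[died] = int(Phase.DEAD)
        pop.radius_at_death[died] = pop.radius[died]
    return mitosis_due, died


def advance_cycle_phase(cell: CellState, dt: float, rng: np.random.Generator,
                        params: MetabolicParams,
                        ext_lactate_conc: float = 0.0,
                        free_fraction: float = 0.15,
                        allow_death: bool = True) -> tuple[CellState, CellEvent]:
    """Single-cell wrapper over the vectorized event kernel."""
    if not cell.alive:
        return cell, CellEvent.NONE
    ext = np.array([0.0, 0.0, 0.0, ext_lactate_conc])
    pop = _cell_to_arrays(cell, free_fraction, ext)
    mit, died = advance_population_events(pop, params, free_fraction, dt, rng,
                                          allow_death=allow_death)
    out = pop.get_cell(0)
    if died[0]:
        return out, CellEvent.DIED
    return out, CellEvent.MITOSIS_DUE if mit[0] else CellEvent.NONE


# ---------------------------------------------------------------------------
# Mitosis


def _split_population_row(pop: Population, i: int, params: MetabolicParams,
                          rng: np.random.Generator):
    """Partition the contents of cell i between two daughters.

    Returns (arrays for daughter 1, arrays for daughter 2) as dicts.
    Protein and every soluble species split with a truncated-Gaussian
    fraction; mitochondria are partitioned binomially (p = 1/2); the
    extracellular compartment splits with the same fraction as the solubles.
    """
    lo, hi = params.volume_split_bounds
    while True:
        f = rng.normal(0.5, params.volume_split_sd)
        if lo <= f <= hi:
            break
    n_m = int(pop.n_mito[i])
    n1 = int(rng.binomial(n_m, 0.5))
    mt = float(pop.X[i, IMT])
    mt_frac = mt - math.floor(mt)
    X = pop.X[i]
    X1 = X.copy()
    X2 = X.copy()
    soluble = [IG, IG6P, ISTORE, IA, IAL, IO2, IATP, IPROT]
    for j in soluble:
        X1[j] = f * X[j]
        X2[j] = (1.0 - f) * X[j]
    X1[IDNA] = 0.0
    X2[IDNA] = 0.0
    X1[IMT] = n1 + mt_frac * f
    X2[IMT] = (n_m - n1) + mt_frac * (1.0 - f)
    X1[ICE] = 0.0
    X2[ICE] = 0.0
    X1[ICB] = 0.0
    X2[ICB] = 0.0
    E1 = f * pop.E[i]
    E2 = (1.0 - f) * pop.E[i]

    # mitotic placement: inside the mother, separated by 0.4 R0 along a
    # uniformly random axis
    r0 = float(pop.radius[i])
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    sep = params.daughter_separation_frac * r0
    x1 = pop.position[i] + 0.5 * sep * axis
    x2 = pop.position[i] - 0.5 * sep * axis

    v1 = volume_from_composition(X1[IPROT], n1, params)
    v2 = volume_from_composition(X2[IPROT], n_m - n1, params)
    d1 = dict(X=X1, E=E1, n_mito=n1, position=x1, radius=float(radius_from_volume(v1)))
    d2 = dict(X=X2, E=E2, n_mito=n_m - n1, position=x2, radius=float(radius_from_volume(v2)))
    return d1, d2


def divide_cell(mother: CellState, rng: np.random.Generator,
                params: MetabolicParams,
                free_fraction: float = 0.15) -> tuple[CellState, CellState]:
    """Mitosis of a single cell.

    Requires the mother in M phase with the genome fully replicated.  Both
    daughters are reset to the start of G1m with DNA = 0; volume, the
    mitochondria count and every soluble species mass are conserved exactly.
    """
    if mother.phase != Phase.M:
        raise ValueError("mother cell must be in M phase to divide")
    if mother.DNA < 1.0 - 1e-6:
        raise ValueError("mother genome must be fully replicated (DNA = 1)")
    ext = np.zeros(4)
    pop = _cell_to_arrays(mother, free_fraction, ext)
    d1, d2 = _split_population_row(pop, 0, params, rng)

    def mk(d, new_id):
        return CellState(
            id=new_id,
            position=np.asarray(d["position"], dtype=float),
            velocity=mother.velocity.copy(),
            radius=d["radius"],
            phase=Phase.G1M,
            age_in_phase=0.0,
            G_in=d["X"][IG], G6P=d["X"][IG6P], store=d["X"][ISTORE],
            A_in=d["X"][IA], AL_in=d["X"][IAL], O2_in=d["X"][IO2],
            ATPp=d["X"][IATP], protein=d["X"][IPROT], DNA=0.0,
            mtDNA=d["X"][IMT], n_mito=int(d["n_mito"]),
            cyclinE=0.0, cyclinB=0.0,
        )

    return mk(d1, mother.id), mk(d2, mother.id + 1)


# ---------------------------------------------------------------------------
# Fixed-environment integrator (initialization, calibration, isolated cells)


def step_fixed_environment(
    pop: Population,
    params: MetabolicParams,
    env_conc: np.ndarray,
    ph_env: float,
    free_fraction: float,
    dt: float,
    n_substeps: int = 5,
) -> None:
    """Advance the intracellular ODEs of all cells over dt with the
    extracellular compartments pinned at the environment concentrations.

    Used during the initialization protocol, where cells grow freely in an
    environment held fixed and no spatial diffusion solve is needed.  The
    fast passive O2 exchange is integrated by exact exponential relaxation;
    the remaining (non-stiff) reactions use explicit sub-steps.
    """
    if len(pop) == 0:
        return
    env_conc = np.asarray(env_conc, dtype=float)
    vol = pop.volume
    vfree = free_fraction * vol
    pop.E[:] = np.outer(np.ones(len(pop)), env_conc) * vfree[:, None]
    ph = np.full(len(pop), ph_env)
    dt_s = dt / n_substeps
    area = 4.0 * math.pi * pop.radius**2
    k_o2 = params.perm_o2 * area / vol  # 1/s relaxation rate of O2_in
    decay = np.exp(-k_o2 * dt_s)
    alive = pop.alive
    for _ in range(n_substeps):
        dX, _ = population_local_rhs(pop, params, free_fraction, ph)
        # O2: semi-analytic — relax toward the quasi-steady level set by
        # exchange minus consumption (consumption frozen over the sub-step).
        ci_o2 = pop.X[:, IO2] / vol
        cons = params.perm_o2 * area * (env_conc[EO2] - ci_o2) - dX[:, IO2]
        target = (env_conc[EO2] - cons / (params.perm_o2 * area)) * vol
        o2_new = target + (pop.X[:, IO2] - target) * decay
        pop.X[:, :] += dt_s * dX
        pop.X[alive, IO2] = o2_new[alive]
        np.clip(pop.X[:, :IDNA + 1], 0.0, None, out=pop.X[:, :IDNA + 1])
        np.clip(pop.X[:, IDNA], 0.0, 1.0, out=pop.X[:, IDNA])
        pop.X[:, IMT] = np.clip(pop.X[:, IMT], 0.0, None)
        pop.X[:, ICE:] = np.clip(pop.X[:, ICE:], 0.0, None)


def update_live_volumes(pop: Population, params: MetabolicParams) -> None:
    """Refresh radius of live cells from the protein/mitochondria volume map."""
    live = pop.alive
    if not np.any(live):
        return
    v = volume_from_composition(pop.X[live, IPROT], pop.n_mito[live], params)
    pop.radius[live] = radius_from_volume(v)
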