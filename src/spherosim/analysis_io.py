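"""Snapshot serialization and derived observables.

Snapshots are self-contained (cells as CSV, metadata as JSON sidecar) and
every derived observable — radial profiles, rim/core histo-metrics, flow
fields, growth curves — is a pure function of a snapshot, recomputable
offline from the files alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diffusion import build_diffusion_network, ph_from_lactate
from .geometry import build_contact_network
from .metabolism import EAL, Phase, Population
from .params import (
    DiffusionParams, SimulationConfig, po2_from_concentration,
)

SNAPSHOT_SCHEMA_VERSION = 1

_PHASE_NAMES = {int(p): p.name for p in Phase}
_PHASE_FROM_NAME = {p.name: int(p) for p in Phase}

#: CSV column order (units in the name; masses kg, positions um, velocity m/s)
CELL_COLUMNS = [
    "id", "x_um", "y_um", "z_um", "vx_m_s", "vy_m_s", "vz_m_s",
    "radius_um", "phase", "age_in_phase_s", "alive", "n_mito",
    "time_of_death_s", "radius_at_death_um",
    "m_glucose_in_kg", "m_g6p_kg", "m_store_kg", "m_glutamine_in_kg",
    "m_lactate_in_kg", "m_o2_in_kg", "m_atp_kg", "m_protein_kg",
    "dna_fraction", "mtdna_units", "cyclin_e", "cyclin_b",
    "m_o2_ext_kg", "m_glucose_ext_kg", "m_glutamine_ext_kg", "m_lactate_ext_kg",
]


@dataclass
class SnapshotRecord:
    """Serializable state of the whole simulation at one time point."""

    time: float                      # s
    cells: pd.DataFrame              # one row per cell, CELL_COLUMNS
    env_concentrations: np.ndarray   # (4,) kg/m^3, order O2/glucose/glutamine/lactate
    env_volume: float
    env_mode: str
    summary: dict
    seed: int
    free_volume_fraction: float = 0.15
    diffusion_params: dict | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def snapshot_from_state(state, config: SimulationConfig) -> SnapshotRecord:
    pop: Population = state.pop
    n = len(pop)
    df = pd.DataFrame({
        "id": pop.ids,
        "x_um": pop.position[:, 0] * 1e6,
        "y_um": pop.position[:, 1] * 1e6,
        "z_um": pop.position[:, 2] * 1e6,
        "vx_m_s": pop.velocity[:, 0],
        "vy_m_s": pop.velocity[:, 1],
        "vz_m_s": pop.velocity[:, 2],
        "radius_um": pop.radius * 1e6,
        "phase": [_PHASE_NAMES[int(p)] for p in pop.phase],
        "age_in_phase_s": pop.age_in_phase,
        "alive": pop.alive,
        "n_mito": pop.n_mito,
        "time_of_death_s": pop.time_of_death,
        "radius_at_death_um": pop.radius_at_death * 1e6,
        "m_glucose_in_kg": pop.X[:, 0],
        "m_g6p_kg": pop.X[:, 1],
        "m_store_kg": pop.X[:, 2],
        "m_glutamine_in_kg": pop.X[:, 3],
        "m_lactate_in_kg": pop.X[:, 4],
        "m_o2_in_kg": pop.X[:, 5],
        "m_atp_kg": pop.X[:, 6],
        "m_protein_kg": pop.X[:, 7],
        "dna_fraction": pop.X[:, 8],
        "mtdna_units": pop.X[:, 9],
        "cyclin_e": pop.X[:, 10],
        "cyclin_b": pop.X[:, 11],
        "m_o2_ext_kg": pop.E[:, 0],
        "m_glucose_ext_kg": pop.E[:, 1],
        "m_glutamine_ext_kg": pop.E[:, 2],
        "m_lactate_ext_kg": pop.E[:, 3],
    })
    alive = pop.alive
    vol = pop.volume
    centroid = (pop.position.mean(axis=0) if n else np.zeros(3))
    summary = {
        "step": int(state.step),
        "n_live": int(alive.sum()),
        "n_dead": int(n - alive.sum()),
        "total_volume_m3": float(vol.sum()),
        "centroid_um": (centroid * 1e6).tolist(),
        "n_divisions": int(getattr(state, "n_divisions", 0)),
        "n_deaths": int(getattr(state, "n_deaths", 0)),
    }
    env_conc = np.asarray(state.env_masses, dtype=float) / config.environment.volume
    import dataclasses
    return SnapshotRecord(
        time=float(state.time), cells=df,
        env_concentrations=env_conc,
        env_volume=config.environment.volume,
        env_mode=config.environment.mode,
        summary=summary, seed=config.seed,
        free_volume_fraction=config.diffusion.free_volume_fraction,
        diffusion_params=dataclasses.asdict(config.diffusion),
    )


# ---------------------------------------------------------------------------
# Serialization


def write_snapshot(snapshot: SnapshotRecord, path: str | Path) -> None:
    """Write ``<path>.csv`` (cell table) and ``<path>.json`` (metadata)."""
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    snapshot.cells.to_csv(base.with_suffix(".csv"), index=False,
                          columns=CELL_COLUMNS)
    meta = {
        "schema_version": SNAPSHOT_SCHEMA_VERSION,
        "time_s": snapshot.time,
        "seed": snapshot.seed,
        "free_volume_fraction": snapshot.free_volume_fraction,
        "environment": {
            "concentrations_kg_m3": np.asarray(snapshot.env_concentrations).tolist(),
            "volume_m3": snapshot.env_volume,
            "mode": snapshot.env_mode,
        },
        "summary": snapshot.summary,
        "diffusion_params": snapshot.diffusion_params,
    }
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_snapshot(path: str | Path) -> SnapshotRecord:
    base = Path(path)
    with open(base.with_suffix(".json")) as fh:
        meta = json.load(fh)
    if meta.get("schema_version") != SNAPSHOT_SCHEMA_VERSION:
        raise ValueError(
            f"snapshot schema version {meta.get('schema_version')} "
            f"not supported (expected {SNAPSHOT_SCHEMA_VERSION})")
    cells = pd.read_csv(base.with_suffix(".csv"))
    env = meta["environment"]
    return SnapshotRecord(
        time=meta["time_s"], cells=cells,
        env_concentrations=np.asarray(env["concentrations_kg_m3"]),
        env_volume=env["volume_m3"], env_mode=env["mode"],
        summary=meta["summary"], seed=meta["seed"],
        free_volume_fraction=meta.get("free_volume_fraction", 0.15),
        diffusion_params=meta.get("diffusion_params"),
    )


def population_from_snapshot(snapshot: SnapshotRecord) -> Population:
    """Rebuild the vectorized population (to resume a run from a snapshot)."""
    df = snapshot.cells
    n = len(df)
    X = np.column_stack([
        df["m_glucose_in_kg"], df["m_g6p_kg"], df["m_store_kg"],
        df["m_glutamine_in_kg"], df["m_lactate_in_kg"], df["m_o2_in_kg"],
        df["m_atp_kg"], df["m_protein_kg"], df["dna_fraction"],
        df["mtdna_units"], df["cyclin_e"], df["cyclin_b"],
    ]) if n else np.zeros((0, 12))
    E = np.column_stack([
        df["m_o2_ext_kg"], df["m_glucose_ext_kg"],
        df["m_glutamine_ext_kg"], df["m_lactate_ext_kg"],
    ]) if n else np.zeros((0, 4))
    return Population(
        ids=df["id"].to_numpy(np.int64),
        position=np.column_stack([df["x_um"], df["y_um"], df["z_um"]]) * 1e-6,
        velocity=np.column_stack([df["vx_m_s"], df["vy_m_s"], df["vz_m_s"]]),
        radius=df["radius_um"].to_numpy(float) * 1e-6,
        phase=np.array([_PHASE_FROM_NAME[p] for p in df["phase"]], dtype=np.int8),
        age_in_phase=df["age_in_phase_s"].to_numpy(float),
        X=X, E=E,
        n_mito=df["n_mito"].to_numpy(np.int64),
        time_of_death=df["time_of_death_s"].to_numpy(float),
        radius_at_death=df["radius_at_death_um"].to_numpy(float) * 1e-6,
        next_id=int(df["id"].max()) + 1 if n else 0,
    )


def write_vtk(snapshot: SnapshotRecord, path: str | Path) -> None:
    """Legacy ASCII VTK polydata export (points + per-point arrays)."""
    df = snapshot.cells
    n = len(df)
    lines = [
        "# vtk DataFile Version 3.0",
        f"spherosim snapshot t={snapshot.time:.1f}s",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} float",
    ]
    for _, row in df.iterrows():
        lines.append(f"{row.x_um:.4f} {row.y_um:.4f} {row.z_um:.4f}")
    lines.append(f"POINT_DATA {n}")
    for name, col in [("radius_um", "radius_um"), ("alive", "alive"),
                      ("lactate_ext_kg", "m_lactate_ext_kg")]:
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{float(v):.6g}" for v in df[col])
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Derived per-cell quantities


def _dist_from_centroid_um(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    pts = df[["x_um", "y_um", "z_um"]].to_numpy(float)
    centroid = pts.mean(axis=0)
    return np.linalg.norm(pts - centroid, axis=1), centroid


def _free_volumes(snapshot: SnapshotRecord) -> np.ndarray:
    r = snapshot.cells["radius_um"].to_numpy(float) * 1e-6
    return snapshot.free_volume_fraction * 4.0 / 3.0 * math.pi * r**3


def _diffusion_params(snapshot: SnapshotRecord) -> DiffusionParams:
    if snapshot.diffusion_params:
        return DiffusionParams(**snapshot.diffusion_params)
    return DiffusionParams()


def cell_quantity(snapshot: SnapshotRecord, quantity: str) -> np.ndarray:
    """Resolve a named per-cell quantity for profiles and maps."""
    df = snapshot.cells
    vfree = _free_volumes(snapshot)
    r = df["radius_um"].to_numpy(float) * 1e-6
    vol = 4.0 / 3.0 * math.pi * r**3
    dp = _diffusion_params(snapshot)
    if quantity == "dead_fraction":
        return 1.0 - df["alive"].to_numpy(float)
    if quantity == "radial_velocity":
        dist, centroid = _dist_from_centroid_um(df)
        pts = df[["x_um", "y_um", "z_um"]].to_numpy(float) - centroid
        unit = np.where(dist[:, None] > 0, pts / np.maximum(dist, 1e-12)[:, None], 0.0)
        v = df[["vx_m_s", "vy_m_s", "vz_m_s"]].to_numpy(float)
        return (v * unit).sum(axis=1) * 3.6e9  # m/s -> um/h
    if quantity == "pO2_ext":
        return po2_from_concentration(df["m_o2_ext_kg"].to_numpy(float) / vfree)
    if quantity == "pH":
        # microenvironment pH from the local tissue lactate (cell +
        # extracellular space; dead cells keep their metabolite load)
        c_al = (df["m_lactate_in_kg"].to_numpy(float)
                + df["m_lactate_ext_kg"].to_numpy(float)) / (vol + vfree)
        return np.asarray(ph_from_lactate(c_al, dp))
    if quantity == "lactate_tissue":
        return (df["m_lactate_in_kg"].to_numpy(float)
                + df["m_lactate_ext_kg"].to_numpy(float)) / (vol + vfree)
    ext = {"o2_ext": "m_o2_ext_kg", "glucose_ext": "m_glucose_ext_kg",
           "glutamine_ext": "m_glutamine_ext_kg", "lactate_ext": "m_lactate_ext_kg"}
    if quantity in ext:
        return df[ext[quantity]].to_numpy(float) / vfree
    intra = {"glucose_in": "m_glucose_in_kg", "lactate_in": "m_lactate_in_kg",
             "atp": "m_atp_kg", "o2_in": "m_o2_in_kg",
             "glutamine_in": "m_glutamine_in_kg"}
    if quantity in intra:
        return df[intra[quantity]].to_numpy(float) / vol
    raise ValueError(f"unknown quantity {quantity!r}")


# ---------------------------------------------------------------------------
# Radial profiles


@dataclass
class RadialProfile:
    bin_centers: np.ndarray    # um from the centroid
    mean: np.ndarray           # per-bin average (NaN where the bin is empty)
    count: np.ndarray          # cells per bin


def radial_profile(snapshot: SnapshotRecord, quantity: str,
                   n_bins: int = 30) -> RadialProfile:
    """Per-bin average of a named quantity vs. distance from the centroid."""
    if snapshot.n_cells == 0:
        raise ValueError("snapshot has no cells")
    values = cell_quantity(snapshot, quantity)
    dist, _ = _dist_from_centroid_um(snapshot.cells)
    r_max = max(dist.max(), 1e-9)
    edges = np.linspace(0.0, r_max * (1 + 1e-9), n_bins + 1)
    idx = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    count = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, sums / np.maximum(count, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(bin_centers=centers, mean=mean, count=count)


# ---------------------------------------------------------------------------
# Rim / core metrics


def rim_core_metrics(snapshot: SnapshotRecord,
                     central_radius_um: float = 50.0,
                     hypoxia_po2_mmhg: float = 5.0,
                     alive_threshold: float = 0.05,
                     surface_percentile: float = 97.5,
                     n_bins: int = 30) -> dict:
    """Histo-metric summary of a mature spheroid snapshot.

    Definitions: the spheroid surface radius is the sphere enclosing
    ``surface_percentile`` % of cell centers; the viable rim thickness is the
    distance between the surface and the innermost shell where only 5 % of
    the cells are still alive; central pO2 and pH are averaged over a sphere
    of ``central_radius_um`` about the centroid; delta pH is the difference
    between the environmental pH and the pH 200 um below the surface; the
    hypoxic rim is the distance between the viable-rim inner edge and the
    shell where pO2 first drops below the hypoxia threshold (the necrotic
    core radius is reported alongside as the alternative definition); the
    cycle census maps {G1m, G1p} -> G0/G1, S -> S, {G2, M} -> G2/M over live
    cells.
    """
    df = snapshot.cells
    if len(df) == 0:
        raise ValueError("snapshot has no cells")
    dist, _ = _dist_from_centroid_um(df)
    r_surface = float(np.percentile(dist, surface_percentile))
    alive = df["alive"].to_numpy(bool)

    edges = np.linspace(0.0, max(dist.max(), 1e-9) * (1 + 1e-9), n_bins + 1)
    idx = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    count = np.bincount(idx, minlength=n_bins)
    n_alive = np.bincount(idx, weights=alive.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        alive_frac = np.where(count > 0, n_alive / np.maximum(count, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])

    necrotic = np.nonzero((count > 0) & (alive_frac <= alive_threshold))[0]
    if len(necrotic):
        r_core = float(edges[necrotic.max() + 1])  # outer edge of the 5% shell
    else:
        r_core = 0.0
    viable_rim = max(r_surface - r_core, 0.0)

    po2 = cell_quantity(snapshot, "pO2_ext")
    po2_sum = np.bincount(idx, weights=po2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        po2_prof = np.where(count > 0, po2_sum / np.maximum(count, 1), np.nan)
    hypoxic = np.nonzero((count > 0) & (po2_prof <= hypoxia_po2_mmhg))[0]
    r_hypoxia = float(edges[hypoxic.max() + 1]) if len(hypoxic) else 0.0
    hypoxic_rim = max(r_hypoxia - r_core, 0.0)

    central = dist <= central_radius_um
    ph = cell_quantity(snapshot, "pH")
    central_po2 = float(np.mean(po2[central])) if central.any() else float("nan")
    central_ph = float(np.mean(ph[central])) if central.any() else float("nan")

    dp = _diffusion_params(snapshot)
    ph_env = float(ph_from_lactate(float(snapshot.env_concentrations[EAL]), dp))
    depth_r = r_surface - 200.0
    shell_w = max((edges[1] - edges[0]), 5.0)
    shell = np.abs(dist - depth_r) <= shell_w
    delta_ph = float(ph_env - np.mean(ph[shell])) if shell.any() else float("nan")

    phases = df["phase"].to_numpy()
    live_phases = phases[alive]
    n_live = max(len(live_phases), 1)
    g01 = np.isin(live_phases, ["G1M", "G1P"]).sum() / n_live * 100.0
    s = (live_phases == "S").sum() / n_live * 100.0
    g2m = np.isin(live_phases, ["G2", "M"]).sum() / n_live * 100.0

    return {
        "surface_radius_um": r_surface,
        "necrotic_core_radius_um": r_core,
        "viable_rim_thickness_um": viable_rim,
        "hypoxic_rim_thickness_um": hypoxic_rim,
        "hypoxic_rim_thickness_alt_um": r_core,  # necrotic-core-radius definition
        "central_pO2_mmHg": central_po2,
        "central_pH": central_ph,
        "delta_pH": delta_ph,
        "cycle_census_percent": {"G0/G1": float(g01), "S": float(s),
                                 "G2/M": float(g2m)},
        "alive_fraction_profile": (centers, alive_frac),
    }


# ---------------------------------------------------------------------------
# Flow fields


def flow_field_slice(snapshot: SnapshotRecord, point_um, normal,
                     thickness_um: float, field: str) -> list[tuple[np.ndarray, np.ndarray]]:
    """Vectors of a named flow projected on a central section.

    For molecular species the per-node vector is the resultant of the
    diffusive link fluxes (kg/s, direction-weighted); for ``velocity`` it is
    the cell velocity.  Only cells within the slab are reported, and every
    output vector lies in the slice plane.
    """
    if thickness_um <= 0:
        raise ValueError("slab thickness must be positive")
    df = snapshot.cells
    nhat = np.asarray(normal, dtype=float)
    nhat = nhat / np.linalg.norm(nhat)
    pts = df[["x_um", "y_um", "z_um"]].to_numpy(float)
    signed = (pts - np.asarray(point_um, dtype=float)) @ nhat
    in_slab = np.abs(signed) <= thickness_um / 2.0
    if not in_slab.any():
        return []
    if field == "velocity":
        vec = df[["vx_m_s", "vy_m_s", "vz_m_s"]].to_numpy(float)
    else:
        try:
            s = {"o2": 0, "glucose": 1, "glutamine": 2, "lactate": 3}[field]
        except KeyError:
            raise ValueError(f"unknown flow field {field!r}") from None
        vec = _species_flow_vectors(snapshot, s)
    proj = vec - np.outer(vec @ nhat, nhat)
    return [(pts[i], proj[i]) for i in np.nonzero(in_slab)[0]]


def _species_flow_vectors(snapshot: SnapshotRecord, species: int) -> np.ndarray:
    """Per-cell resultant of the extracellular diffusive link fluxes (kg/s)."""
    df = snapshot.cells
    pop = population_from_snapshot(snapshot)
    dp = _diffusion_params(snapshot)
    network = build_contact_network(pop.position, pop.radius)
    net = build_diffusion_network(pop, network, dp)
    d_s = [dp.d_o2, dp.d_glucose, dp.d_glutamine, dp.d_lactate][species]
    vfree = dp.free_volume_fraction * pop.volume
    conc = np.where(vfree > 0, pop.E[:, species] / vfree, 0.0)
    out = np.zeros((len(pop), 3))
    if len(net.cell_links) == 0:
        return out
    a = net.cell_links[:, 0]
    b = net.cell_links[:, 1]
    delta = pop.position[b] - pop.position[a]
    dist = np.linalg.norm(delta, axis=1)
    ok = dist > 0
    unit = np.zeros_like(delta)
    unit[ok] = delta[ok] / dist[ok, None]
    flux = d_s * net.g * (conc[a] - conc[b])   # kg/s, positive a -> b
    contrib = 0.5 * flux[:, None] * unit
    np.add.at(out, a, contrib)
    np.add.at(out, b, contrib)
    return out


# ---------------------------------------------------------------------------
# Growth curves


def growth_curve(trajectory: list[SnapshotRecord]) -> pd.DataFrame:
    """(time, total volume, equivalent diameter, N_live, N_dead) series."""
    if not trajectory:
        raise ValueError("empty trajectory")
    rows = []
    for snap in trajectory:
        v = snap.summary["total_volume_m3"]
        d_eq = 2.0 * (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0) * 1e6
        rows.append({
            "time_days": snap.time / 86400.0,
            "total_volume_m3": v,
            "equivalent_diameter_um": d_eq,
            "n_live": snap.summary["n_live"],
            "n_dead": snap.summary["n_dead"],
        })
    return pd.DataFrame(rows)
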