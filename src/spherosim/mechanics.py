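"""Center-based cell mechanics.

Cells are stretchable spheres.  Overlapping pairs repel with a Hertz contact
force (capped at a saturation value for deep compression), slightly separated
pairs attract through membrane adhesion, and beyond a detachment distance the
force vanishes; the force is continuous everywhere.  Motion is overdamped
(velocity = force / drag) and integrated with stability-bounded sub-steps of
the biochemical time step.  Dead cells shrink exponentially toward a residual
radius, which drives the inward motion of the necrotic core.
"""

from __future__ import annotations

import math

import numpy as np

from .geometry import ContactNetwork
from .metabolism import Phase, Population
from .params import ForceLawParams


def pairwise_force(distance, r_a, r_b, params: ForceLawParams):
    """Signed scalar force along the center line; repulsion positive.

    Regions: Hertz repulsion ``(k sqrt(R*) delta^{3/2})`` capped at
    ``f_saturation`` for overlap delta > 0; zero at contact
    (distance = r_a + r_b); a cubic adhesion well, continuously reaching
    zero with zero slope at the detachment distance
    ``detachment_mult (r_a + r_b)``; exactly zero beyond.
    """
    d = np.asarray(distance, dtype=float)
    ra = np.asarray(r_a, dtype=float)
    rb = np.asarray(r_b, dtype=float)
    rsum = ra + rb
    r_eff = ra * rb / rsum
    overlap = np.clip(rsum - d, 0.0, None)
    f_rep = np.minimum(
        params.hertz_prefactor * np.sqrt(r_eff) * overlap**1.5,
        params.f_saturation)
    d_detach = params.detachment_mult * rsum
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.clip((d - rsum) / (d_detach - rsum), 0.0, 1.0)
    # 27/4 s (1-s)^2 peaks at exactly 1 (s = 1/3) and has zero slope at s = 1
    f_adh = -params.adhesion_peak * 6.75 * s * (1.0 - s) ** 2
    out = np.where(d < rsum, f_rep, np.where(d < d_detach, f_adh, 0.0))
    return float(out) if out.ndim == 0 else out


def drag_coefficient(radius, params: ForceLawParams):
    """Stokes-like per-cell drag, gamma = 6 pi eta_eff r."""
    return 6.0 * math.pi * params.viscosity_eff * np.asarray(radius, dtype=float)


def net_forces(pop: Population, network: ContactNetwork,
               params: ForceLawParams) -> np.ndarray:
    """Per-cell force vectors from pairwise interactions over Delaunay links.

    Newton's third law holds pairwise, so the total internal force is the
    zero vector to machine precision.
    """
    n = len(pop)
    if network.n_cells != n:
        raise ValueError("contact network is stale (cell count mismatch)")
    forces = np.zeros((n, 3))
    edges = network.edges
    if len(edges) == 0:
        return forces
    a = edges[:, 0]
    b = edges[:, 1]
    delta = pop.position[a] - pop.position[b]
    dist = np.linalg.norm(delta, axis=1)
    # coincident centers: no defined direction, skip (division placement
    # always separates daughters)
    ok = dist > 0
    f = np.zeros(len(edges))
    f[ok] = pairwise_force(dist[ok], pop.radius[a[ok]], pop.radius[b[ok]], params)
    unit = np.zeros_like(delta)
    unit[ok] = delta[ok] / dist[ok, None]
    fv = f[:, None] * unit
    for k in range(3):
        forces[:, k] = (np.bincount(a, weights=fv[:, k], minlength=n)
                        - np.bincount(b, weights=fv[:, k], minlength=n))
    return forces


def motion_step(pop: Population, forces: np.ndarray, dt: float,
                params: ForceLawParams) -> None:
    """One overdamped update: v = F / gamma(r), x += v dt (in place)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.all(np.isfinite(forces)):
        bad = np.nonzero(~np.isfinite(forces).all(axis=1))[0]
        raise ValueError(f"non-finite force on cells {pop.ids[bad][:5].tolist()}")
    gamma = drag_coefficient(pop.radius, params)
    v = forces / gamma[:, None]
    pop.position += v * dt
    pop.velocity[:] = v


def _stable_substep(pop: Population, network: ContactNetwork,
                    params: ForceLawParams) -> float:
    """Explicit-stability bound on the mechanics sub-step from the stiffest
    pair currently in contact (dt < gamma / k_spring)."""
    if len(network.edges) == 0:
        return params.dt_mech_max
    a = network.edges[:, 0]
    b = network.edges[:, 1]
    rsum = pop.radius[a] + pop.radius[b]
    overlap = np.clip(rsum - network.distance, 1e-9, None)
    r_eff = pop.radius[a] * pop.radius[b] / rsum
    k_spring = 1.5 * params.hertz_prefactor * np.sqrt(r_eff * overlap)
    # deeply compressed pairs sit on the flat (saturated) force branch and
    # contribute no stiffness
    f_rep = params.hertz_prefactor * np.sqrt(r_eff) * overlap**1.5
    k_spring[f_rep >= params.f_saturation] = 0.0
    gamma = np.minimum(drag_coefficient(pop.radius[a], params),
                       drag_coefficient(pop.radius[b], params))
    k_max = float(k_spring.max())
    if k_max <= 0:
        return params.dt_mech_max
    dt_lim = 0.3 * float(np.min(gamma)) / k_max
    return min(params.dt_mech_max, max(dt_lim, 1e-3))


def relax_mechanics(pop: Population, network_builder, dt_total: float,
                    params: ForceLawParams,
                    rebuild_every: int = 50) -> ContactNetwork:
    """Advance the mechanical sub-system over one biochemical step.

    ``network_builder`` is a callable returning a fresh :class:`ContactNetwork`
    for the current positions; the adjacency is refreshed every few sub-steps
    as cells move.  Velocities stored on the population are displacement over
    ``dt_total`` (the macroscopic velocity field of the output snapshots).
    """
    network = network_builder()
    if len(pop) == 0 or dt_total <= 0:
        return network
    x0 = pop.position.copy()
    t = 0.0
    i = 0
    while t < dt_total and i < params.max_substeps:
        # stop early rather than take an unstable jump: relaxation is
        # quasi-static and simply continues in the next macro step
        if i > 0 and i % rebuild_every == 0:
            network = network_builder()
        dt_sub = min(_stable_substep(pop, network, params), dt_total - t)
        forces = net_forces(pop, network, params)
        motion_step(pop, forces, dt_sub, params)
        t += dt_sub
        i += 1
    pop.velocity[:] = (pop.position - x0) / dt_total
    return network


def shrink_dead_cell(radius: float, radius_at_death: float, dt: float,
                     params: ForceLawParams) -> float:
    """Exponential decay of a dead cell's radius toward the residual radius.

    ``r(t) = r_res + (r_death - r_res) exp(-k t)`` with
    ``r_res = residual_radius_fraction * r_death``; the radius never falls
    below the residual and is non-increasing.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    r_res = params.residual_radius_fraction * radius_at_death
    return r_res + max(radius - r_res, 0.0) * math.exp(-params.shrink_rate * dt)


def shrink_dead_population(pop: Population, dt: float,
                           params: ForceLawParams) -> None:
    dead = pop.phase == int(Phase.DEAD)
    if not np.any(dead):
        return
    r_res = params.residual_radius_fraction * pop.radius_at_death[dead]
    pop.radius[dead] = r_res + np.clip(pop.radius[dead] - r_res, 0.0, None) \
        * math.exp(-params.shrink_rate * dt)
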