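"""Extracellular diffusion network and the stiff coupled solve.

Each cell carries its own extracellular compartment (free volume, masses of
O2, glucose, glutamine and lactate); compartments of Delaunay neighbors
exchange mass through links whose conductance is set by a geometric factor
``g_ab`` (estimated shared boundary area / center distance), and surface
cells exchange with the external environment.  Because the extracellular
free volumes are tiny, their filling times are orders of magnitude shorter
than the macroscopic evolution of the spheroid; the combined
metabolism-transport-diffusion system is therefore integrated with the
implicit Euler method, solving the nonlinear step equations with a
(modified) Newton-Raphson iteration warm-started from the current state.

The linear solve inside the Newton loop is direct (sparse LU) for small
systems and preconditioned GMRES (incomplete LU) for large ones; because
the environment slots sit at the front of the global vector and newborn
cells are appended at the back, a preconditioner built a few steps earlier
remains usable after divisions, padded with a diagonal tail for the new
rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import ContactNetwork
from .metabolism import (
    EAL, N_EXTRACELLULAR, N_INTRACELLULAR, Population, population_local_rhs,
)
from .params import DiffusionParams, Environment, MetabolicParams, SolverParams

#: environment pseudo-node id in DiffusionLink records
ENVIRONMENT_ID = -1

#: per-cell slot layout of the global state vector (after the 4 env slots)
SLOTS_PER_CELL = 19
_X_SLOTS = slice(0, N_INTRACELLULAR)            # 12 dynamic intracellular
_FROZEN_SLOTS = slice(N_INTRACELLULAR, 15)      # n_mito, volume, age (algebraic)
_E_SLOTS = slice(15, 19)                        # 4 extracellular masses

#: below this system size the Newton linear solve is a direct sparse LU
DIRECT_SOLVE_MAX_SIZE = 4000


@dataclass
class ExtracellularNode:
    """Per-cell extracellular compartment."""

    cell_id: int
    free_volume: float
    mass_O2: float
    mass_glucose: float
    mass_glutamine: float
    mass_lactate: float
    is_surface: bool


@dataclass
class DiffusionLink:
    """A single conductive link of the network (node_b may be the environment)."""

    node_a: int
    node_b: int
    length: float
    g_ab: float


@dataclass
class EnvironmentNode:
    concentrations: np.ndarray
    volume: float
    mode: str


def ph_from_lactate(al_conc, params: DiffusionParams | None = None):
    """Phenomenological extracellular pH from the local lactate concentration.

    ``pH = pH0 - dpH_max * c / (c + K)``: smooth, monotone non-increasing,
    equal to the environment baseline at zero lactate.
    """
    if params is None:
        params = DiffusionParams()
    c = np.asarray(al_conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("lactate concentration must be non-negative")
    out = params.ph0 - params.ph_drop_max * c / (c + params.k_ph)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Network construction


@dataclass
class DiffusionNetwork:
    """Array view of the diffusion links (cell-cell and cell-environment)."""

    cell_links: np.ndarray     # (M, 2) int indices into the population
    length: np.ndarray         # (M,)
    g: np.ndarray              # (M,) geometric factor, m
    env_cells: np.ndarray      # (K,) surface cell indices
    g_env: np.ndarray          # (K,)

    def links(self) -> list[DiffusionLink]:
        out = [DiffusionLink(int(a), int(b), float(l), float(g))
               for (a, b), l, g in zip(self.cell_links, self.length, self.g)]
        out += [DiffusionLink(int(c), ENVIRONMENT_ID, 0.0, float(g))
                for c, g in zip(self.env_cells, self.g_env)]
        return out


def geometric_factor(dist, ra, rb, cutoff_mult: float):
    """g_ab = (estimated shared boundary area) / (center distance).

    The shared area of two neighboring extracellular spaces is estimated as
    ``pi * min(ra, rb)^2`` for closely packed pairs, tapering linearly to
    zero at the cutoff distance ``cutoff_mult * (ra + rb)`` (beyond which
    the link carries no flux); symmetric in the two cells by construction.
    """
    dist = np.asarray(dist, dtype=float)
    ra = np.asarray(ra, dtype=float)
    rb = np.asarray(rb, dtype=float)
    rsum = ra + rb
    d_eq = 0.9 * rsum
    d_cut = cutoff_mult * rsum
    taper = np.clip((d_cut - dist) / (d_cut - d_eq), 0.0, 1.0)
    area = math.pi * np.minimum(ra, rb) ** 2 * taper
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(dist > 0, area / np.maximum(dist, 1e-12), 0.0)
    return g


def build_diffusion_network(pop: Population, network: ContactNetwork,
                            params: DiffusionParams) -> DiffusionNetwork:
    """One conductive link per Delaunay edge plus one environment link per
    surface cell; the geometric factor is computed from contact geometry."""
    if network.is_surface is None or len(network.is_surface) != len(pop):
        raise ValueError("contact network lacks a surface classification")
    edges = network.edges
    if len(edges):
        ra = pop.radius[edges[:, 0]]
        rb = pop.radius[edges[:, 1]]
        g = geometric_factor(network.distance, ra, rb, params.link_cutoff_mult)
    else:
        g = np.zeros(0)
    env_cells = np.nonzero(network.is_surface)[0]
    g_env = params.env_link_scale * 4.0 * math.pi * pop.radius[env_cells]
    return DiffusionNetwork(
        cell_links=edges, length=network.distance.copy(), g=g,
        env_cells=env_cells, g_env=g_env,
    )


# ---------------------------------------------------------------------------
# Global state vector


class GlobalStateVector:
    """Index map between the population arrays and the flat solver vector.

    Layout: 4 environment mass slots first, then 19 slots per cell — the 12
    dynamic intracellular variables, three algebraic slots (n_mito, volume,
    age; frozen within a biochemical step) and the 4 extracellular masses.
    Putting the environment first keeps every existing index stable when
    newborn cells are appended at mitosis.
    """

    def __init__(self, n_cells: int):
        self.n_cells = n_cells
        self.size = N_EXTRACELLULAR + SLOTS_PER_CELL * n_cells

    def cell_blocks(self, x: np.ndarray) -> np.ndarray:
        """(N, 19) view of the per-cell part of x."""
        return x[N_EXTRACELLULAR:].reshape(self.n_cells, SLOTS_PER_CELL)

    def pack(self, pop: Population, env_masses: np.ndarray) -> np.ndarray:
        x = np.zeros(self.size)
        x[:N_EXTRACELLULAR] = env_masses
        blocks = self.cell_blocks(x)
        blocks[:, _X_SLOTS] = pop.X
        blocks[:, 12] = pop.n_mito
        blocks[:, 13] = pop.volume
        blocks[:, 14] = pop.age_in_phase
        blocks[:, _E_SLOTS] = pop.E
        return x

    def unpack(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        blocks = self.cell_blocks(x)
        return blocks[:, _X_SLOTS], blocks[:, _E_SLOTS], x[:N_EXTRACELLULAR]

    def write_back(self, x: np.ndarray, pop: Population) -> np.ndarray:
        X, E, env = self.unpack(x)
        pop.X[:] = X
        pop.E[:] = E
        return env

    def x_index(self, cell: int, slot: int) -> int:
        return N_EXTRACELLULAR + SLOTS_PER_CELL * cell + slot

    def env_index(self, species: int) -> int:
        return species


# ---------------------------------------------------------------------------
# Coupled reaction-diffusion system


class ReactionDiffusionSystem:
    """The right-hand side F of the coupled metabolism-transport-diffusion
    problem on the current geometry, plus its sparse Jacobian."""

    def __init__(self, pop: Population, net: DiffusionNetwork,
                 env: Environment, mparams: MetabolicParams,
                 dparams: DiffusionParams):
        self.pop = pop
        self.net = net
        self.env = env
        self.mparams = mparams
        self.dparams = dparams
        self.gsv = GlobalStateVector(len(pop))
        self.vol = pop.volume
        self.vfree = dparams.free_volume_fraction * self.vol
        self.d_species = np.array([dparams.d_o2, dparams.d_glucose,
                                   dparams.d_glutamine, dparams.d_lactate])
        self._lap = self._build_laplacian()

    # -- diffusion operator (linear, analytic) ------------------------------

    def _build_laplacian(self) -> sp.csr_matrix:
        """Sparse matrix L with F_diff = L x acting on the extracellular and
        environment mass slots (flux = D_s * g * (c_a - c_b))."""
        n = self.gsv.size
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        inv_vf = np.where(self.vfree > 0, 1.0 / np.maximum(self.vfree, 1e-30), 0.0)
        inv_ve = 1.0 / self.env.volume
        links = self.net.cell_links
        g_link = self.net.g
        if len(links):
            active = g_link > 0
            a = links[active, 0]
            b = links[active, 1]
            g_ab = g_link[active]
        else:
            a = b = np.zeros(0, dtype=np.int64)
            g_ab = np.zeros(0)
        c = self.net.env_cells
        g_env = self.net.g_env
        base = N_EXTRACELLULAR
        for s in range(N_EXTRACELLULAR):
            d = self.d_species[s]
            slot = 15 + s
            ia = base + SLOTS_PER_CELL * a + slot
            ib = base + SLOTS_PER_CELL * b + slot
            ka = d * g_ab * inv_vf[a]
            kb = d * g_ab * inv_vf[b]
            rows += [ia, ia, ib, ib]
            cols += [ia, ib, ib, ia]
            vals += [-ka, kb, -kb, ka]
            ic = base + SLOTS_PER_CELL * c + slot
            kc = d * g_env * inv_vf[c]
            ke = d * g_env * inv_ve
            ie_arr = np.full(len(c), s)
            rows += [ic, ic]
            cols += [ic, ie_arr]
            vals += [-kc, ke]
            if self.env.mode == "evolving":
                rows += [ie_arr, ie_arr]
                cols += [ic, ie_arr]
                vals += [kc, -ke]
        if rows:
            rows_a = np.concatenate(rows)
            cols_a = np.concatenate(cols)
            vals_a = np.concatenate(vals)
        else:
            rows_a = cols_a = np.zeros(0, dtype=np.int64)
            vals_a = np.zeros(0)
        return sp.csr_matrix((vals_a, (rows_a, cols_a)), shape=(n, n))

    # -- right-hand side -----------------------------------------------------

    def _local_rhs_flat(self, x: np.ndarray) -> np.ndarray:
        X, E, _ = self.gsv.unpack(x)
        out = np.zeros(self.gsv.size)
        n = self.gsv.n_cells
        if n:
            from .metabolism import IAL
            with np.errstate(invalid="ignore", divide="ignore"):
                # local microenvironment pH from the tissue lactate (cell +
                # extracellular space): dead cells retain their metabolite
                # load, so the necrotic core stays acidic
                c_al = np.where(self.vol > 0,
                                (np.clip(X[:, IAL], 0.0, None)
                                 + np.clip(E[:, EAL], 0.0, None))
                                / (self.vol + self.vfree), 0.0)
            ph = ph_from_lactate(c_al, self.dparams)
            ph = np.clip(ph, 5.51, 7.99)
            dX, dE = population_local_rhs(self.pop, self.mparams,
                                          self.dparams.free_volume_fraction,
                                          ph, X=X, E=E)
            blocks = self.gsv.cell_blocks(out)
            blocks[:, _X_SLOTS] = dX
            blocks[:, _E_SLOTS] = dE
        return out

    def rhs(self, x: np.ndarray) -> np.ndarray:
        """F(x): local metabolism/membrane terms plus network diffusion."""
        return self._local_rhs_flat(x) + self._lap @ x

    def assemble_residual(self, x_next: np.ndarray, x_now: np.ndarray,
                          dt: float) -> np.ndarray:
        """Implicit-Euler residual x_next - x_now - dt F(x_next).

        Environment slots are pinned (residual = x_next - x_now) when the
        environment mode is ``fixed``.
        """
        if x_next.shape != (self.gsv.size,) or x_now.shape != (self.gsv.size,):
            raise ValueError("state vector dimension mismatch")
        r = x_next - x_now - dt * self.rhs(x_next)
        if self.env.mode == "fixed":
            r[:N_EXTRACELLULAR] = x_next[:N_EXTRACELLULAR] - x_now[:N_EXTRACELLULAR]
        return r

    # -- Jacobian ------------------------------------------------------------

    def local_jacobian(self, x: np.ndarray,
                       fd_eps: float = 1.0e-6) -> sp.csr_matrix:
        """Within-cell Jacobian of the local terms by grouped finite
        differences: each of the 16 dynamic per-cell slots is perturbed for
        all cells simultaneously (local terms never couple distinct cells)."""
        n = self.gsv.n_cells
        if n == 0:
            return sp.csr_matrix((self.gsv.size, self.gsv.size))
        base = self._local_rhs_flat(x)
        base_blocks = self.gsv.cell_blocks(base)
        dyn_slots = list(range(0, N_INTRACELLULAR)) + list(range(15, 19))
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        x_blocks = self.gsv.cell_blocks(x)
        typ = np.maximum(np.abs(x_blocks).mean(axis=0), 1e-30)
        cell_base = N_EXTRACELLULAR + SLOTS_PER_CELL * np.arange(n)
        for k in dyn_slots:
            eps = fd_eps * np.maximum(np.abs(x_blocks[:, k]), typ[k])
            xp = x.copy()
            self.gsv.cell_blocks(xp)[:, k] += eps
            pert_blocks = self.gsv.cell_blocks(self._local_rhs_flat(xp))
            dcol = (pert_blocks - base_blocks) / eps[:, None]
            for r_slot in dyn_slots:
                rows.append(cell_base + r_slot)
                cols.append(cell_base + k)
                vals.append(dcol[:, r_slot])
        return sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.gsv.size, self.gsv.size))

    def jacobian(self, x: np.ndarray, dt: float,
                 fd_eps: float = 1.0e-6) -> sp.csc_matrix:
        """J = I - dt dF/dx, with pinned rows for fixed-environment slots."""
        j = sp.identity(self.gsv.size, format="csr") - dt * (
            self.local_jacobian(x, fd_eps) + self._lap)
        if self.env.mode == "fixed":
            j = j.tolil()
            for s in range(N_EXTRACELLULAR):
                j.rows[s] = [s]
                j.data[s] = [1.0]
            j = j.tocsr()
        return j.tocsc()

    # -- convenience ---------------------------------------------------------

    def pack_state(self) -> np.ndarray:
        env_masses = np.asarray(self.env.concentrations()) * self.env.volume
        return self.gsv.pack(self.pop, env_masses)

    def nodes(self) -> list[ExtracellularNode]:
        surf = np.zeros(len(self.pop), dtype=bool)
        surf[self.net.env_cells] = True
        return [ExtracellularNode(
            cell_id=int(self.pop.ids[i]), free_volume=float(self.vfree[i]),
            mass_O2=float(self.pop.E[i, 0]), mass_glucose=float(self.pop.E[i, 1]),
            mass_glutamine=float(self.pop.E[i, 2]), mass_lactate=float(self.pop.E[i, 3]),
            is_surface=bool(surf[i])) for i in range(len(self.pop))]


def assemble_residual(system: ReactionDiffusionSystem, x_next: np.ndarray,
                      x_now: np.ndarray, dt: float) -> np.ndarray:
    return system.assemble_residual(x_next, x_now, dt)


# ---------------------------------------------------------------------------
# Newton solver


class NewtonDiagnostics:
    def __init__(self) -> None:
        self.iterations = 0
        self.halvings = 0
        self.clamped_mass = 0.0
        self.factorizations = 0
        self.gmres_fallbacks = 0


class _PaddedILU:
    """ILU preconditioner of an earlier (possibly smaller) Jacobian, padded
    with a diagonal tail for rows appended since it was built."""

    def __init__(self, ilu, size_built: int):
        self.ilu = ilu
        self.size_built = size_built

    def operator(self, size: int, diag: np.ndarray) -> spla.LinearOperator:
        s0 = self.size_built
        tail = diag[s0:]
        tail = np.where(np.abs(tail) > 1e-300, tail, 1.0)

        def mv(v: np.ndarray) -> np.ndarray:
            out = np.empty(size)
            out[:s0] = self.ilu.solve(v[:s0])
            out[s0:] = v[s0:] / tail
            return out

        return spla.LinearOperator((size, size), matvec=mv)


class NewtonSolver:
    """Modified Newton-Raphson for the implicit Euler step.

    The linearization is refreshed once per step; the warm start from the
    previous state keeps iterates close, so convergence typically takes two
    or three iterations.  Small systems use a cached direct LU; large ones
    use GMRES preconditioned with an incomplete LU that is rebuilt only
    every ``jacobian_refresh_every`` steps (appended cells are covered by a
    diagonal tail).  Non-convergence triggers step halving before raising.
    """

    def __init__(self, system: ReactionDiffusionSystem,
                 solver_params: SolverParams | None = None):
        self.system = system
        self.params = solver_params or SolverParams()
        self._lu = None
        self._lu_size = 0
        self._ilu: _PaddedILU | None = None
        self._age = 0
        self.diagnostics = NewtonDiagnostics()

    def invalidate(self) -> None:
        self._lu = None
        self._ilu = None

    def note_step(self) -> None:
        self._age += 1

    # -- linear algebra -------------------------------------------------------

    def _direct(self) -> bool:
        return self.system.gsv.size <= DIRECT_SOLVE_MAX_SIZE

    def _refresh_factorization(self, j: sp.csc_matrix) -> None:
        if self._direct():
            self._lu = spla.splu(j)
            self._lu_size = j.shape[0]
        else:
            ilu = spla.spilu(j, drop_tol=1e-6, fill_factor=12)
            self._ilu = _PaddedILU(ilu, j.shape[0])
        self._age = 0
        self.diagnostics.factorizations += 1

    def _linear_solve(self, j: sp.csc_matrix, rhs: np.ndarray) -> np.ndarray:
        if self._direct():
            if self._lu is None or self._lu_size != j.shape[0] or \
                    self._age >= self.params.jacobian_refresh_every:
                self._refresh_factorization(j)
            return self._lu.solve(rhs)
        if self._ilu is None or self._ilu.size_built > j.shape[0] or \
                self._age >= self.params.jacobian_refresh_every:
            self._refresh_factorization(j)
        # inexact Newton: a loose relative tolerance on the inner solve is
        # enough for the 1% outer convergence test
        M = self._ilu.operator(j.shape[0], j.diagonal())
        dx, info = spla.gmres(j, rhs, M=M, rtol=1e-6, atol=0.0,
                              restart=40, maxiter=120)
        if info != 0:
            # stale preconditioner: rebuild once and retry
            self.diagnostics.gmres_fallbacks += 1
            self._refresh_factorization(j)
            M = self._ilu.operator(j.shape[0], j.diagonal())
            dx, info = spla.gmres(j, rhs, M=M, rtol=1e-6, atol=0.0,
                                  restart=40, maxiter=120)
            if info != 0:
                raise RuntimeError("preconditioned GMRES failed to converge")
        return dx

    # -- convergence scale ----------------------------------------------------

    def _scale(self, x: np.ndarray) -> np.ndarray:
        """Per-slot scale for the relative-update convergence test:
        max(|x|, population-typical value of the slot, class floor).

        Class floors keep zero-valued slots (fresh cyclins, absent lactate)
        from blowing up the relative metric: for mass slots the floor is the
        mass at a negligible concentration (1e-6 kg/m^3) in the compartment.
        """
        n = self.system.gsv.n_cells
        scale = np.abs(x).copy()
        if n:
            blocks = np.abs(self.system.gsv.cell_blocks(x))
            typ = blocks.mean(axis=0)
            floors = np.empty(SLOTS_PER_CELL)
            v_typ = float(np.mean(self.system.vol)) if len(self.system.vol) else 1e-16
            floors[0:8] = 1e-6 * v_typ       # intracellular masses (kg)
            floors[8] = 1e-3                 # DNA fraction
            floors[9] = 0.1                  # mtDNA units
            floors[10:12] = 1e-3             # cyclins (a.u.)
            floors[12] = 1.0                 # n_mito (frozen)
            floors[13] = v_typ               # volume (frozen)
            floors[14] = 1.0                 # age (frozen)
            floors[15:19] = 1e-6 * v_typ * self.system.dparams.free_volume_fraction
            typ = np.maximum(typ, floors)
            scale_blocks = self.system.gsv.cell_blocks(scale)
            np.maximum(scale_blocks, typ[None, :], out=scale_blocks)
        env_floor = 1e-6 * self.system.env.volume
        scale[:N_EXTRACELLULAR] = np.maximum(scale[:N_EXTRACELLULAR], env_floor)
        return scale

    # -- the implicit step ----------------------------------------------------

    def solve_step(self, x_now: np.ndarray, dt: float,
                   rel_tol: float | None = None, _depth: int = 0) -> np.ndarray:
        """One implicit Euler step, warm-started from x_now."""
        rel_tol = self.params.rel_tol if rel_tol is None else rel_tol
        if rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if not np.all(np.isfinite(x_now)):
            raise ValueError("non-finite state entering the implicit step")
        system = self.system
        x = x_now.copy()
        j = system.jacobian(x, dt, self.params.fd_eps)
        prev_upd = np.inf
        rebuilds = 0
        for it in range(self.params.max_newton_iter):
            r = system.assemble_residual(x, x_now, dt)
            scale = self._scale(x)
            # residual-based acceptance: x already satisfies the implicit
            # step equations to well within the solution precision
            if np.max(np.abs(r) / scale) <= 0.2 * rel_tol:
                return self._finalize(x)
            dx = self._linear_solve(j, -r)
            rnorm = np.linalg.norm(r / scale)
            if rnorm < 1e-12 * math.sqrt(len(x)):
                return self._finalize(x + dx)
            # backtracking line search with projection onto the positive
            # orthant: without it, a cell whose O2 crosses zero makes the
            # clipped oxygen sensor flip each iteration and Newton 2-cycles
            alpha = 1.0
            for _ in range(6):
                x_trial = self._project(x + alpha * dx)
                r_trial = system.assemble_residual(x_trial, x_now, dt)
                if np.linalg.norm(r_trial / scale) <= (1 - 1e-4 * alpha) * rnorm:
                    break
                alpha *= 0.5
            moved = np.max(np.abs(x_trial - x) / self._scale(x_trial))
            x = x_trial
            self.diagnostics.iterations += 1
            # convergence on the projected motion: an iterate pinned at a
            # positivity boundary (e.g. anoxic O2 = 0) counts as stationary
            if moved <= rel_tol:
                return self._finalize(x)
            upd = moved
            if it >= 3 and (alpha < 1.0 or upd > 0.3 * prev_upd) and rebuilds < 3:
                # stalled or damped: the linearization has gone stale (e.g. a
                # cell crossed the oxygen-sensor switch); relinearize here.
                # The ILU preconditioner is left alone — GMRES solves the
                # fresh Jacobian accurately either way.
                j = system.jacobian(x, dt, self.params.fd_eps)
                if self._direct():
                    self._refresh_factorization(j)
                rebuilds += 1
            prev_upd = upd
        # non-convergence: halve the step and retry
        if _depth >= self.params.max_step_halvings:
            raise RuntimeError(
                f"Newton iteration failed to converge (dt={dt:g}, "
                f"update={upd:.3g}, rel_tol={rel_tol:g})")
        self.diagnostics.halvings += 1
        self.invalidate()
        x_half = self.solve_step(x_now, dt / 2, rel_tol, _depth + 1)
        x_full = self.solve_step(x_half, dt / 2, rel_tol, _depth + 1)
        self.invalidate()
        return x_full

    def _project(self, x: np.ndarray) -> np.ndarray:
        """Project mass-valued slots onto the non-negative orthant."""
        n = self.system.gsv.n_cells
        if n:
            blocks = self.system.gsv.cell_blocks(x)
            np.clip(blocks[:, 0:8], 0.0, None, out=blocks[:, 0:8])
            np.clip(blocks[:, 15:19], 0.0, None, out=blocks[:, 15:19])
        np.clip(x[:N_EXTRACELLULAR], 0.0, None, out=x[:N_EXTRACELLULAR])
        return x

    def _finalize(self, x: np.ndarray) -> np.ndarray:
        """Positivity: clamp negative species masses; for extracellular
        species, redistribute the deficit proportionally over the positive
        compartments of the same species so no global mass is created."""
        n = self.system.gsv.n_cells
        if n == 0:
            return x
        blocks = self.system.gsv.cell_blocks(x)
        neg = blocks[:, 0:8] < 0
        if np.any(neg):
            self.diagnostics.clamped_mass += -blocks[:, 0:8][neg].sum()
            blocks[:, 0:8][neg] = 0.0
        env = x[:N_EXTRACELLULAR]
        for s in range(N_EXTRACELLULAR):
            col = blocks[:, 15 + s]
            negm = col < 0
            if not np.any(negm):
                continue
            deficit = -col[negm].sum()
            self.diagnostics.clamped_mass += deficit
            col[negm] = 0.0
            pos = col > 0
            total = col[pos].sum()
            if total > deficit > 0:
                col[pos] -= deficit * col[pos] / total
        blocks[:, 8] = np.clip(blocks[:, 8], 0.0, 1.0)    # DNA fraction
        blocks[:, 9] = np.clip(blocks[:, 9], 0.0, None)   # mtDNA
        blocks[:, 10:12] = np.clip(blocks[:, 10:12], 0.0, None)  # cyclins
        np.clip(env, 0.0, None, out=env)
        return x


def newton_solve_step(system: ReactionDiffusionSystem, x_now: np.ndarray,
                      dt: float, rel_tol: float = 0.01) -> np.ndarray:
    """Single-shot convenience wrapper around :class:`NewtonSolver`."""
    return NewtonSolver(system).solve_step(x_now, dt, rel_tol)
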