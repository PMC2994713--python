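"""Geometry and topology of the cell cluster.

The Delaunay triangulation of the cell centers provides the proximity
relations used both as the scaffolding of the discretized extracellular
diffusion problem and as the neighbor lists of the pairwise force loop; the
alpha shape of the cluster identifies the surface cells that exchange matter
directly with the environment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError


@dataclass
class ContactNetwork:
    """Symmetric neighbor structure over cell ids (array indices).

    ``edges`` is an (M, 2) array with ``edges[:, 0] < edges[:, 1]``; per-link
    distance, overlap and sphere-sphere contact area are stored alongside.
    """

    n_cells: int
    edges: np.ndarray                 # (M, 2) int
    distance: np.ndarray              # (M,) m
    overlap: np.ndarray               # (M,) m
    contact_area: np.ndarray          # (M,) m^2
    is_surface: np.ndarray            # (N,) bool
    centroid: np.ndarray              # (3,) m

    def neighbor_lists(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_cells)]
        for a, b in self.edges:
            out[a].append(int(b))
            out[b].append(int(a))
        return out

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_cells, dtype=np.int64)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg


def _dedupe_points(points: np.ndarray, seed: int = 0,
                   scale: float | None = None) -> np.ndarray:
    """Deterministically perturb exactly duplicated points.

    Coincident centers break the triangulation; they are separated by a tiny
    seeded jitter (1e-9 of the cloud scale) so results stay reproducible.
    """
    pts = np.array(points, dtype=float)
    if len(pts) < 2:
        return pts
    if scale is None:
        scale = max(np.ptp(pts, axis=0).max(), 1.0e-6)
    _, inverse, counts = np.unique(pts.round(decimals=15), axis=0,
                                   return_inverse=True, return_counts=True)
    dup = counts[inverse] > 1
    if np.any(dup):
        rng = np.random.default_rng(seed)
        jitter = rng.normal(size=pts.shape) * 1.0e-9 * scale
        pts[dup] += jitter[dup]
    return pts


def delaunay_neighbors(points: np.ndarray, seed: int = 0) -> tuple[np.ndarray, Delaunay | None]:
    """Edges of the 3D Delaunay triangulation of the given centers.

    Returns ``(edges, tri)`` where ``edges`` is an (M, 2) sorted int array and
    ``tri`` the scipy triangulation (None for N <= 4 or degenerate input,
    where the complete graph is returned instead).  Duplicate points are
    resolved by a deterministic seeded perturbation.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (N, 3) array")
    n = len(pts)
    if n == 0:
        return np.zeros((0, 2), dtype=np.int64), None
    if n <= 4:
        edges = np.array(list(itertools.combinations(range(n), 2)),
                         dtype=np.int64).reshape(-1, 2)
        return edges, None
    pts = _dedupe_points(pts, seed=seed)
    try:
        tri = Delaunay(pts)
    except QhullError:
        # coplanar/collinear clouds: joggle deterministically
        tri = Delaunay(pts, qhull_options="QJ Qbb Qz")
    pairs = tri.simplices[:, _SIMPLEX_EDGE_IDX].reshape(-1, 2)
    pairs = pairs[(pairs < n).all(axis=1)]  # drop Qhull's point at infinity (Qz)
    pairs = np.sort(pairs, axis=1)
    keys = np.unique(pairs[:, 0].astype(np.int64) * n + pairs[:, 1])
    edges = np.column_stack([keys // n, keys % n])
    return edges, tri


_SIMPLEX_EDGE_IDX = np.array(
    [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])
_SIMPLEX_FACE_IDX = np.array(
    [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])


def _circumradius2(simplices: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Squared circumradii of the tetrahedra ``pts[simplices]``, vectorized.

    Degenerate (near-flat) tetrahedra get an infinite circumradius, which
    excludes them from any alpha complex.
    """
    tetra = pts[simplices]                      # (m, 4, 3)
    a = tetra[:, 0]
    rel = tetra[:, 1:] - a[:, None, :]          # (m, 3, 3)
    rhs = 0.5 * (rel**2).sum(axis=2)            # (m, 3)
    det = np.linalg.det(rel)
    scale = np.abs(rel).max(axis=(1, 2)) ** 3 + 1e-300
    good = np.abs(det) > 1e-12 * scale
    r2 = np.full(len(tetra), np.inf)
    if good.any():
        center = np.linalg.solve(rel[good], rhs[good][..., None])[..., 0]
        r2[good] = (center**2).sum(axis=1)
    return r2


def surface_cells(points: np.ndarray, radii: np.ndarray,
                  alpha: float | None = None,
                  tri: Delaunay | None = None) -> np.ndarray:
    """Boolean surface flags from the alpha shape of the cluster.

    The alpha complex keeps the Delaunay tetrahedra whose squared
    circumradius is at most ``alpha`` (CGAL convention: alpha is a squared
    length); cells on the boundary of the complex, or belonging to no kept
    tetrahedron, are surface cells.  Default ``alpha = (2 <r>)^2`` with
    ``<r>`` the average cell radius.  Any cluster of up to 4 cells is all
    surface.
    """
    pts = np.asarray(points, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(pts)
    if n == 0:
        return np.zeros(0, dtype=bool)
    if alpha is None:
        alpha = (2.0 * float(radii.mean())) ** 2
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n <= 4:
        return np.ones(n, dtype=bool)
    if tri is None:
        try:
            tri = Delaunay(_dedupe_points(pts))
        except QhullError:
            return np.ones(n, dtype=bool)
    simplices = tri.simplices[(tri.simplices < n).all(axis=1)]
    if len(simplices) == 0:
        return np.ones(n, dtype=bool)
    r2 = _circumradius2(simplices, pts)
    kept = simplices[r2 <= alpha]
    surface = np.zeros(n, dtype=bool)
    in_complex = np.zeros(n, dtype=bool)
    if len(kept):
        in_complex[kept.ravel()] = True
        faces = np.sort(kept[:, _SIMPLEX_FACE_IDX].reshape(-1, 3), axis=1)
        uniq, counts = np.unique(faces, axis=0, return_counts=True)
        surface[uniq[counts == 1].ravel()] = True  # boundary facets
    surface |= ~in_complex
    if not surface.any():
        surface[:] = True  # degenerate fallback: non-empty surface contract
    return surface


def contact_geometry(cell_a, cell_b) -> tuple[float, float, float]:
    """Distance, overlap and sphere-sphere contact area of two cells.

    Accepts :class:`~spherosim.metabolism.CellState`-like objects (with
    ``position`` and ``radius``).  The contact area is the area of the
    intersection circle of the two spheres, zero when detached; when one
    sphere contains the other's center the smaller sphere's great circle is
    used as a bounded estimate.
    """
    xa = np.asarray(cell_a.position, dtype=float)
    xb = np.asarray(cell_b.position, dtype=float)
    ra, rb = float(cell_a.radius), float(cell_b.radius)
    d = float(np.linalg.norm(xa - xb))
    return pair_contact_geometry(d, ra, rb)


def pair_contact_geometry(d: float, ra: float, rb: float) -> tuple[float, float, float]:
    ra, rb = max(ra, rb), min(ra, rb)  # canonical order: exact swap symmetry
    overlap = max(0.0, ra + rb - d)
    if overlap <= 0.0:
        return d, 0.0, 0.0
    if d <= abs(ra - rb) or d == 0.0:
        return d, overlap, float(np.pi * rb**2)
    a2 = (4.0 * d**2 * ra**2 - (d**2 - rb**2 + ra**2) ** 2) / (4.0 * d**2)
    a2 = max(a2, 0.0)
    return d, overlap, float(np.pi * a2)


def contact_areas(dist: np.ndarray, ra: np.ndarray, rb: np.ndarray) -> np.ndarray:
    """Vectorized sphere-sphere intersection-circle areas."""
    dist = np.asarray(dist, dtype=float)
    ra = np.asarray(ra, dtype=float)
    rb = np.asarray(rb, dtype=float)
    area = np.zeros(np.broadcast(dist, ra, rb).shape)
    touching = dist < ra + rb
    contained = touching & ((dist <= np.abs(ra - rb)) | (dist == 0))
    rmin = np.minimum(ra, rb)
    area[contained] = np.pi * np.broadcast_to(rmin, area.shape)[contained]**2
    proper = touching & ~contained
    if np.any(proper):
        d = dist[proper]
        a = np.broadcast_to(ra, area.shape)[proper]
        b = np.broadcast_to(rb, area.shape)[proper]
        a2 = (4 * d**2 * a**2 - (d**2 - b**2 + a**2) ** 2) / (4 * d**2)
        area[proper] = np.pi * np.clip(a2, 0.0, None)
    return area


def build_contact_network(positions: np.ndarray, radii: np.ndarray,
                          alpha: float | None = None,
                          seed: int = 0,
                          compute_surface: bool = True) -> ContactNetwork:
    """Delaunay adjacency + per-link geometry + alpha-shape surface flags.

    ``compute_surface=False`` skips the alpha shape (the mechanics sub-steps
    only need the adjacency; the surface classification is refreshed with
    the full geometry pass of each macro step).
    """
    pts = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(pts)
    edges, tri = delaunay_neighbors(pts, seed=seed)
    if len(edges):
        delta = pts[edges[:, 0]] - pts[edges[:, 1]]
        dist = np.linalg.norm(delta, axis=1)
        rsum = radii[edges[:, 0]] + radii[edges[:, 1]]
        overlap = np.clip(rsum - dist, 0.0, None)
        area = contact_areas(dist, radii[edges[:, 0]], radii[edges[:, 1]])
    else:
        dist = np.zeros(0)
        overlap = np.zeros(0)
        area = np.zeros(0)
    if compute_surface:
        surf = surface_cells(pts, radii, alpha=alpha, tri=tri)
    else:
        surf = np.ones(n, dtype=bool)
    centroid = pts.mean(axis=0) if n else np.zeros(3)
    return ContactNetwork(
        n_cells=n, edges=edges, distance=dist, overlap=overlap,
        contact_area=area, is_surface=surf, centroid=centroid,
    )
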