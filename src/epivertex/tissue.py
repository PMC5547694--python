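"""Polygonal cell mesh, tissue energy, forces, and overdamped relaxation.

The tissue is an apical-surface vertex model: each cell is a simple polygon
whose vertices are shared with its neighbours, and each vertex moves down the
gradient of the dimensionless tissue energy

    U = 1/2 sum_a (A_a - A0_a)^2 + sum_edges Lam_ab l_ab + sum_a Gam_a/2 L_a^2

where ``A_a`` is the polygon area, ``A0_a`` the natural area (1 outside
mitosis), ``l_ab`` the length of the edge shared by cells a and b with
effective line tension ``Lam_ab``, and ``L_a`` the cell perimeter.  Boundary
edges carry a stronger line tension (3 Lam by default) which keeps the tissue
outline roughly circular.  Vertex motion is overdamped:

    eta dr_i/dt = -dU/dr_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .config import SimConfig

__all__ = [
    "Tissue",
    "CellState",
    "MeshError",
    "effective_line_tension",
    "compute_energy",
    "compute_forces",
    "step",
    "relax",
]


class MeshError(ValueError):
    """Raised when a mesh violates the tissue invariants."""


@dataclass
class CellState:
    """Per-cell mechanical and cycle state (a read/write view onto a Tissue)."""

    lam: float = 0.14
    gam: float = 0.04
    trait_id: int = -1
    clock: float = 0.0
    cycle_len: float = 200.0
    natural_area: float = 1.0
    mitotic: bool = False
    pre_mitotic_area: float = 1.0


def effective_line_tension(lam_a: float, lam_b: float, mode: str = "max"):
    """Effective line tension of an edge between cells with tensions lam_a, lam_b.

    Two combination rules are supported, reflecting two readings of how the
    tension of a shared interface arises from the two cells: ``"max"``
    (default, appropriate when the interface tension is set by the less
    adhesive cell) and ``"mean"``.  Works elementwise on arrays.
    """
    lam_a = np.asarray(lam_a, dtype=float)
    lam_b = np.asarray(lam_b, dtype=float)
    if np.any(lam_a < 0) or np.any(lam_b < 0):
        raise ValueError("line tensions must be non-negative")
    if mode == "max":
        out = np.maximum(lam_a, lam_b)
    elif mode == "mean":
        out = 0.5 * (lam_a + lam_b)
    else:
        raise ValueError("mode must be 'max' or 'mean'")
    return out if out.ndim else float(out)


class _MeshCache:
    """Flattened index arrays derived from the cell cycles.

    Rebuilt whenever the topology changes; everything the force/energy kernels
    need is expressed through these arrays so the hot loop is pure numpy.
    """

    __slots__ = (
        "corner_v", "corner_c", "nxt", "prv", "starts", "counts",
        "edge_id", "n_edges", "edge_vertices", "edge_cells",
        "edge_boundary", "corner_lam", "boundary_vertices",
    )

    def __init__(self, tissue: "Tissue", config: SimConfig):
        cells = tissue.cells
        if len(cells) == 0:
            raise MeshError("tissue has no cells")
        counts = np.array([len(c) for c in cells], dtype=np.int64)
        if np.any(counts < 3):
            raise MeshError("every cell needs at least 3 vertices")
        corner_v = np.concatenate(cells).astype(np.int64)
        corner_c = np.repeat(np.arange(len(cells)), counts)
        starts = np.zeros(len(cells), dtype=np.int64)
        np.cumsum(counts[:-1], out=starts[1:])
        # flat index of the next / previous corner within the same cell
        idx = np.arange(corner_v.size)
        nxt = idx + 1
        ends = starts + counts - 1
        nxt[ends] = starts
        prv = idx - 1
        prv[starts] = ends

        # undirected edge identification
        a = corner_v
        b = corner_v[nxt]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        key = lo * (tissue.vertices.shape[0] + 1) + hi
        uniq, edge_id, counts_e = np.unique(key, return_inverse=True,
                                            return_counts=True)
        if np.any(counts_e > 2):
            raise MeshError("an edge is shared by more than two cells")
        n_edges = uniq.size
        edge_vertices = np.empty((n_edges, 2), dtype=np.int64)
        edge_vertices[edge_id, 0] = lo
        edge_vertices[edge_id, 1] = hi
        edge_cells = np.full((n_edges, 2), -1, dtype=np.int64)
        # first pass fills slot 0, second fills slot 1 for shared edges
        order = np.argsort(edge_id, kind="stable")
        eid_sorted = edge_id[order]
        first = np.ones(eid_sorted.size, dtype=bool)
        first[1:] = eid_sorted[1:] != eid_sorted[:-1]
        edge_cells[eid_sorted[first], 0] = corner_c[order[first]]
        edge_cells[eid_sorted[~first], 1] = corner_c[order[~first]]
        edge_boundary = counts_e == 1

        # per-corner line-tension coefficient: internal edges appear twice so
        # each corner carries half the effective tension; boundary edges appear
        # once and carry the full (multiplied) tension of their lone cell.
        lam = tissue.lam
        c0 = edge_cells[:, 0]
        c1 = np.where(edge_cells[:, 1] >= 0, edge_cells[:, 1], c0)
        lam_edge = effective_line_tension(lam[c0], lam[c1],
                                          config.lam_combination)
        lam_edge = np.where(edge_boundary,
                            config.boundary_tension_mult * lam[c0], lam_edge)
        corner_lam = np.where(edge_boundary[edge_id],
                              lam_edge[edge_id], 0.5 * lam_edge[edge_id])

        bverts = np.unique(edge_vertices[edge_boundary])

        self.corner_v = corner_v
        self.corner_c = corner_c
        self.nxt = nxt
        self.prv = prv
        self.starts = starts
        self.counts = counts
        self.edge_id = edge_id
        self.n_edges = n_edges
        self.edge_vertices = edge_vertices
        self.edge_cells = edge_cells
        self.edge_boundary = edge_boundary
        self.corner_lam = corner_lam
        self.boundary_vertices = bverts


class Tissue:
    """A planar polygonal cell mesh with per-cell state.

    Parameters
    ----------
    vertices : (Nv, 2) array of vertex positions.
    cells : sequence of vertex-index cycles, each counter-clockwise.
    states : optional sequence of CellState; defaults are filled otherwise.
    """

    def __init__(self, vertices, cells: Sequence[Iterable[int]],
                 states: Optional[Sequence[CellState]] = None,
                 lam: float = 0.14, gam: float = 0.04):
        self.vertices = np.asarray(vertices, dtype=float).copy()
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise MeshError("vertices must be an (N, 2) array")
        self.cells: List[np.ndarray] = [
            np.asarray(list(c), dtype=np.int64) for c in cells
        ]
        n = len(self.cells)
        if states is not None:
            if len(states) != n:
                raise MeshError("one CellState per cell required")
            self.lam = np.array([s.lam for s in states], dtype=float)
            self.gam = np.array([s.gam for s in states], dtype=float)
            self.trait = np.array([s.trait_id for s in states], dtype=np.int64)
            self.clock = np.array([s.clock for s in states], dtype=float)
            self.cycle_len = np.array([s.cycle_len for s in states],
                                      dtype=float)
            self.natural_area = np.array([s.natural_area for s in states],
                                         dtype=float)
            self.mitotic = np.array([s.mitotic for s in states], dtype=bool)
            self.premit_area = np.array([s.pre_mitotic_area for s in states],
                                        dtype=float)
        else:
            self.lam = np.full(n, lam, dtype=float)
            self.gam = np.full(n, gam, dtype=float)
            self.trait = np.full(n, -1, dtype=np.int64)
            self.clock = np.zeros(n, dtype=float)
            self.cycle_len = np.full(n, 200.0, dtype=float)
            self.natural_area = np.ones(n, dtype=float)
            self.mitotic = np.zeros(n, dtype=bool)
            self.premit_area = np.ones(n, dtype=float)
        # persistent cell identifiers (stable across divisions/eliminations)
        self.uid = np.arange(n, dtype=np.int64)
        self.next_uid = n
        self._cache: Optional[_MeshCache] = None
        self._cache_cfg_key = None

    # ---------------------------------------------------------------- basics
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def cell_state(self, i: int) -> CellState:
        return CellState(
            lam=float(self.lam[i]), gam=float(self.gam[i]),
            trait_id=int(self.trait[i]), clock=float(self.clock[i]),
            cycle_len=float(self.cycle_len[i]),
            natural_area=float(self.natural_area[i]),
            mitotic=bool(self.mitotic[i]),
            pre_mitotic_area=float(self.premit_area[i]),
        )

    def copy(self) -> "Tissue":
        t = Tissue.__new__(Tissue)
        t.vertices = self.vertices.copy()
        t.cells = [c.copy() for c in self.cells]
        for name in ("lam", "gam", "trait", "clock", "cycle_len",
                     "natural_area", "mitotic", "premit_area", "uid"):
            setattr(t, name, getattr(self, name).copy())
        t.next_uid = self.next_uid
        t._cache = None
        t._cache_cfg_key = None
        return t

    def invalidate(self) -> None:
        """Drop cached topology arrays (call after any topology change)."""
        self._cache = None

    def mesh_cache(self, config: SimConfig) -> _MeshCache:
        key = (config.lam_combination, config.boundary_tension_mult)
        if self._cache is None or self._cache_cfg_key != key:
            self._cache = _MeshCache(self, config)
            self._cache_cfg_key = key
        return self._cache

    # ------------------------------------------------------------- geometry
    def areas(self) -> np.ndarray:
        """Signed polygon areas (positive for CCW cells)."""
        out = np.empty(self.n_cells)
        v = self.vertices
        for i, c in enumerate(self.cells):
            p = v[c]
            x, y = p[:, 0], p[:, 1]
            out[i] = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        return out

    def perimeters(self) -> np.ndarray:
        out = np.empty(self.n_cells)
        v = self.vertices
        for i, c in enumerate(self.cells):
            p = v[c]
            out[i] = np.sum(np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1))
        return out

    def centroids(self) -> np.ndarray:
        """Area centroids of every cell."""
        out = np.empty((self.n_cells, 2))
        v = self.vertices
        for i, c in enumerate(self.cells):
            p = v[c]
            q = np.roll(p, -1, axis=0)
            cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
            a = 0.5 * np.sum(cross)
            if abs(a) < 1e-14:
                out[i] = p.mean(axis=0)
            else:
                out[i] = np.sum((p + q) * cross[:, None], axis=0) / (6.0 * a)
        return out

    def _fast_areas(self, cache: _MeshCache) -> np.ndarray:
        p = self.vertices[cache.corner_v]
        q = self.vertices[cache.corner_v[cache.nxt]]
        cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
        return 0.5 * np.add.reduceat(cross, cache.starts)

    def _fast_perimeters(self, cache: _MeshCache) -> np.ndarray:
        p = self.vertices[cache.corner_v]
        q = self.vertices[cache.corner_v[cache.nxt]]
        elen = np.hypot(q[:, 0] - p[:, 0], q[:, 1] - p[:, 1])
        return np.add.reduceat(elen, cache.starts)

    def edge_lengths(self, config: SimConfig) -> np.ndarray:
        cache = self.mesh_cache(config)
        ev = cache.edge_vertices
        d = self.vertices[ev[:, 1]] - self.vertices[ev[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])

    def boundary_cells(self, config: SimConfig) -> np.ndarray:
        """Boolean mask of cells touching the tissue boundary."""
        cache = self.mesh_cache(config)
        mask = np.zeros(self.n_cells, dtype=bool)
        bcells = cache.edge_cells[cache.edge_boundary, 0]
        mask[bcells] = True
        return mask

    def adjacency(self, config: SimConfig) -> list:
        """Neighbour lists on the cell-adjacency graph (shared internal edge)."""
        cache = self.mesh_cache(config)
        nb = [[] for _ in range(self.n_cells)]
        internal = ~cache.edge_boundary
        for c0, c1 in cache.edge_cells[internal]:
            nb[c0].append(int(c1))
            nb[c1].append(int(c0))
        return nb

    # ------------------------------------------------------------ validation
    def validate(self, config: Optional[SimConfig] = None,
                 check_simple: bool = False) -> None:
        """Raise MeshError if any tissue invariant is violated."""
        config = config or SimConfig()
        cache = self.mesh_cache(config)  # checks >=3 vertices, <=2 cells/edge
        for i, c in enumerate(self.cells):
            if len(np.unique(c)) != len(c):
                raise MeshError(f"cell {i} repeats a vertex")
        a = self._fast_areas(cache)
        if np.any(a <= 0):
            raise MeshError("cell with non-positive signed area "
                            "(orientation must be counter-clockwise)")
        if check_simple:
            try:
                from shapely.geometry import Polygon
            except ImportError:  # pragma: no cover
                return
            for i, c in enumerate(self.cells):
                if not Polygon(self.vertices[c]).is_valid:
                    raise MeshError(f"cell {i} is self-intersecting")


# ----------------------------------------------------------------- mechanics

def compute_energy(tissue: Tissue, config: SimConfig) -> float:
    """Dimensionless tissue energy (area elasticity + line tension + perimeter)."""
    cache = tissue.mesh_cache(config)
    p = tissue.vertices[cache.corner_v]
    q = tissue.vertices[cache.corner_v[cache.nxt]]
    cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
    areas = 0.5 * np.add.reduceat(cross, cache.starts)
    if np.any(np.abs(areas) < 1e-12):
        raise MeshError("degenerate (zero-area) cell")
    elen = np.hypot(q[:, 0] - p[:, 0], q[:, 1] - p[:, 1])
    perim = np.add.reduceat(elen, cache.starts)
    u_area = 0.5 * np.sum((areas - tissue.natural_area) ** 2)
    u_line = float(np.dot(cache.corner_lam, elen))
    u_perim = 0.5 * np.sum(tissue.gam * perim ** 2)
    return float(u_area + u_line + u_perim)


def forces_and_geometry(tissue: Tissue, config: SimConfig):
    """Forces plus the per-step geometry the growth loop also needs.

    Returns (forces (Nv,2), areas, perimeters, edge_lengths, corner_elen).
    Computing them together avoids re-walking the mesh several times per step.
    """
    cache = tissue.mesh_cache(config)
    v = tissue.vertices
    cv = cache.corner_v
    p = v[cv]
    q = v[cv[cache.nxt]]
    r = v[cv[cache.prv]]

    cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
    areas = 0.5 * np.add.reduceat(cross, cache.starts)
    elen = np.hypot(q[:, 0] - p[:, 0], q[:, 1] - p[:, 1])
    if np.any(elen < 1e-12):
        raise MeshError("zero-length edge; topology handling missed a T1/T2")
    perim = np.add.reduceat(elen, cache.starts)

    cc = cache.corner_c
    # area term: -dU/dr_v = -(A - A0) * dA/dr_v, dA/dr = 0.5*(y+ - y-, x- - x+)
    coefA = -(areas - tissue.natural_area)[cc]
    fx = coefA * 0.5 * (q[:, 1] - r[:, 1])
    fy = coefA * 0.5 * (r[:, 0] - q[:, 0])

    # tension + perimeter elasticity act along each directed edge v -> next
    u = (q - p) / elen[:, None]
    coefE = cache.corner_lam + (tissue.gam * perim)[cc]
    tx = coefE * u[:, 0]
    ty = coefE * u[:, 1]
    fx += tx
    fy += ty
    nv = tissue.n_vertices
    nxt_v = cv[cache.nxt]
    out_x = (np.bincount(cv, weights=fx, minlength=nv)
             - np.bincount(nxt_v, weights=tx, minlength=nv))
    out_y = (np.bincount(cv, weights=fy, minlength=nv)
             - np.bincount(nxt_v, weights=ty, minlength=nv))
    forces = np.column_stack([out_x, out_y])

    edge_len = np.zeros(cache.n_edges)
    edge_len[cache.edge_id] = elen
    return forces, areas, perim, edge_len, elen


def compute_forces(tissue: Tissue, config: SimConfig) -> np.ndarray:
    """Analytic force -dU/dr_i on every vertex, shape (Nv, 2)."""
    return forces_and_geometry(tissue, config)[0]


def step(tissue: Tissue, config: SimConfig, dt: Optional[float] = None,
         forces: Optional[np.ndarray] = None) -> Tissue:
    """One explicit-Euler step of the overdamped vertex dynamics (in place)."""
    if dt is None:
        dt = config.dt
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if forces is None:
        forces = compute_forces(tissue, config)
    tissue.vertices += (dt / config.eta) * forces
    return tissue


def relax(tissue: Tissue, config: SimConfig, force_tol: float = 1e-3,
          max_steps: int = 5000) -> Tuple[Tissue, bool, int]:
    """Iterate vertex dynamics until the max vertex force drops below tolerance.

    Returns (tissue, converged, n_steps).  Under the quasi-static assumption
    the tissue between division events sits near such a relaxed state.
    """
    n = 0
    while n < max_steps:
        f = compute_forces(tissue, config)
        fmax = float(np.max(np.hypot(f[:, 0], f[:, 1]))) if f.size else 0.0
        if fmax < force_tol:
            return tissue, True, n
        step(tissue, config, forces=f)
        n += 1
    warnings.warn(f"relax did not converge in {max_steps} steps")
    return tissue, False, n
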