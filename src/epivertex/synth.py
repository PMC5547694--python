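"""Initial-tissue generation, toy fixture meshes, and parameter sweeps.

``generate_initial_tissue`` builds the starting ~250-cell disc: blue-noise
points in a disc, a Voronoi tessellation bounded by mirroring the generators
across the disc edge (so adjacent cells share vertices exactly), a few Lloyd
iterations to even out cell sizes, rescaling to unit mean area, and a
mechanical relaxation to the model's quasi-static state.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import Voronoi

from .config import SimConfig
from .tissue import Tissue, relax

__all__ = [
    "generate_initial_tissue",
    "regular_hexagon",
    "two_unit_squares",
    "hexagonal_patch",
    "four_cell_cross",
    "sweep",
]


# ----------------------------------------------------------------- generation

def _disc_points(n: int, radius: float, rng: np.random.Generator,
                 oversample: int = 30) -> np.ndarray:
    """Approximate blue-noise sample: greedy thinning of uniform candidates."""
    m = n * oversample
    r = radius * np.sqrt(rng.uniform(0, 1, m))
    th = rng.uniform(0, 2 * math.pi, m)
    cand = np.column_stack([r * np.cos(th), r * np.sin(th)])
    min_d = 0.7 * radius * math.sqrt(2.0 / n)   # a bit below hex packing
    chosen = [cand[0]]
    for p in cand[1:]:
        arr = np.asarray(chosen)
        if np.min(np.hypot(arr[:, 0] - p[0], arr[:, 1] - p[1])) >= min_d:
            chosen.append(p)
            if len(chosen) == n:
                break
    while len(chosen) < n:   # fall back to plain uniform fill
        r = radius * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        chosen.append(np.array([r * math.cos(th), r * math.sin(th)]))
    return np.asarray(chosen)


def _mirror(points: np.ndarray, radius: float) -> np.ndarray:
    """Reflect generators radially across the disc boundary.

    Bounds the Voronoi cells of the originals, so each interior region is
    finite and neighbouring cells share Voronoi vertices exactly.
    """
    d = np.hypot(points[:, 0], points[:, 1])
    d = np.maximum(d, 1e-9)
    scale = (2 * radius - d) / d
    return points * scale[:, None]


def _bounded_voronoi(points: np.ndarray, radius: float):
    vor = Voronoi(np.vstack([points, _mirror(points, radius)]))
    cells = []
    for i in range(points.shape[0]):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise RuntimeError("unbounded Voronoi region despite mirroring")
        poly = np.asarray(region, dtype=np.int64)
        pts = vor.vertices[poly]
        # enforce counter-clockwise orientation
        q = np.roll(pts, -1, axis=0)
        if 0.5 * np.sum(pts[:, 0] * q[:, 1] - q[:, 0] * pts[:, 1]) < 0:
            poly = poly[::-1]
        cells.append(poly)
    return vor.vertices, cells


def _merge_short_edges(vertices: np.ndarray, cells, tol: float):
    """Collapse edges shorter than tol to their midpoints (Voronoi slivers)."""
    parent = np.arange(vertices.shape[0])

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for c in cells:
        pts = vertices[c]
        q = np.roll(c, -1)
        d = np.hypot(*(vertices[q] - pts).T)
        for k in np.flatnonzero(d < tol):
            a, b = find(c[k]), find(q[k])
            if a != b:
                vertices[a] = 0.5 * (vertices[a] + vertices[b])
                parent[b] = a
    new_cells = []
    for c in cells:
        mapped = [find(v) for v in c]
        out = []
        for v in mapped:
            if not out or out[-1] != v:
                out.append(v)
        while len(out) > 1 and out[0] == out[-1]:
            out.pop()
        new_cells.append(np.asarray(out, dtype=np.int64))
    return vertices, new_cells


def generate_initial_tissue(n_cells: int = 250,
                            seed: Optional[int] = None,
                            rng: Optional[np.random.Generator] = None,
                            config: Optional[SimConfig] = None,
                            lloyd_iters: int = 4,
                            relax_tol: float = 2e-3,
                            relax_steps: int = 12000) -> Tissue:
    """A roughly circular, mechanically relaxed tissue of ``n_cells`` cells.

    The mesh is built at unit mean cell area and then relaxed to the model's
    quasi-static state; under line tension and contractility the relaxed
    cells settle somewhat below the natural area (about 0.5 at the reference
    parameters).  Deterministic for a given seed / generator.
    """
    if n_cells < 7:
        raise ValueError("need at least 7 cells")
    rng = rng if rng is not None else np.random.default_rng(seed)
    config = config or SimConfig()
    radius = math.sqrt(n_cells / math.pi)
    pts = _disc_points(n_cells, radius, rng)
    verts, cells = None, None
    for _ in range(lloyd_iters):
        verts, cells = _bounded_voronoi(pts, radius)
        # Lloyd: move each generator to its cell centroid, re-clamped to disc
        new_pts = np.empty_like(pts)
        for i, c in enumerate(cells):
            p = verts[c]
            q = np.roll(p, -1, axis=0)
            cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
            a = 0.5 * cross.sum()
            new_pts[i] = (p + q).T @ cross / (6 * a) if abs(a) > 1e-12 \
                else p.mean(axis=0)
        d = np.hypot(new_pts[:, 0], new_pts[:, 1])
        too_far = d > 0.999 * radius
        new_pts[too_far] *= (0.999 * radius / d[too_far])[:, None]
        pts = new_pts
    verts, cells = _bounded_voronoi(pts, radius)
    verts = verts.copy()
    verts, cells = _merge_short_edges(verts, cells,
                                      tol=0.35 * config.theta_T1)

    tissue = Tissue(verts, cells, lam=config.lam0, gam=config.gam0)
    from .growth import _compact_vertices, split_rosettes
    _compact_vertices(tissue)
    split_rosettes(tissue, config)   # edge merges can leave 4-way junctions

    a = tissue.areas()
    tissue.vertices /= math.sqrt(float(np.mean(a)))
    tissue.invalidate()
    relax(tissue, config, force_tol=relax_tol, max_steps=relax_steps)
    # relaxation under tension shrinks cells slightly; rescale to unit mean
    tissue.vertices /= math.sqrt(float(np.mean(tissue.areas())))
    tissue.invalidate()
    relax(tissue, config, force_tol=relax_tol, max_steps=relax_steps // 2)
    tissue.validate(config)
    return tissue


# ------------------------------------------------------------------- fixtures

def regular_hexagon(area: float = 1.0, center=(0.0, 0.0),
                    lam: float = 0.14, gam: float = 0.04) -> Tissue:
    """A single regular hexagonal cell of the given area."""
    s = math.sqrt(2.0 * area / (3.0 * math.sqrt(3.0)))
    ang = np.arange(6) * math.pi / 3.0
    verts = np.column_stack([s * np.cos(ang), s * np.sin(ang)]) + center
    return Tissue(verts, [np.arange(6)], lam=lam, gam=gam)


def two_unit_squares(lam: float = 0.14, gam: float = 0.04) -> Tissue:
    """Two unit squares sharing a vertical edge (7 unit edges in total)."""
    verts = np.array([
        [0, 0], [1, 0], [1, 1], [0, 1],   # left square
        [2, 0], [2, 1],                   # right square extras
    ], dtype=float)
    cells = [np.array([0, 1, 2, 3]), np.array([1, 4, 5, 2])]
    return Tissue(verts, cells, lam=lam, gam=gam)


def hexagonal_patch(rings: int = 2, edge_len: float = 0.62,
                    lam: float = 0.14, gam: float = 0.04) -> Tissue:
    """A honeycomb patch of cells: 1 + 3 rings (rings+1) hexagons."""
    s = edge_len
    centers = []
    for qa in range(-rings, rings + 1):
        for ra in range(-rings, rings + 1):
            if abs(qa + ra) <= rings:
                cx = s * math.sqrt(3) * (qa + ra / 2.0)
                cy = s * 1.5 * ra
                centers.append((cx, cy))
    ang = np.arange(6) * math.pi / 3.0 + math.pi / 6.0
    corner = np.column_stack([s * np.cos(ang), s * np.sin(ang)])
    vert_map = {}
    verts = []
    cells = []
    for cx, cy in centers:
        cyc = []
        for dx, dy in corner:
            key = (round((cx + dx) * 1e6), round((cy + dy) * 1e6))
            if key not in vert_map:
                vert_map[key] = len(verts)
                verts.append((cx + dx, cy + dy))
            cyc.append(vert_map[key])
        cells.append(np.asarray(cyc, dtype=np.int64))
    return Tissue(np.asarray(verts, float), cells, lam=lam, gam=gam)


def four_cell_cross(short_len: float = 0.05, lam: float = 0.14,
                    gam: float = 0.04) -> Tissue:
    """The canonical 4-cell T1 configuration with a central short edge."""
    h = short_len / 2.0
    verts = np.array([
        [-1, -1], [1, -1], [1, 1], [-1, 1],    # outer corners
        [0, -h], [0, h],                        # central short edge
    ], dtype=float)
    cells = [
        np.array([0, 4, 5, 3]),   # west
        np.array([1, 2, 5, 4]),   # east
        np.array([0, 1, 4]),      # south
        np.array([2, 3, 5]),      # north
    ]
    return Tissue(verts, cells, lam=lam, gam=gam)


# ---------------------------------------------------------------------- sweep

def sweep(config_template: SimConfig, param_name: str,
          values: Sequence[float], replicates: int = 1,
          n_target: int = 600, n_initial: int = 250,
          seed: int = 0, window_cells: int = 125):
    """One-parameter response sweep: grow a tissue per value x replicate.

    Returns a pandas DataFrame with one row per run: the parameter value, the
    temporal-mean elimination rate, realised tissue fitness, CV of interior
    cell size, and variance of interior stress magnitude.
    """
    import dataclasses

    import pandas as pd

    from .fitness import elimination_rate, tissue_fitness
    from .growth import run_growth
    from .stress import geometry_stats

    allowed = {"lam0", "gam0", "theta_T1", "kappa", "mu"}
    if param_name not in allowed:
        raise ValueError(f"param_name must be one of {sorted(allowed)}")
    rows = []
    base_seed = np.random.SeedSequence(seed)
    run_seeds = base_seed.spawn(len(values) * max(replicates, 1))
    k = 0
    for value in values:
        for rep in range(max(replicates, 1)):
            cfg = dataclasses.replace(config_template,
                                      **{param_name: float(value)})
            rng = np.random.default_rng(run_seeds[k])
            k += 1
            try:
                res = run_growth(cfg, n_target=n_target, n_initial=n_initial,
                                 rng=rng)
            except Exception as exc:   # record the failure, keep sweeping
                rows.append(dict(param=param_name, value=value, rep=rep,
                                 eps=np.nan, phi=np.nan, cv_size=np.nan,
                                 var_stress=np.nan, error=str(exc)))
                continue
            _, eps_mean = elimination_rate(res.log, window_cells=window_cells)
            times, sizes = res.log.size_series()
            phi = float(np.nanmean(tissue_fitness(times, sizes)))
            gs = geometry_stats(res.tissue, cfg)
            rows.append(dict(param=param_name, value=value, rep=rep,
                             eps=eps_mean, phi=phi,
                             cv_size=gs["cv_size"],
                             var_stress=gs["var_stress"], error=""))
    return pd.DataFrame(rows)
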