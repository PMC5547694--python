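"""Per-cell stress tensors and geometric/mechanical tissue statistics.

Two discrete representations of the Cauchy stress of a polygonal cell are
provided.  Method A integrates the outer product of the (linearly
interpolated) vertex forces with position around the cell boundary; method B
sums pressure and edge-tension dyads:

    sigma_A = (1/A) sym( sum_edges integral_0^1 F(l) x r(l) dl )
    sigma_B = -P I + sum_edges (T/A) (r_ij x r_ij)/|r_ij|

with cell pressure P = -(A - A0) and per-cell edge-tension share
T = Lam_eff/2 + Gam L.  Both are symmetric 2x2 tensors; the scalars reported
are the stress magnitude sigma1+sigma2 (trace; positive = tensile) and the
stress anisotropy sigma1-sigma2, plus the direction of the maximum principal
stress.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import SimConfig
from .growth import EventLog, shortest_axis, _polygon_centroid
from .tissue import Tissue, MeshError

__all__ = [
    "CellStress",
    "cell_pressure",
    "edge_tension",
    "stress_tensor_A",
    "stress_tensor_B",
    "stress_tensors_B_all",
    "principal_decomposition",
    "geometry_stats",
    "stress_geometry_correlations",
    "circular_correlation",
    "local_stress_change",
    "local_density_cv_change",
    "regional_stats",
    "morans_I",
]


@dataclass
class CellStress:
    tensor: np.ndarray
    sigma1: float
    sigma2: float
    magnitude: float       # sigma1 + sigma2
    anisotropy: float      # sigma1 - sigma2  (>= 0)
    orientation: float     # direction of max principal stress, in [0, pi)
    method: str = "B"
    degenerate: bool = False


def cell_pressure(area: float, natural_area: float = 1.0) -> float:
    """P = -dU/dA = -(A - A0): compressed cells (A < A0) push outward."""
    return -(area - natural_area)


def edge_tension(lam_eff: float, gam: float, perimeter: float) -> float:
    """Per-cell share of an edge's tension: T = Lam_eff/2 + Gam L."""
    return 0.5 * lam_eff + gam * perimeter


def principal_decomposition(tensor: np.ndarray,
                            tol: float = 1e-10) -> Tuple[float, float, float, bool]:
    """(sigma1, sigma2, orientation, degenerate) of a symmetric 2x2 tensor."""
    t = np.asarray(tensor, float)
    w, v = np.linalg.eigh(0.5 * (t + t.T))
    s1, s2 = float(w[1]), float(w[0])
    if s1 - s2 < tol:
        return s1, s2, 0.0, True
    e = v[:, 1]
    return s1, s2, math.atan2(e[1], e[0]) % math.pi, False


def _cell_edge_shares(tissue: Tissue, config: SimConfig, idx: int):
    """Positions (centroid frame), per-edge tension shares, pressure for a cell."""
    cache = tissue.mesh_cache(config)
    cyc = tissue.cells[idx]
    pts = tissue.vertices[cyc]
    centroid = _polygon_centroid(pts)
    r = pts - centroid
    q = np.roll(pts, -1, axis=0)
    cross = pts[:, 0] * q[:, 1] - q[:, 0] * pts[:, 1]
    area = 0.5 * cross.sum()
    if area <= 1e-12:
        raise MeshError("degenerate cell")
    perim = float(np.sum(np.hypot(*(q - pts).T)))
    # per-edge effective line tension from the cached per-corner coefficients
    start = cache.starts[idx]
    n = len(cyc)
    lam_half = cache.corner_lam[start:start + n]   # Lam_eff/2 (full if boundary)
    t_share = lam_half + tissue.gam[idx] * perim
    pressure = cell_pressure(area, tissue.natural_area[idx])
    return r, t_share, pressure, area, perim


def stress_tensor_A(tissue: Tissue, config: SimConfig, idx: int) -> CellStress:
    """Boundary-integral stress tensor of one cell (vertex-force based).

    Vertex forces follow the pressure + two-edge-tension decomposition: the
    pressure acts along the outward normal of the segment joining the two
    neighbours of the vertex, scaled by half that segment's length (so the
    pressure contributions integrate P over the cell boundary), and tensions
    pull along the two incident edges.
    """
    r, t_share, pressure, area, _ = _cell_edge_shares(tissue, config, idx)
    n = len(r)
    nxt = np.roll(np.arange(n), -1)
    prv = np.roll(np.arange(n), 1)
    # tension force on vertex i from edge (i, j): t * (r_j - r_i)/|..|
    F = np.zeros_like(r)
    for i in range(n):
        j, k = nxt[i], prv[i]
        d_j = r[j] - r[i]
        d_k = r[k] - r[i]
        F[i] += t_share[i] * d_j / np.linalg.norm(d_j)
        F[i] += t_share[k] * d_k / np.linalg.norm(d_k)
        seg = r[j] - r[k]                       # prev -> next, CCW sense
        normal = np.array([seg[1], -seg[0]])    # outward for CCW polygons
        F[i] += pressure * 0.5 * normal
    # closed-form edge integral of the linear interpolation F(l) x r(l)
    M = np.zeros((2, 2))
    for i in range(n):
        j = nxt[i]
        M += (np.outer(F[i], r[i]) + np.outer(F[j], r[j])) / 3.0
        M += (np.outer(F[i], r[j]) + np.outer(F[j], r[i])) / 6.0
    # the minus sign makes the convention match method B: tension positive,
    # compression negative (F here is the force exerted ON the boundary)
    tensor = -0.5 * (M + M.T) / area
    s1, s2, ori, deg = principal_decomposition(tensor)
    return CellStress(tensor=tensor, sigma1=s1, sigma2=s2, magnitude=s1 + s2,
                      anisotropy=s1 - s2, orientation=ori, method="A",
                      degenerate=deg)


def stress_tensor_B(tissue: Tissue, config: SimConfig, idx: int,
                    tension_total: bool = False) -> CellStress:
    """Pressure + edge-dyad stress tensor of one cell.

    By default each edge contributes the cell's own tension share
    T = Lam_eff/2 + Gam L; with ``tension_total`` the full edge tension
    (both incident cells' shares) is used instead.
    """
    r, t_share, pressure, area, _ = _cell_edge_shares(tissue, config, idx)
    q = np.roll(r, -1, axis=0)
    d = q - r
    lens = np.hypot(d[:, 0], d[:, 1])
    t = t_share.copy()
    if tension_total:
        t = 2.0 * t   # identical shares on both sides of each edge
    M = (d[:, :, None] * d[:, None, :] * (t / lens)[:, None, None]).sum(0)
    tensor = -pressure * np.eye(2) + M / area
    s1, s2, ori, deg = principal_decomposition(tensor)
    return CellStress(tensor=tensor, sigma1=s1, sigma2=s2, magnitude=s1 + s2,
                      anisotropy=s1 - s2, orientation=ori, method="B",
                      degenerate=deg)


def stress_tensors_B_all(tissue: Tissue, config: SimConfig) -> np.ndarray:
    """Vectorised method-B tensors for every cell, shape (n_cells, 2, 2)."""
    cache = tissue.mesh_cache(config)
    v = tissue.vertices
    p = v[cache.corner_v]
    q = v[cache.corner_v[cache.nxt]]
    cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
    areas = 0.5 * np.add.reduceat(cross, cache.starts)
    d = q - p
    lens = np.hypot(d[:, 0], d[:, 1])
    perim = np.add.reduceat(lens, cache.starts)
    cc = cache.corner_c
    t_share = cache.corner_lam + (tissue.gam * perim)[cc]
    w = t_share / lens
    xx = np.add.reduceat(w * d[:, 0] * d[:, 0], cache.starts)
    xy = np.add.reduceat(w * d[:, 0] * d[:, 1], cache.starts)
    yy = np.add.reduceat(w * d[:, 1] * d[:, 1], cache.starts)
    pressure = -(areas - tissue.natural_area)
    out = np.empty((tissue.n_cells, 2, 2))
    out[:, 0, 0] = -pressure + xx / areas
    out[:, 0, 1] = out[:, 1, 0] = xy / areas
    out[:, 1, 1] = -pressure + yy / areas
    return out


def _principal_all(tensors: np.ndarray):
    """Vectorised eigendecomposition of symmetric 2x2 tensors."""
    a = tensors[:, 0, 0]
    b = tensors[:, 0, 1]
    c = tensors[:, 1, 1]
    mean = 0.5 * (a + c)
    half = np.sqrt(np.maximum(0.25 * (a - c) ** 2 + b ** 2, 0.0))
    s1 = mean + half
    s2 = mean - half
    ori = 0.5 * np.arctan2(2 * b, a - c) % math.pi
    return s1, s2, ori


# ----------------------------------------------------------------- statistics

def geometry_stats(tissue: Tissue, config: Optional[SimConfig] = None,
                   method: str = "B"):
    """Per-cell geometric and stress table plus interior-cell summaries.

    Returns a dict with keys 'table' (pandas DataFrame: area, shape
    anisotropy, axis orientations, stress scalars, interior flag),
    'cv_size', 'mean_aniso' and 'var_stress' (interior cells only).
    """
    import pandas as pd

    config = config or SimConfig()
    areas = tissue.areas()
    interior = ~tissue.boundary_cells(config)
    aniso = np.empty(tissue.n_cells)
    ang_long = np.empty(tissue.n_cells)
    for i, c in enumerate(tissue.cells):
        _, aniso[i], ang_long[i] = shortest_axis(tissue.vertices[c])
    if method == "B":
        tensors = stress_tensors_B_all(tissue, config)
    else:
        tensors = np.array([stress_tensor_A(tissue, config, i).tensor
                            for i in range(tissue.n_cells)])
    s1, s2, ori = _principal_all(tensors)
    table = pd.DataFrame(dict(
        area=areas, inv_area=1.0 / areas, shape_aniso=aniso,
        long_axis=ang_long, sigma1=s1, sigma2=s2,
        stress_mag=s1 + s2, stress_aniso=s1 - s2, stress_ori=ori,
        interior=interior, mitotic=tissue.mitotic.astype(bool),
    ))
    sub = table[table.interior]
    return dict(
        table=table,
        cv_size=float(sub.area.std(ddof=0) / sub.area.mean()),
        mean_aniso=float(sub.shape_aniso.mean()),
        var_stress=float(sub.stress_mag.var(ddof=0)),
    )


def circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher-Lee circular correlation for axial data (period pi).

    Angles are doubled to map the axial period onto the circle.
    """
    a = 2.0 * np.asarray(a, float)
    b = 2.0 * np.asarray(b, float)
    abar = math.atan2(np.sin(a).mean(), np.cos(a).mean())
    bbar = math.atan2(np.sin(b).mean(), np.cos(b).mean())
    sa = np.sin(a - abar)
    sb = np.sin(b - bbar)
    denom = math.sqrt(float(np.sum(sa ** 2) * np.sum(sb ** 2)))
    if denom == 0:
        return float("nan")
    return float(np.sum(sa * sb) / denom)


def stress_geometry_correlations(tissue: Tissue,
                                 config: Optional[SimConfig] = None,
                                 method: str = "B",
                                 min_cells: int = 100):
    """Stress-geometry correlations over interior cells.

    Returns (rho_mag_area, rho_aniso_aniso, rho_dir_dir): Pearson correlation
    of stress magnitude with cell area and of stress anisotropy with shape
    anisotropy, and the circular correlation (period pi) between the maximum
    principal stress direction and the shape long axis.  Boundary cells are
    excluded, and so are cells in the mitotic swelling phase: their stress
    carries the programmed natural-area offset, which is not a crowding
    signal, so they are transient outliers in the stress-geometry relation.
    """
    config = config or SimConfig()
    stats = geometry_stats(tissue, config, method=method)
    sub = stats["table"]
    sub = sub[sub.interior & ~sub.mitotic]
    if len(sub) < min_cells:
        raise ValueError(f"need at least {min_cells} interior cells, "
                         f"got {len(sub)}")
    rho_mag = float(np.corrcoef(sub.stress_mag, sub.area)[0, 1])
    rho_aniso = float(np.corrcoef(sub.stress_aniso, sub.shape_aniso)[0, 1])
    rho_dir = circular_correlation(sub.stress_ori.to_numpy(),
                                   sub.long_axis.to_numpy())
    return rho_mag, rho_aniso, rho_dir


# ------------------------------------------------------------- event locality

def local_stress_change(log: EventLog) -> dict:
    """Mean ring-1 change in stress magnitude across events, by event kind.

    Uses the before/after values recorded during a run with
    ``run_growth(..., measure_local=True)``.  Division events compress the
    neighbourhood (negative change); eliminations release stress (positive).
    """
    out = {}
    for kind in ("division", "t2"):
        deltas = [e.after_S - e.before_S for e in log.of_kind(kind)
                  if not (math.isnan(e.before_S) or math.isnan(e.after_S))]
        out[kind] = dict(mean=float(np.mean(deltas)) if deltas else
                         float("nan"), n=len(deltas))
    return out


def local_density_cv_change(log: EventLog):
    """Paired CV(1/area) around each elimination, before vs after.

    The "before" neighbourhood includes the dying cell; "after" covers its
    surviving ring-1 neighbours.  Returns (before, after) arrays.
    """
    before, after = [], []
    for e in log.of_kind("t2"):
        if math.isnan(e.before_cv) or math.isnan(e.after_cv):
            continue
        before.append(e.before_cv)
        after.append(e.after_cv)
    return np.asarray(before), np.asarray(after)


# -------------------------------------------------------------------- regions

def _region_of(rel_r: np.ndarray) -> np.ndarray:
    """Concentric region index 0..2 from radius normalised to the rim radius.

    For uniform density, equal-count terciles of a disc lie at radii
    sqrt(1/3) and sqrt(2/3) of the rim.
    """
    r1, r2 = math.sqrt(1.0 / 3.0), math.sqrt(2.0 / 3.0)
    return np.digitize(rel_r, [r1, r2])


def regional_stats(snapshots: Sequence[Tuple[float, Tissue]],
                   log: Optional[EventLog] = None,
                   config: Optional[SimConfig] = None):
    """Temporal averages of density / size CV / event rates in 3 annuli.

    Cells are binned by centroid distance from the tissue centroid into three
    concentric equal-population annuli (center -> periphery) and the per-region
    density (mean inverse cell area) and CV of cell size are averaged over all
    snapshots.  If an event log is supplied, per-region elimination rate
    (eliminations per division) and T1 counts are added, with events assigned
    by their radius relative to the instantaneous tissue rim radius
    sqrt(g(t)/pi).
    """
    import pandas as pd

    config = config or SimConfig()
    acc = {k: [[] for _ in range(3)] for k in ("density", "cv_size")}
    for _, tis in snapshots:
        cent = tis.centroids()
        mid = cent.mean(axis=0)
        rr = np.hypot(*(cent - mid).T)
        reg = np.digitize(rr, np.quantile(rr, [1 / 3, 2 / 3]))  # equal counts
        areas = tis.areas()
        for k in range(3):
            m = reg == k
            if m.sum() >= 3:
                acc["density"][k].append(float(np.mean(1.0 / areas[m])))
                acc["cv_size"][k].append(
                    float(np.std(areas[m]) / np.mean(areas[m])))
    rows = []
    ev_counts = {k: np.zeros(3) for k in ("division", "t2", "t1")}
    if log is not None:
        times, sizes = log.size_series()
        for e in log.events:
            g = float(np.interp(e.time, times, sizes)) if len(times) else 250.0
            rim = math.sqrt(g / math.pi)
            rel = min(math.hypot(*e.location) / rim, 1.0)
            ev_counts[e.kind][int(_region_of(np.array([rel]))[0])] += 1
    for k in range(3):
        row = dict(region=k + 1,
                   density=float(np.mean(acc["density"][k]))
                   if acc["density"][k] else float("nan"),
                   cv_size=float(np.mean(acc["cv_size"][k]))
                   if acc["cv_size"][k] else float("nan"))
        if log is not None:
            ndiv = ev_counts["division"][k]
            row["eps"] = ev_counts["t2"][k] / ndiv if ndiv else float("nan")
            row["t1_count"] = int(ev_counts["t1"][k])
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ Moran's I

def morans_I(tissue: Tissue, values: np.ndarray,
             config: Optional[SimConfig] = None):
    """Moran's spatial autocorrelation of a per-cell quantity.

    Binary (unnormalised) weights on the cell-adjacency graph.  Returns nan
    for constant input (the index is undefined there).
    """
    config = config or SimConfig()
    x = np.asarray(values, float)
    if x.size != tissue.n_cells:
        raise ValueError("one value per cell required")
    z = x - x.mean()
    denom = float(np.sum(z ** 2))
    if denom == 0:
        return float("nan")
    cache = tissue.mesh_cache(config)
    internal = ~cache.edge_boundary
    pairs = cache.edge_cells[internal]
    pairs = np.unique(np.sort(pairs, axis=1), axis=0)  # one weight per pair
    # each unordered neighbour pair contributes twice to W and the numerator
    num = 2.0 * float(np.sum(z[pairs[:, 0]] * z[pairs[:, 1]]))
    w_total = 2.0 * pairs.shape[0]
    n = tissue.n_cells
    return float((n / w_total) * num / denom)
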