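"""Cell cycle, division, T1 rearrangement, T2 elimination, and the growth loop.

Division follows Hertwig's rule with tunable noise: the cleavage plane passes
through the cell centroid along the shortest axis of the vertex-set ellipse,
perturbed by a von Mises-distributed angle with concentration ``kappa``
(kappa=0 gives uniformly random orientation).  An edge shorter than
``theta_T1`` is reconnected (T1 process); a cell whose area drops below
``theta_T2`` collapses to a vertex and disappears (T2 process) -- the model's
mechanical cell elimination event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .config import SimConfig, FeedbackConfig
from .tissue import (Tissue, MeshError, compute_energy, forces_and_geometry,
                     step as euler_step)

__all__ = [
    "Event", "EventLog", "RunResult",
    "advance_clocks", "shortest_axis", "sample_division_axis",
    "divide_cell", "apply_T1", "apply_T2", "split_rosettes", "run_growth",
]


# --------------------------------------------------------------------- events

@dataclass
class Event:
    kind: str                  # "division" | "t1" | "t2"
    time: float
    cell_uid: int
    location: Tuple[float, float]
    parent_trait: int = -1
    daughter_uids: Tuple[int, ...] = ()
    daughter_traits: Tuple[int, ...] = ()
    last_area: float = float("nan")
    # event-local stress / density bookkeeping (filled when measuring)
    before_S: float = float("nan")
    after_S: float = float("nan")
    before_cv: float = float("nan")
    after_cv: float = float("nan")


class EventLog:
    """Ordered event records plus the tissue-size time series."""

    def __init__(self) -> None:
        self.events: List[Event] = []
        self.times: List[float] = []
        self.sizes: List[int] = []
        self.trait_times: List[float] = []
        self.trait_counts: List[np.ndarray] = []

    def add(self, ev: Event) -> None:
        if self.events and ev.time < self.events[-1].time - 1e-9:
            raise ValueError("event times must be non-decreasing")
        self.events.append(ev)

    def record_size(self, t: float, n: int) -> None:
        self.times.append(t)
        self.sizes.append(n)

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e.kind == kind)

    def of_kind(self, kind: str) -> List[Event]:
        return [e for e in self.events if e.kind == kind]

    def size_series(self) -> Tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.times), np.asarray(self.sizes, dtype=float)

    def trait_series(self) -> Tuple[np.ndarray, np.ndarray]:
        """(times, counts[t, trait]) for mixed-population runs."""
        return (np.asarray(self.trait_times),
                np.vstack(self.trait_counts) if self.trait_counts
                else np.empty((0, 0)))

    def to_table(self):
        """Events as a pandas DataFrame (time, kind, cell, x, y, trait, area)."""
        import pandas as pd

        rows = [dict(time=e.time, kind=e.kind, cell_uid=e.cell_uid,
                     x=e.location[0], y=e.location[1], trait=e.parent_trait,
                     area=e.last_area, before_S=e.before_S, after_S=e.after_S,
                     before_cv=e.before_cv, after_cv=e.after_cv)
                for e in self.events]
        return pd.DataFrame(rows)


@dataclass
class RunResult:
    tissue: Tissue
    log: EventLog
    config: SimConfig
    t_end: float
    S_bar_init: float = float("nan")
    snapshots: list = field(default_factory=list)   # (time, Tissue) pairs
    aborted: bool = False


# ----------------------------------------------------------------- cell cycle

def advance_clocks(tissue: Tissue, dt: float,
                   gate: Optional[np.ndarray] = None) -> np.ndarray:
    """Advance cell-cycle clocks linearly in time; return cells that are due.

    ``gate`` is a per-cell clock-rate multiplier (1 everywhere by default;
    the stress-gated feedback sets it to 0 for compressed cells).  Mitotic
    cells are frozen: their progression is the natural-area ramp instead.
    """
    active = ~tissue.mitotic
    if gate is None:
        rate = np.ones(tissue.n_cells)
    else:
        rate = np.asarray(gate, float)
        if rate.size < tissue.n_cells:   # cells born since the last gate update
            rate = np.concatenate([rate, np.ones(tissue.n_cells - rate.size)])
        elif rate.size > tissue.n_cells:
            rate = rate[: tissue.n_cells]
    tissue.clock[active] += rate[active] * dt
    due = np.flatnonzero(active & (tissue.clock >= tissue.cycle_len))
    return due


def _draw_cycle_len(config: SimConfig, rng: np.random.Generator,
                    size: Optional[int] = None):
    tbar = config.cycle_len_mean
    j = config.cycle_jitter
    return rng.uniform(tbar * (1 - j), tbar * (1 + j), size=size)


# ------------------------------------------------------------- cell geometry

def shortest_axis(points: np.ndarray) -> Tuple[float, float, float]:
    """Elliptical approximation of a cell from its vertex positions.

    Returns (short_axis_angle, anisotropy, long_axis_angle) where anisotropy
    is 1 - (shortest axis length / longest axis length) and angles are in
    [0, pi).  The ellipse is the second-moment ellipse of the vertex set
    (the tricellular junctions), so axis lengths scale with the square roots
    of the covariance eigenvalues.
    """
    pts = np.asarray(points, float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 vertices")
    d = pts - pts.mean(axis=0)
    cov = d.T @ d / pts.shape[0]
    w, vec = np.linalg.eigh(cov)          # ascending eigenvalues
    if w[1] <= 1e-24:
        return 0.0, 0.0, 0.0
    aniso = 1.0 - math.sqrt(max(w[0], 0.0) / w[1])
    short = vec[:, 0]                     # minor axis of the ellipse
    long_ = vec[:, 1]
    ang_s = math.atan2(short[1], short[0]) % math.pi
    ang_l = math.atan2(long_[1], long_[0]) % math.pi
    return ang_s, aniso, ang_l


def sample_division_axis(short_axis_angle: float, kappa: float,
                         rng: np.random.Generator) -> float:
    """Cleavage-plane angle: shortest axis plus von Mises noise.

    The axis is undirected (period pi), so the deviation is sampled on the
    doubled angle and halved; kappa=0 reduces to a uniformly random axis.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    delta = rng.vonmises(0.0, kappa) / 2.0
    return (short_axis_angle + delta) % math.pi


# ---------------------------------------------------------------- cell lists

def _append_cell_state(tissue: Tissue, *, lam, gam, trait, clock, cycle_len,
                       natural_area=1.0, mitotic=False, premit=1.0) -> int:
    tissue.lam = np.append(tissue.lam, lam)
    tissue.gam = np.append(tissue.gam, gam)
    tissue.trait = np.append(tissue.trait, trait)
    tissue.clock = np.append(tissue.clock, clock)
    tissue.cycle_len = np.append(tissue.cycle_len, cycle_len)
    tissue.natural_area = np.append(tissue.natural_area, natural_area)
    tissue.mitotic = np.append(tissue.mitotic, mitotic)
    tissue.premit_area = np.append(tissue.premit_area, premit)
    tissue.uid = np.append(tissue.uid, tissue.next_uid)
    tissue.next_uid += 1
    return tissue.uid[-1]


def _delete_cell(tissue: Tissue, idx: int) -> None:
    del tissue.cells[idx]
    for name in ("lam", "gam", "trait", "clock", "cycle_len",
                 "natural_area", "mitotic", "premit_area", "uid"):
        setattr(tissue, name, np.delete(getattr(tissue, name), idx))


def _compact_vertices(tissue: Tissue) -> None:
    """Drop vertices no longer referenced by any cell and remap indices."""
    used = np.zeros(tissue.n_vertices, dtype=bool)
    for c in tissue.cells:
        used[c] = True
    if used.all():
        return
    remap = -np.ones(tissue.n_vertices, dtype=np.int64)
    remap[used] = np.arange(int(used.sum()))
    tissue.vertices = tissue.vertices[used]
    tissue.cells = [remap[c] for c in tissue.cells]
    tissue.invalidate()


# ------------------------------------------------------------------- division

def _polygon_centroid(pts: np.ndarray) -> np.ndarray:
    q = np.roll(pts, -1, axis=0)
    cross = pts[:, 0] * q[:, 1] - q[:, 0] * pts[:, 1]
    a = 0.5 * cross.sum()
    if abs(a) < 1e-14:
        return pts.mean(axis=0)
    return (pts + q).T @ cross / (6.0 * a)


def _split_points(pts: np.ndarray, angle: float, min_sep: float = 0.0):
    """Intersections of the centroid line at `angle` with the polygon boundary.

    Returns ((k1, s1), (k2, s2)) edge indices and fractional positions for the
    two crossings bracketing the centroid, or None if the line does not cross
    the boundary cleanly on both sides (pathological concavity).

    ``min_sep`` keeps each crossing point at least that far from the existing
    endpoints of the crossed edge (when the edge is long enough; shorter edges
    get the crossing pushed to their midpoint).  Without this, a crossing that
    lands next to a vertex leaves a sub-threshold edge that immediately fires
    a rearrangement and strips the newborn daughter down to a fragile triangle.
    """
    c = _polygon_centroid(pts)
    u = np.array([math.cos(angle), math.sin(angle)])
    n = len(pts)
    best_pos = None
    best_neg = None
    for k in range(n):
        a = pts[k]
        b = pts[(k + 1) % n]
        e = b - a
        denom = e[0] * u[1] - e[1] * u[0]
        if abs(denom) < 1e-12:
            continue
        w = c - a
        s = (w[0] * u[1] - w[1] * u[0]) / denom
        t = (w[0] * e[1] - w[1] * e[0]) / (-denom)
        if -1e-9 <= s < 1.0 - 1e-9:
            if t > 1e-9 and (best_pos is None or t < best_pos[2]):
                best_pos = (k, s, t)
            elif t < -1e-9 and (best_neg is None or t > best_neg[2]):
                best_neg = (k, s, t)
    if best_pos is None or best_neg is None or best_pos[0] == best_neg[0]:
        return None
    out = []
    for k, s, _t in (best_pos, best_neg):
        elen = float(np.hypot(*(pts[(k + 1) % n] - pts[k])))
        frac = min_sep / elen if elen > 0 else 0.5
        lo, hi = (frac, 1.0 - frac) if frac < 0.5 else (0.5, 0.5)
        s = min(max(s, max(lo, 0.05)), min(hi, 0.95))
        out.append((k, s))
    return tuple(out)


def divide_cell(tissue: Tissue, config: SimConfig, idx: int, angle: float,
                rng: Optional[np.random.Generator] = None,
                trait_fn: Optional[Callable[[int], int]] = None,
                time: float = 0.0) -> Event:
    """Split cell ``idx`` along ``angle`` through its centroid.

    A new edge is inserted between two new vertices placed on the cell
    boundary; each neighbour sharing a split edge gains the corresponding
    vertex.  Daughters restart their cycle with a fresh jittered cycle time;
    traits are assigned by ``trait_fn`` (parent trait kept if absent).
    """
    rng = rng or np.random.default_rng(0)
    cyc = tissue.cells[idx]
    pts = tissue.vertices[cyc]
    min_sep = 1.2 * config.theta_T1
    split = _split_points(pts, angle, min_sep=min_sep)
    tries = 0
    while split is None and tries < 12:
        angle = (angle + rng.uniform(0.2, math.pi - 0.2)) % math.pi
        split = _split_points(pts, angle, min_sep=min_sep)
        tries += 1
    if split is None:
        raise MeshError("division axis does not cross the cell boundary twice")
    (k1, s1), (k2, s2) = split
    n = len(cyc)
    v = tissue.n_vertices
    p1 = pts[k1] + s1 * (pts[(k1 + 1) % n] - pts[k1])
    p2 = pts[k2] + s2 * (pts[(k2 + 1) % n] - pts[k2])
    tissue.vertices = np.vstack([tissue.vertices, p1[None], p2[None]])
    w1, w2 = v, v + 1

    # insert the new vertices into neighbours sharing the split edges
    cache = tissue.mesh_cache(config)
    ev_tab = cache.edge_vertices
    for (k, w) in ((k1, w1), (k2, w2)):
        a, b = int(cyc[k]), int(cyc[(k + 1) % n])
        lo, hi = (a, b) if a < b else (b, a)
        hits = np.flatnonzero((ev_tab[:, 0] == lo) & (ev_tab[:, 1] == hi))
        other = -1
        if hits.size:
            c0, c1 = cache.edge_cells[hits[0]]
            other = int(c1) if int(c0) == idx else int(c0)
        if other >= 0:
            oc = tissue.cells[other]
            m = len(oc)
            for pos in range(m):
                if oc[pos] == b and oc[(pos + 1) % m] == a:
                    tissue.cells[other] = np.insert(oc, pos + 1, w)
                    break

    # daughter vertex cycles
    def arc(k_from: int, k_to: int) -> list:
        out = []
        k = (k_from + 1) % n
        while True:
            out.append(int(cyc[k]))
            if k == k_to:
                break
            k = (k + 1) % n
        return out

    d1 = np.array([w1] + arc(k1, k2) + [w2], dtype=np.int64)
    d2 = np.array([w2] + arc(k2, k1) + [w1], dtype=np.int64)

    parent_uid = int(tissue.uid[idx])
    parent_trait = int(tissue.trait[idx])
    parent_lam = float(tissue.lam[idx])
    parent_gam = float(tissue.gam[idx])
    centroid = _polygon_centroid(pts)

    # first daughter replaces the parent slot
    tissue.cells[idx] = d1
    tissue.clock[idx] = 0.0
    tissue.cycle_len[idx] = _draw_cycle_len(config, rng)
    tissue.natural_area[idx] = 1.0
    tissue.mitotic[idx] = False
    tissue.premit_area[idx] = 1.0
    tissue.uid[idx] = tissue.next_uid
    tissue.next_uid += 1
    uid1 = int(tissue.uid[idx])

    tissue.cells.append(d2)
    uid2 = int(_append_cell_state(
        tissue, lam=parent_lam, gam=parent_gam, trait=parent_trait,
        clock=0.0, cycle_len=float(_draw_cycle_len(config, rng)),
    ))

    traits = []
    for di in (idx, tissue.n_cells - 1):
        t_id = parent_trait if trait_fn is None else trait_fn(parent_trait)
        tissue.trait[di] = t_id
        traits.append(t_id)
        if trait_fn is not None and tissue.trait[di] >= 0 and \
                config.trait_grid is not None:
            value = float(np.asarray(config.trait_grid)[t_id])
            if config.trait_target == "lam":
                tissue.lam[di] = value
            else:
                tissue.gam[di] = value

    tissue.invalidate()
    return Event(kind="division", time=time, cell_uid=parent_uid,
                 location=(float(centroid[0]), float(centroid[1])),
                 parent_trait=parent_trait,
                 daughter_uids=(uid1, uid2), daughter_traits=tuple(traits))


# ------------------------------------------------------------------------- T1

def _vertex_cells(tissue: Tissue, v: int) -> List[int]:
    return [i for i, c in enumerate(tissue.cells) if v in c]


def apply_T1(tissue: Tissue, config: SimConfig,
             time: float = 0.0, log: Optional[EventLog] = None) -> int:
    """Reconnect every eligible internal edge shorter than theta_T1.

    The two cells sharing the short edge separate and the two cells at its
    endpoints become neighbours; the new edge is perpendicular to the old one
    with length ``t1_expansion * theta_T1`` so the swap does not immediately
    re-trigger.  Edges on triangles and edges whose endpoints are not simple
    three-way junctions are skipped.

    A short *boundary* edge is handled by the boundary variant of the move:
    the edge collapses to its midpoint, detaching its cell from the tissue rim
    (the two rim neighbours then meet at the merged vertex).  This is how a
    peripheral cell squeezed by the contractile rim escapes into the interior
    instead of being crushed below the elimination threshold.

    Returns the event count.
    """
    n_events = 0
    guard = 0
    while guard < 10 * max(tissue.n_cells, 1):
        guard += 1
        cache = tissue.mesh_cache(config)
        ev = cache.edge_vertices
        d = tissue.vertices[ev[:, 1]] - tissue.vertices[ev[:, 0]]
        lens = np.hypot(d[:, 0], d[:, 1])
        cand = np.flatnonzero(lens < config.theta_T1)
        if cand.size == 0:
            break
        done_any = False
        for e in cand[np.argsort(lens[cand])]:
            vi, vj = (int(x) for x in ev[e])
            if cache.edge_boundary[e]:
                # rim detachment: collapse the boundary edge of cell alpha
                alpha = int(cache.edge_cells[e, 0])
                if len(tissue.cells[alpha]) < 4:
                    continue
                cells_i = _vertex_cells(tissue, vi)
                cells_j = _vertex_cells(tissue, vj)
                if len(cells_i) != 2 or len(cells_j) != 2:
                    continue
                gamma = next(c for c in cells_i if c != alpha)
                delta = next(c for c in cells_j if c != alpha)
                if gamma == delta:
                    continue
                mid = 0.5 * (tissue.vertices[vi] + tissue.vertices[vj])
                tissue.vertices[vi] = mid
                ca = tissue.cells[alpha]
                tissue.cells[alpha] = ca[ca != vj]
                cd = tissue.cells[delta]
                tissue.cells[delta] = np.where(cd == vj, vi, cd)
                tissue.invalidate()
                n_events += 1
                done_any = True
                if log is not None:
                    log.add(Event(kind="t1", time=time, cell_uid=int(
                        tissue.uid[alpha]), location=(float(mid[0]),
                                                      float(mid[1]))))
                break   # topology changed; rescan
            alpha, beta = (int(x) for x in cache.edge_cells[e])
            if len(tissue.cells[alpha]) < 4 or len(tissue.cells[beta]) < 4:
                continue
            bi = vi in cache.boundary_vertices
            bj = vj in cache.boundary_vertices
            if bi and bj:
                continue
            if bi or bj:
                # lateral rim edge: one endpoint on the boundary.  The swap
                # lets the interior cell at the other endpoint intercalate
                # into the rim, relieving the squeezed peripheral cells.
                if bj:
                    vi, vj = vj, vi
                cells_i = _vertex_cells(tissue, vi)
                cells_j = _vertex_cells(tissue, vj)
                if len(cells_i) != 2 or len(cells_j) != 3:
                    continue
                delta = next(c for c in cells_j if c not in (alpha, beta))
                ca = tissue.cells[alpha]
                pos_i = int(np.flatnonzero(ca == vi)[0])
                if ca[(pos_i + 1) % len(ca)] != vj:
                    alpha, beta = beta, alpha
                    ca = tissue.cells[alpha]
                cb = tissue.cells[beta]
                # alpha drops j, beta drops i, delta gains i before j; the
                # old edge becomes a new boundary edge of delta
                tissue.cells[alpha] = ca[ca != vj]
                tissue.cells[beta] = cb[cb != vi]
                cd = tissue.cells[delta]
                pos = int(np.flatnonzero(cd == vj)[0])
                tissue.cells[delta] = np.insert(cd, pos, vi)
                ri, rj = tissue.vertices[vi], tissue.vertices[vj]
                mid = 0.5 * (ri + rj)
                t = rj - ri
                norm = math.hypot(t[0], t[1])
                perp = (np.array([-t[1], t[0]]) / norm if norm > 1e-14
                        else np.array([1.0, 0.0]))
                ca_cent = _polygon_centroid(
                    tissue.vertices[tissue.cells[alpha]])
                if np.dot(perp, ca_cent - mid) < 0:
                    perp = -perp
                half = 0.5 * config.t1_expansion * config.theta_T1
                tissue.vertices[vi] = mid + half * perp
                tissue.vertices[vj] = mid - half * perp
                tissue.invalidate()
                n_events += 1
                done_any = True
                if log is not None:
                    log.add(Event(kind="t1", time=time, cell_uid=int(
                        tissue.uid[alpha]), location=(float(mid[0]),
                                                      float(mid[1]))))
                break   # topology changed; rescan
            cells_i = _vertex_cells(tissue, vi)
            cells_j = _vertex_cells(tissue, vj)
            if len(cells_i) != 3 or len(cells_j) != 3:
                continue
            gamma = next(c for c in cells_i if c not in (alpha, beta))
            delta = next(c for c in cells_j if c not in (alpha, beta))
            if gamma == delta:
                continue
            # orient: alpha is the cell traversing i -> j
            ca = tissue.cells[alpha]
            pos_i = int(np.flatnonzero(ca == vi)[0])
            if ca[(pos_i + 1) % len(ca)] != vj:
                alpha, beta = beta, alpha
                gamma, delta = (next(c for c in cells_i
                                     if c not in (alpha, beta)),
                                next(c for c in cells_j
                                     if c not in (alpha, beta)))
                ca = tissue.cells[alpha]
            cb = tissue.cells[beta]

            # topology: alpha drops j, beta drops i, gamma gains j before i,
            # delta gains i before j
            tissue.cells[alpha] = ca[ca != vj]
            tissue.cells[beta] = cb[cb != vi]
            cg = tissue.cells[gamma]
            pos = int(np.flatnonzero(cg == vi)[0])
            tissue.cells[gamma] = np.insert(cg, pos, vj)
            cd = tissue.cells[delta]
            pos = int(np.flatnonzero(cd == vj)[0])
            tissue.cells[delta] = np.insert(cd, pos, vi)

            # geometry: rotate the edge 90 degrees about its midpoint and
            # stretch it; vertex i stays with alpha, j with beta
            ri, rj = tissue.vertices[vi], tissue.vertices[vj]
            mid = 0.5 * (ri + rj)
            t = rj - ri
            norm = math.hypot(t[0], t[1])
            perp = (np.array([-t[1], t[0]]) / norm if norm > 1e-14
                    else np.array([1.0, 0.0]))
            ca_cent = _polygon_centroid(tissue.vertices[tissue.cells[alpha]])
            if np.dot(perp, ca_cent - mid) < 0:
                perp = -perp
            half = 0.5 * config.t1_expansion * config.theta_T1
            tissue.vertices[vi] = mid + half * perp
            tissue.vertices[vj] = mid - half * perp
            tissue.invalidate()
            n_events += 1
            done_any = True
            if log is not None:
                log.add(Event(kind="t1", time=time, cell_uid=int(
                    tissue.uid[alpha]), location=(float(mid[0]),
                                                  float(mid[1]))))
            break   # topology changed; rescan
        if not done_any:
            break
    return n_events


# -------------------------------------------------------------------- rosettes

def _split_vertex(tissue: Tissue, config: SimConfig, v: int,
                  cells: List[int], boundary: bool = False) -> bool:
    """Split an over-connected vertex into two junctions joined by an edge.

    Eliminations collapse a polygon onto a single vertex, leaving a rosette
    (one vertex shared by 4+ cells, or 3+ on the tissue rim, where a regular
    junction has only 2).  Rosettes jam rearrangement -- the T1 eligibility
    test requires simple junctions -- so they are resolved the standard way:
    one incident cell detaches onto its own junction, and the two cells
    flanking it gain the short new edge.  Among the possible detaching cells
    the one giving the lowest total energy is used.  On the rim the detached
    cell moves inward and the original vertex stays on the boundary.

    Returns True when a split was performed.
    """
    pos = tissue.vertices[v].copy()
    cents = np.array([_polygon_centroid(tissue.vertices[tissue.cells[c]])
                      for c in cells])
    ang = np.arctan2(cents[:, 1] - pos[1], cents[:, 0] - pos[0])
    order = np.argsort(ang)
    if boundary:
        # rotate the ordering so the outside gap sits between the last and
        # the first cell of the fan; only fan-interior cells may detach
        a_sorted = ang[order]
        gaps = np.diff(np.concatenate([a_sorted,
                                       [a_sorted[0] + 2 * math.pi]]))
        g = int(np.argmax(gaps))
        order = np.roll(order, -(g + 1))
    ring = [cells[i] for i in order]
    k = len(ring)
    picks = range(1, k - 1) if boundary else range(k)
    half = 0.5 * config.t1_expansion * config.theta_T1

    best = None
    for pick in picks:
        c0 = ring[pick]
        cL = ring[(pick - 1) % k]
        cR = ring[(pick + 1) % k]
        others = [c for c in ring if c not in (c0, cL, cR)]
        u = cents[order[pick]] - pos
        nu = np.hypot(*u)
        if nu < 1e-12:
            continue
        u = u / nu
        trial = tissue.copy()
        w = trial.n_vertices
        if boundary:
            # w (and the rim cells that keep it) stays on the boundary
            w_pos, v_pos = pos, pos + 2 * half * u
        else:
            w_pos, v_pos = pos - half * u, pos + half * u
        trial.vertices = np.vstack([trial.vertices, w_pos[None]])
        trial.vertices[v] = v_pos
        ok = True
        for c in others:
            cyc = trial.cells[c]
            trial.cells[c] = np.where(cyc == v, w, cyc)
        for c in (cL, cR):
            cyc = trial.cells[c]
            p = int(np.flatnonzero(cyc == v)[0])
            best_area, best_cyc = -np.inf, None
            for pair in ((v, w), (w, v)):
                cand = np.concatenate([cyc[:p], pair, cyc[p + 1:]])
                pts = trial.vertices[cand]
                q = np.roll(pts, -1, axis=0)
                area = 0.5 * np.sum(pts[:, 0] * q[:, 1] - q[:, 0] * pts[:, 1])
                if area > best_area:
                    best_area, best_cyc = area, cand
            if best_cyc is None or best_area <= 0:
                ok = False
                break
            trial.cells[c] = best_cyc.astype(np.int64)
        if not ok:
            continue
        trial.invalidate()
        try:
            e = compute_energy(trial, config)
        except MeshError:
            continue
        if np.min(trial.areas()) <= 0:
            continue
        if best is None or e < best[0]:
            best = (e, trial)
    if best is None:
        return False
    _, trial = best
    tissue.vertices = trial.vertices
    tissue.cells = trial.cells
    tissue.invalidate()
    return True


def split_rosettes(tissue: Tissue, config: SimConfig) -> int:
    """Resolve every over-connected vertex; returns the split count.

    Interior vertices shared by 4+ cells and rim vertices shared by 3+ cells
    (a regular rim junction has 2) are split until none remain.
    """
    n_split = 0
    guard = 0
    skip: set = set()
    while guard < 4 * max(tissue.n_cells, 8):
        guard += 1
        incid: dict = {}
        for ci, c in enumerate(tissue.cells):
            for vv in np.unique(c):
                incid.setdefault(int(vv), []).append(ci)
        try:
            bset = set(int(b) for b in
                       tissue.mesh_cache(config).boundary_vertices)
        except MeshError:
            break
        target = None
        for vv, cs in incid.items():
            if vv in skip:
                continue
            if vv in bset:
                if len(cs) >= 3:
                    target = (vv, cs, True)
                    break
            elif len(cs) >= 4:
                target = (vv, cs, False)
                break
        if target is None:
            break
        if not _split_vertex(tissue, config, *target):
            skip.add(target[0])
            continue
        n_split += 1
    return n_split


# ------------------------------------------------------------------------- T2

def _collapse_cell(tissue: Tissue, idx: int) -> None:
    """Collapse cell ``idx`` to a single vertex at its centroid."""
    cyc = tissue.cells[idx]
    centroid = _polygon_centroid(tissue.vertices[cyc])
    w = tissue.n_vertices
    tissue.vertices = np.vstack([tissue.vertices, centroid[None]])
    dead = set(int(v) for v in cyc)
    for j in range(tissue.n_cells):
        if j == idx:
            continue
        c = tissue.cells[j]
        if not dead.intersection(c.tolist()):
            continue
        newc = [w if int(v) in dead else int(v) for v in c]
        # merge consecutive duplicates (cyclically)
        out = []
        for v in newc:
            if not out or out[-1] != v:
                out.append(v)
        while len(out) > 1 and out[0] == out[-1]:
            out.pop()
        tissue.cells[j] = np.array(out, dtype=np.int64)
    _delete_cell(tissue, idx)
    tissue.invalidate()


def apply_T2(tissue: Tissue, config: SimConfig, time: float = 0.0,
             log: Optional[EventLog] = None,
             areas: Optional[np.ndarray] = None) -> List[Event]:
    """Remove every cell whose area has dropped below theta_T2.

    Each such cell is collapsed to a single vertex at its centroid (the
    incident cells inherit that vertex).  A neighbour left with fewer than 3
    distinct vertices by the collapse is itself degenerate and is removed the
    same way.  Returns the T2 events.
    """
    events: List[Event] = []
    a = tissue.areas() if areas is None else areas
    doomed = set(int(tissue.uid[i])
                 for i in np.flatnonzero(a < config.theta_T2))
    guard = 0
    while guard < max(4 * tissue.n_cells, 16):
        guard += 1
        a = tissue.areas() if areas is None or guard > 1 else areas
        counts = np.array([len(np.unique(c)) for c in tissue.cells])
        # Collapsing a cell perturbs the polygons around it, which can push
        # healthy neighbours under the threshold transiently.  Those cells
        # get a chance to re-equilibrate: only cells that were already below
        # the threshold when the sweep began are removed now, plus any cell
        # the collapses left combinatorially degenerate or inverted.
        in_doom = np.array([int(u) in doomed for u in tissue.uid],
                           dtype=bool)
        bad = np.flatnonzero(((a < config.theta_T2) & in_doom)
                             | (counts < 3) | (a <= 0.0))
        if bad.size == 0:
            break
        idx = int(bad[np.argmin(a[bad])])
        cyc = tissue.cells[idx]
        centroid = _polygon_centroid(tissue.vertices[cyc])
        ev = Event(kind="t2", time=time, cell_uid=int(tissue.uid[idx]),
                   location=(float(centroid[0]), float(centroid[1])),
                   parent_trait=int(tissue.trait[idx]),
                   last_area=float(a[idx]))
        _collapse_cell(tissue, idx)
        events.append(ev)
        if log is not None:
            log.add(ev)
        areas = None
    if events:
        _compact_vertices(tissue)
    return events


# --------------------------------------------------------------- mitotic ramp

def mitotic_growth(tissue: Tissue, config: SimConfig, dt: float,
                   areas: np.ndarray) -> np.ndarray:
    """Advance the natural-area ramp of mitotic cells; return cells due to split.

    During mitosis the natural area grows linearly; the cell divides once its
    actual area reaches twice the area it had on mitosis entry.  If crowding
    prevents doubling, division is forced when the ramp hits its cap.
    """
    mit = tissue.mitotic
    if not mit.any():
        return np.empty(0, dtype=np.int64)
    rate = config.mitosis_ramp_rate
    tissue.natural_area[mit] += rate * dt
    a0_cap = 1.0 + config.mitosis_cap_frac / config.mitosis_duration_frac
    due = mit & ((areas >= 2.0 * tissue.premit_area)
                 | (tissue.natural_area >= a0_cap))
    return np.flatnonzero(due)


# ------------------------------------------------------------------ main loop

def _stress_magnitudes(tissue: Tissue, config: SimConfig,
                       areas: np.ndarray, perims: np.ndarray,
                       corner_elen: np.ndarray) -> np.ndarray:
    """Per-cell stress magnitude sigma1+sigma2 (trace of the edge-sum tensor).

    trace sigma = -2 P + (1/A) sum_edges T_ij,a |r_ij| with P = -(A - A0) and
    T_ij,a = Lam_eff/2 + Gam_a L_a.  Cheap enough to evaluate every few steps.
    """
    cache = tissue.mesh_cache(config)
    cc = cache.corner_c
    t_corner = cache.corner_lam + (tissue.gam * perims)[cc]
    s = np.add.reduceat(t_corner * corner_elen, cache.starts)
    pressure = -(areas - tissue.natural_area)
    return -2.0 * pressure + s / areas


def run_growth(config: SimConfig, n_target: int,
               tissue: Optional[Tissue] = None,
               n_initial: int = 250,
               rng: Optional[np.random.Generator] = None,
               max_time: Optional[float] = None,
               measure_local: bool = False,
               measure_delay: float = 1.0,
               snapshot_every_cells: Optional[int] = None,
               record_traits_every: int = 50,
               callbacks: Sequence[Callable] = ()) -> RunResult:
    """Grow a tissue from its initial size to ``n_target`` cells.

    Per integrator step: one overdamped Euler move, clock advance (with the
    stress gate if enabled), mitosis/divisions, a T1 sweep, a T2 sweep, and
    feedback updates.  Deterministic given the seed in ``config`` (or ``rng``).

    measure_local records, around every division/elimination, the mean stress
    magnitude and CV of inverse area over ring-1 neighbours just before the
    event and again ``measure_delay`` time units later.
    """
    from .synth import generate_initial_tissue   # deferred: avoids cycle

    rng = rng or np.random.default_rng(config.seed)
    if tissue is None:
        tissue = generate_initial_tissue(n_initial, rng=rng, config=config)
    else:
        tissue = tissue.copy()
    # desynchronise the starting population
    tissue.cycle_len = np.asarray(_draw_cycle_len(config, rng,
                                                  tissue.n_cells))
    tissue.clock = rng.uniform(0.0, tissue.cycle_len)
    if config.trait_grid is not None and np.all(tissue.trait < 0):
        grid = np.asarray(config.trait_grid, float)
        tissue.trait = rng.integers(0, grid.size, tissue.n_cells)
        if config.trait_target == "lam":
            tissue.lam = grid[tissue.trait]
        else:
            tissue.gam = grid[tissue.trait]
        tissue.invalidate()

    fb = config.feedback
    gate: Optional[np.ndarray] = None
    chi0 = fb.chi0
    if fb.mode in {"fluidity_self", "fluidity_neighbor"} and chi0 is None:
        chi0 = config.gam0 if fb.target == "gam" else config.lam0

    trait_fn = None
    if config.trait_grid is not None:
        from .competition import inherit_trait
        n_traits = len(config.trait_grid)
        trait_fn = lambda parent: inherit_trait(parent, config.q, n_traits,
                                                rng)

    log = EventLog()
    snapshots: List[Tuple[float, Tissue]] = []
    pending: List[Tuple[float, Event, List[int], str]] = []
    uid_index: dict = {}

    def rebuild_uid_index():
        uid_index.clear()
        uid_index.update({int(u): i for i, u in enumerate(tissue.uid)})

    rebuild_uid_index()

    t = 0.0
    dt = config.dt
    S_bar_init = float("nan")
    next_snapshot = (tissue.n_cells + snapshot_every_cells
                     if snapshot_every_cells else None)
    if snapshot_every_cells:
        snapshots.append((t, tissue.copy()))
    max_time = max_time if max_time is not None else 100.0 * \
        config.cycle_len_mean
    step_i = 0
    S_cached: Optional[np.ndarray] = None
    aborted = False

    interior0 = ~tissue.boundary_cells(config)
    f, areas, perims, edge_len, corner_elen = forces_and_geometry(tissue,
                                                                  config)
    S_cached = _stress_magnitudes(tissue, config, areas, perims, corner_elen)
    S_bar_init = float(np.mean(S_cached[interior0])) if interior0.any() \
        else float(np.mean(S_cached))

    log.record_size(t, tissue.n_cells)
    if config.trait_grid is not None:
        log.trait_times.append(t)
        log.trait_counts.append(np.bincount(
            tissue.trait[tissue.trait >= 0],
            minlength=len(config.trait_grid)))

    while tissue.n_cells < n_target and t < max_time:
        try:
            f, areas, perims, edge_len, corner_elen = \
                forces_and_geometry(tissue, config)
        except MeshError:
            aborted = True
            break
        topology_changed = False

        # ---- feedback / stress refresh
        if fb.mode != "none" and step_i % fb.update_every == 0:
            S_cached = _stress_magnitudes(tissue, config, areas, perims,
                                          corner_elen)
            if fb.mode == "growth_gate":
                gate = np.where(S_cached >= S_bar_init, fb.clock_const, 0.0)
            elif fb.mode in {"fluidity_self", "fluidity_neighbor"}:
                chi = tissue.gam if fb.target == "gam" else tissue.lam
                if fb.mode == "fluidity_self":
                    s_ref = fb.S0
                else:
                    nb = tissue.adjacency(config)
                    s_ref = np.array([np.mean(S_cached[n]) if n else
                                      S_cached[i]
                                      for i, n in enumerate(nb)])
                dchi = fb.c * (S_cached - s_ref) - fb.d * (chi - chi0)
                chi += dt * fb.update_every * dchi
                np.clip(chi, 0.0, None, out=chi)
                if fb.target == "lam":
                    tissue.invalidate()   # corner tensions depend on lam
        elif measure_local and step_i % 5 == 0:
            S_cached = _stress_magnitudes(tissue, config, areas, perims,
                                          corner_elen)

        # ---- overdamped move
        euler_step(tissue, config, forces=f)

        # ---- cell cycle
        due = advance_clocks(tissue, dt, gate)
        division_queue: List[int] = []
        if config.mitosis_mode == "instant":
            division_queue.extend(int(u) for u in tissue.uid[due])
        else:
            for i in due:
                tissue.mitotic[i] = True
                tissue.premit_area[i] = areas[i]
            ripe = mitotic_growth(tissue, config, dt, areas)
            division_queue.extend(int(u) for u in tissue.uid[ripe])

        # ---- divisions
        for uid in division_queue:
            idx = uid_index.get(uid)
            if idx is None:
                continue
            if measure_local and S_cached is None:
                S_cached = _stress_magnitudes(tissue, config, areas, perims,
                                              corner_elen)
            ring = None
            if measure_local:
                nb = tissue.adjacency(config)[idx]
                ring = [int(tissue.uid[j]) for j in nb]
            pts = tissue.vertices[tissue.cells[idx]]
            if fb.mode == "division_align":
                from .stress import stress_tensor_B, principal_decomposition
                tens = stress_tensor_B(tissue, config, idx)
                from .feedback import stress_aligned_axis
                angle = stress_aligned_axis(pts, tens.tensor)
            else:
                ang_s, _, _ = shortest_axis(pts)
                angle = sample_division_axis(ang_s, config.kappa, rng)
            try:
                ev = divide_cell(tissue, config, idx, angle, rng=rng,
                                 trait_fn=trait_fn, time=t)
            except MeshError:
                continue
            if measure_local and ring:
                idxs = [uid_index[u] for u in ring if u in uid_index]
                if idxs:
                    ev.before_S = float(np.mean(S_cached[idxs]))
                pending.append((t + measure_delay, ev, ring, "S"))
            log.add(ev)
            topology_changed = True
            rebuild_uid_index()
            S_cached = None

        # ---- T1 sweep
        min_len = edge_len[~tissue.mesh_cache(config).edge_boundary].min() \
            if not topology_changed and edge_len.size else None
        if topology_changed or (min_len is not None
                                and min_len < config.theta_T1):
            if apply_T1(tissue, config, time=t, log=log):
                topology_changed = True
                rebuild_uid_index()
                S_cached = None

        # ---- T2 sweep
        areas_now = tissue.areas() if topology_changed else areas
        if np.any(areas_now < config.theta_T2):
            pre = {}
            if measure_local:
                _, a2, p2, _, ce2 = forces_and_geometry(tissue, config)
                S_now = _stress_magnitudes(tissue, config, a2, p2, ce2)
                pre = _pre_measure_t2(tissue, config, a2, S_now)
            t2_events = apply_T2(tissue, config, time=t, log=log)
            if t2_events:
                split_rosettes(tissue, config)
                topology_changed = True
                rebuild_uid_index()
                S_cached = None
                for ev in t2_events:
                    hit = pre.get(ev.cell_uid)
                    if hit is not None:
                        ev.before_S, ev.before_cv, ring = hit
                        pending.append((t + measure_delay, ev, ring, "t2"))

        # ---- due local measurements
        if pending and min(p[0] for p in pending) <= t:
            still = []
            _, a2, p2, _, ce2 = forces_and_geometry(tissue, config)
            S_now = _stress_magnitudes(tissue, config, a2, p2, ce2)
            for due_t, ev, ring, kind in pending:
                if due_t > t:
                    still.append((due_t, ev, ring, kind))
                    continue
                idxs = [uid_index[u] for u in ring if u in uid_index]
                if idxs:
                    ev.after_S = float(np.mean(S_now[idxs]))
                    if kind == "t2" and len(idxs) >= 2:
                        inv = 1.0 / a2[idxs]
                        ev.after_cv = float(np.std(inv) / np.mean(inv))
            pending[:] = still

        t += dt
        step_i += 1
        log.record_size(t, tissue.n_cells)
        if config.trait_grid is not None and step_i % record_traits_every == 0:
            log.trait_times.append(t)
            log.trait_counts.append(np.bincount(
                tissue.trait[tissue.trait >= 0],
                minlength=len(config.trait_grid)))
        if next_snapshot is not None and tissue.n_cells >= next_snapshot:
            snapshots.append((t, tissue.copy()))
            next_snapshot += snapshot_every_cells
        for cb in callbacks:
            cb(t, tissue, log)

    if config.trait_grid is not None:
        log.trait_times.append(t)
        log.trait_counts.append(np.bincount(
            tissue.trait[tissue.trait >= 0],
            minlength=len(config.trait_grid)))
    if snapshot_every_cells:
        snapshots.append((t, tissue.copy()))
    return RunResult(tissue=tissue, log=log, config=config, t_end=t,
                     S_bar_init=S_bar_init, snapshots=snapshots,
                     aborted=aborted)


def _pre_measure_t2(tissue: Tissue, config: SimConfig, areas: np.ndarray,
                    S_now: np.ndarray) -> dict:
    """Pre-elimination neighbourhood stats keyed by the dying cell's uid.

    The density CV is computed on inverse areas over the dying cell plus its
    ring-1 neighbours; the stress mean over the neighbours only (they are the
    cells that persist through the event).
    """
    out = {}
    nb_all = tissue.adjacency(config)
    for idx in np.flatnonzero(areas < config.theta_T2):
        nb = nb_all[idx]
        if len(nb) < 2:
            continue
        ring = [int(tissue.uid[j]) for j in nb]
        inv = 1.0 / areas[nb + [idx]]
        out[int(tissue.uid[idx])] = (
            float(np.mean(S_now[nb])),
            float(np.std(inv) / np.mean(inv)),
            ring,
        )
    return out
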