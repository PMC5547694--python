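"""Division, T1, T2, rosette-resolution, and growth-loop bookkeeping tests."""

import math

import numpy as np
import pytest

import epivertex as ev
from epivertex.growth import (
    EventLog,
    apply_T1,
    apply_T2,
    divide_cell,
    mitotic_growth,
    run_growth,
    sample_division_axis,
    shortest_axis,
    split_rosettes,
)
from epivertex.synth import four_cell_cross, hexagonal_patch, regular_hexagon
from epivertex.tissue import relax


def _neighbors(tissue, cfg):
    adj = tissue.adjacency(cfg)
    return {i: set(nb) for i, nb in enumerate(adj)}


# ------------------------------------------------------------------- division

def test_divide_cell_combinatorics(patch):
    cfg = ev.SimConfig()
    rng = np.random.default_rng(0)
    n0 = patch.n_cells
    centre = int(np.argmin(np.hypot(*patch.centroids().T)))
    area0 = patch.areas()[centre]
    uid0 = int(patch.uid[centre])
    event = divide_cell(patch, cfg, centre, angle=0.3, rng=rng, time=1.5)
    patch.validate(cfg)
    assert patch.n_cells == n0 + 1
    assert event.kind == "division"
    assert event.cell_uid == uid0
    assert len(event.daughter_uids) == 2
    # daughters partition the parent area (the chord adds no area)
    i1 = int(np.flatnonzero(patch.uid == event.daughter_uids[0])[0])
    i2 = int(np.flatnonzero(patch.uid == event.daughter_uids[1])[0])
    a = patch.areas()
    assert a[i1] + a[i2] == pytest.approx(area0, rel=1e-9)
    # daughters are adjacent, start unmitotic with a fresh clock
    cfg2 = cfg
    nb = _neighbors(patch, cfg2)
    assert i2 in nb[i1]
    assert not patch.mitotic[i1] and not patch.mitotic[i2]
    assert patch.clock[i1] == 0.0 and patch.clock[i2] == 0.0


def test_divide_cell_chord_respects_vertex_separation(patch):
    # new chord endpoints must stay clear of existing vertices so the two
    # daughters are not born with sub-threshold edges
    cfg = ev.SimConfig()
    rng = np.random.default_rng(1)
    centre = int(np.argmin(np.hypot(*patch.centroids().T)))
    divide_cell(patch, cfg, centre, angle=0.01, rng=rng)
    lens = patch.edge_lengths(cfg)
    assert np.min(lens[lens > 0]) >= cfg.theta_T1


def test_shortest_axis_of_a_stretched_hexagon():
    hexa = regular_hexagon()
    pts = hexa.vertices.copy()
    pts[:, 0] *= 3.0  # stretch along x -> the short axis is along y
    ang, aniso, ang_long = shortest_axis(pts)
    assert abs(math.sin(ang)) == pytest.approx(1.0, abs=1e-6)
    assert abs(math.cos(ang_long)) == pytest.approx(1.0, abs=1e-6)
    assert 0.5 < aniso <= 1.0


def test_sample_division_axis_kappa_zero_is_uniform_and_large_concentrates():
    rng = np.random.default_rng(3)
    n = 4000
    flat = np.array([sample_division_axis(0.7, 0.0, rng) for _ in range(n)])
    # uniform on [0, pi): chi^2 over 8 bins stays moderate
    counts, _ = np.histogram(flat % math.pi, bins=8, range=(0.0, math.pi))
    chi2 = np.sum((counts - n / 8) ** 2 / (n / 8))
    assert chi2 < 30.0
    tight = np.array([sample_division_axis(0.7, 50.0, rng) for _ in range(n)])
    d = np.angle(np.exp(2j * (tight - 0.7))) / 2.0
    assert np.percentile(np.abs(d), 90) < 0.35


# ------------------------------------------------------------------------- T1

def test_apply_T1_swaps_neighbors_on_the_cross(cross):
    cfg = ev.SimConfig()
    nb0 = _neighbors(cross, cfg)
    # west(0) and east(1) share the short edge; south(2) and north(3) do not
    assert 1 in nb0[0] and 3 not in nb0[2]
    log = EventLog()
    n = apply_T1(cross, cfg, log=log)
    assert n == 1
    cross.validate(cfg)
    nb1 = _neighbors(cross, cfg)
    assert 1 not in nb1[0]      # west and east separated
    assert 3 in nb1[2]          # south and north now touch
    # the new edge has the configured post-swap length
    lens = cross.edge_lengths(cfg)
    expect = cfg.t1_expansion * cfg.theta_T1
    assert np.min(lens[lens > 0]) == pytest.approx(expect, rel=1e-9)
    assert log.count("t1") == 1


def test_apply_T1_leaves_long_edges_alone():
    cfg = ev.SimConfig()
    cross = four_cell_cross(short_len=0.5)   # well above theta_T1
    assert apply_T1(cross, cfg) == 0


# ------------------------------------------------------------------------- T2

def test_apply_T2_removes_small_cell_and_bridges_neighbors(patch):
    cfg = ev.SimConfig()
    centre = int(np.argmin(np.hypot(*patch.centroids().T)))
    # shrink the centre cell well below theta_T2 by pulling its vertices in
    cyc = patch.cells[centre]
    c = patch.vertices[cyc].mean(axis=0)
    patch.vertices[cyc] = c + 0.15 * (patch.vertices[cyc] - c)
    patch.invalidate()
    n0 = patch.n_cells
    log = EventLog()
    events = apply_T2(patch, cfg, time=2.0, log=log)
    split_rosettes(patch, cfg)
    patch.validate(cfg)
    assert len(events) == 1
    assert events[0].kind == "t2"
    assert events[0].last_area < cfg.theta_T2
    assert patch.n_cells == n0 - 1


def test_apply_T2_keeps_healthy_cells():
    cfg = ev.SimConfig(boundary_tension_mult=1.0)
    tis = hexagonal_patch(rings=2, edge_len=0.5)
    relax(tis, cfg, force_tol=1e-4, max_steps=20000)
    assert np.all(tis.areas() > cfg.theta_T2)
    n0 = tis.n_cells
    assert apply_T2(tis, cfg) == []
    assert tis.n_cells == n0


# --------------------------------------------------------------------- rosettes

def test_split_rosettes_resolves_a_four_fold_vertex(cross):
    cfg = ev.SimConfig()
    # merge the central short edge by hand -> one 4-fold vertex
    v4, v5 = 4, 5
    cross.vertices[v4] = 0.5 * (cross.vertices[v4] + cross.vertices[v5])
    for i, cyc in enumerate(cross.cells):
        cyc = np.where(cyc == v5, v4, cyc)
        out = [cyc[0]]
        for v in cyc[1:]:
            if v != out[-1]:
                out.append(v)
        cross.cells[i] = np.asarray(out, dtype=np.int64)
    cross.invalidate()
    n = split_rosettes(cross, cfg)
    assert n >= 1
    cross.validate(cfg)
    # every interior vertex is at most 3-fold afterwards
    incid = {}
    for ci, cyc in enumerate(cross.cells):
        for v in np.unique(cyc):
            incid.setdefault(int(v), []).append(ci)
    bset = set(int(b) for b in
               cross.mesh_cache(cfg).boundary_vertices)
    for v, cs in incid.items():
        if v not in bset:
            assert len(cs) <= 3


# ---------------------------------------------------------------- cell cycle

def test_mitotic_growth_ramp_and_forced_cap():
    cfg = ev.SimConfig()
    tis = regular_hexagon()
    tis.mitotic[0] = True
    tis.premit_area[0] = tis.areas()[0]
    a0_before = float(tis.natural_area[0])
    due = mitotic_growth(tis, cfg, dt=1.0, areas=tis.areas())
    assert tis.natural_area[0] == pytest.approx(
        a0_before + cfg.mitosis_ramp_rate, rel=1e-12)
    assert due.size == 0           # area has not doubled yet
    # force the cap
    cap = 1.0 + cfg.mitosis_cap_frac / cfg.mitosis_duration_frac
    tis.natural_area[0] = cap
    due = mitotic_growth(tis, cfg, dt=0.0, areas=tis.areas())
    assert 0 in due


# ----------------------------------------------------------------- run_growth

def test_run_growth_bookkeeping_and_determinism(reference_config):
    cfg = reference_config
    res1 = run_growth(cfg, n_target=175, n_initial=150,
                      rng=np.random.default_rng(42))
    # cell count balances births and deaths
    n_div = res1.log.count("division")
    n_t2 = res1.log.count("t2")
    assert res1.tissue.n_cells == 150 + n_div - n_t2
    assert not res1.aborted
    res1.tissue.validate(cfg)
    # same seed reproduces the event log and mesh exactly
    res2 = run_growth(cfg, n_target=175, n_initial=150,
                      rng=np.random.default_rng(42))
    assert len(res1.log.events) == len(res2.log.events)
    for e1, e2 in zip(res1.log.events, res2.log.events):
        assert (e1.kind, e1.time, e1.cell_uid) == (e2.kind, e2.time,
                                                   e2.cell_uid)
    assert np.array_equal(res1.tissue.vertices, res2.tissue.vertices)
    assert all(np.array_equal(a, b) for a, b in zip(res1.tissue.cells,
                                                    res2.tissue.cells))


def test_run_growth_aborts_gracefully_below_viable_size(reference_config):
    # very small discs are crushed by the contractile rim; the run must end
    # with aborted=True and a usable partial log rather than an exception
    res = run_growth(reference_config, n_target=90, n_initial=60,
                     rng=np.random.default_rng(42), max_time=2000.0)
    if res.aborted:
        assert len(res.log.times) > 0
    else:   # if it survives, bookkeeping must still balance
        assert res.tissue.n_cells == 60 + res.log.count("division") \
            - res.log.count("t2")


def test_reference_run_is_healthy(reference_run, reference_config):
    res = reference_run
    assert not res.aborted
    assert res.tissue.n_cells >= 900
    res.tissue.validate(reference_config)
    a = res.tissue.areas()
    assert np.all(a > 0)
    # all cells above the elimination threshold at the final snapshot and a
    # size distribution in the physically expected band
    assert a.min() >= reference_config.theta_T2 * 0.8
    assert 0.3 < a.mean() < 0.6
    interior = ~res.tissue.boundary_cells(reference_config)
    cv = a[interior].std() / a[interior].mean()
    assert 0.1 < cv < 0.4
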