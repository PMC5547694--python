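"""Energy, force, and mesh-invariant tests for the mechanical core."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

import epivertex as ev
from epivertex.tissue import (
    MeshError,
    Tissue,
    compute_energy,
    compute_forces,
    effective_line_tension,
    relax,
    step,
)
from epivertex.synth import hexagonal_patch, regular_hexagon, two_unit_squares

LAM, GAM = 0.14, 0.04


def test_two_squares_energy_hand_value_boundary_mult_one():
    # two unit squares: area term 0, perimeter term 2 * (0.04/2) * 16 = 0.64,
    # line term 7 unit edges * 0.14 = 0.98; total 1.62
    tis = two_unit_squares()
    cfg = ev.SimConfig(boundary_tension_mult=1.0)
    assert compute_energy(tis, cfg) == pytest.approx(1.62, abs=1e-12)


def test_two_squares_energy_hand_value_boundary_mult_three():
    # with the 3x rim tension: 0.64 + (1*0.14 + 6*0.42) = 3.30
    tis = two_unit_squares()
    cfg = ev.SimConfig()
    assert compute_energy(tis, cfg) == pytest.approx(3.30, abs=1e-12)


def test_forces_match_finite_difference_gradient(patch):
    cfg = ev.SimConfig()
    f = compute_forces(patch, cfg)
    h = 1e-6
    num = np.zeros_like(f)
    for v in range(patch.n_vertices):
        for k in range(2):
            for s, sign in ((h, 1.0), (-h, -1.0)):
                t2 = patch.copy()
                t2.vertices[v, k] += s
                t2.invalidate()
                num[v, k] += -sign * compute_energy(t2, cfg)
    num /= 2 * h
    assert np.allclose(f, num, rtol=1e-5, atol=1e-7)


def test_energy_translation_and_rotation_invariance(patch):
    cfg = ev.SimConfig()
    e0 = compute_energy(patch, cfg)
    t2 = patch.copy()
    t2.vertices = t2.vertices + np.array([3.7, -1.2])
    t2.invalidate()
    assert compute_energy(t2, cfg) == pytest.approx(e0, rel=1e-12)
    th = 0.813
    R = np.array([[math.cos(th), -math.sin(th)],
                  [math.sin(th), math.cos(th)]])
    t3 = patch.copy()
    t3.vertices = t3.vertices @ R.T
    t3.invalidate()
    assert compute_energy(t3, cfg) == pytest.approx(e0, rel=1e-12)


def test_effective_line_tension_rules():
    assert effective_line_tension(0.1, 0.3, "max") == 0.3
    assert effective_line_tension(0.1, 0.3, "mean") == pytest.approx(0.2)
    with pytest.raises(ValueError):
        effective_line_tension(-0.1, 0.3)
    with pytest.raises(ValueError):
        effective_line_tension(0.1, 0.3, "min")


def test_interior_hexagon_relaxes_to_energy_minimising_edge_length():
    # analytic oracle: minimise the per-interior-cell energy of a regular
    # hexagonal lattice over the edge length, then check the relaxed patch
    # centre cell against it
    def dU(ell):
        area = 1.5 * math.sqrt(3.0) * ell ** 2
        return ((area - 1.0) * 3.0 * math.sqrt(3.0) * ell
                + 36.0 * GAM * ell + 3.0 * LAM)

    # dU has two roots (a small-ell local maximum and the lattice optimum);
    # bracket the larger, stable one
    ell_star = brentq(dU, 0.2, 1.0)
    area_star = 1.5 * math.sqrt(3.0) * ell_star ** 2

    # rim multiplier 1 so the finite patch stays close to the bulk optimum
    cfg = ev.SimConfig(boundary_tension_mult=1.0)
    patch = hexagonal_patch(rings=3, edge_len=0.55)
    relax(patch, cfg, force_tol=1e-6, max_steps=40000)
    areas = patch.areas()
    centre = int(np.argmin(np.hypot(*patch.centroids().T)))
    # the finite rim compresses the patch a little relative to the infinite
    # lattice; the centre cell should still sit near the analytic optimum
    assert areas[centre] == pytest.approx(area_star, rel=0.10)


def test_relax_reaches_force_tolerance():
    # a single cell at these tensions has no stable size (it contracts to a
    # point), and the tripled rim tension crushes very small patches too, so
    # convergence is checked on a small patch with rim multiplier 1
    cfg = ev.SimConfig(boundary_tension_mult=1.0)
    patch = hexagonal_patch(rings=1, edge_len=0.5)
    _, converged, _ = relax(patch, cfg, force_tol=1e-6, max_steps=40000)
    assert converged
    f = compute_forces(patch, cfg)
    assert np.max(np.hypot(f[:, 0], f[:, 1])) < 1e-6


def test_step_moves_down_the_energy_gradient(hexagon):
    cfg = ev.SimConfig()
    e0 = compute_energy(hexagon, cfg)
    step(hexagon, cfg)
    hexagon.invalidate()
    assert compute_energy(hexagon, cfg) < e0


def test_validate_rejects_bad_meshes():
    # fewer than 3 vertices
    verts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
    with pytest.raises(MeshError):
        Tissue(verts, [np.array([0, 1])]).validate()
    # clockwise orientation (negative area)
    with pytest.raises(MeshError):
        Tissue(verts, [np.array([0, 2, 1])]).validate()
    # repeated vertex in a cycle
    with pytest.raises(MeshError):
        Tissue(verts, [np.array([0, 1, 2, 1])]).validate()


def test_boundary_cells_and_adjacency(patch):
    cfg = ev.SimConfig()
    b = patch.boundary_cells(cfg)
    # 2-ring honeycomb: 19 cells, 12 on the rim
    assert patch.n_cells == 19
    assert int(b.sum()) == 12
    adj = patch.adjacency(cfg)
    centre = int(np.argmin(np.hypot(*patch.centroids().T)))
    assert len(adj[centre]) == 6
    # adjacency is symmetric
    for i, nb in enumerate(adj):
        for j in nb:
            assert i in adj[j]


def test_copy_is_deep(hexagon):
    t2 = hexagon.copy()
    t2.vertices[0] += 10.0
    t2.lam[0] = 99.0
    assert hexagon.vertices[0, 0] != t2.vertices[0, 0]
    assert hexagon.lam[0] != 99.0
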