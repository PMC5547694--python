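"""Stress-dependent regulation laws.

Three mechanisms by which a cell could react to the stress magnitude
S = sigma1 + sigma2 acting on it:

* growth gating -- the cell-cycle clock stops while the cell is more
  compressed than the tissue was before growth started (S < S_bar) and runs
  at a constant rate otherwise;
* fluidity feedback -- the contractility or line tension chi relaxes toward
  a basal value chi0 while being driven by the deviation of S from a
  reference (a fixed S0, or the mean over the cell's neighbours):
  d chi/dt = c (S - S_ref) - d (chi - chi0);
* division-orientation feedback -- the cleavage plane is placed along the
  direction of minimum principal stress (for relaxed pure tissues this
  coincides with the geometric shortest axis).

The growth loop applies these via ``SimConfig.feedback``; the functions here
are the laws themselves.
"""

from __future__ import annotations

import math
from typing import Union

import numpy as np

from .config import FeedbackConfig
from .growth import shortest_axis
from .stress import principal_decomposition

__all__ = [
    "FeedbackConfig",
    "stress_gated_rate",
    "fluidity_feedback_step",
    "stress_aligned_axis",
]


def stress_gated_rate(S: Union[float, np.ndarray], S_bar: float,
                      clock_const: float = 1.0):
    """Clock rate of the stress-gated cell cycle: 0 below S_bar, const above."""
    S = np.asarray(S, float)
    out = np.where(S < S_bar, 0.0, clock_const)
    return float(out) if out.ndim == 0 else out


def fluidity_feedback_step(chi, S, S_ref, c: float, d: float, chi0: float,
                           dt: float):
    """One explicit-Euler update of d chi/dt = c (S - S_ref) - d (chi - chi0).

    chi is clipped at zero from below (tensions/contractilities cannot be
    negative).  The fixed point for constant S is chi0 + (c/d)(S - S_ref).
    """
    chi = np.asarray(chi, float)
    new = chi + dt * (c * (np.asarray(S, float) - np.asarray(S_ref, float))
                      - d * (chi - chi0))
    out = np.clip(new, 0.0, None)
    return float(out) if out.ndim == 0 else out


def stress_aligned_axis(points: np.ndarray, tensor: np.ndarray) -> float:
    """Cleavage-plane angle along the minimum-principal-stress direction.

    Falls back to the geometric shortest axis when the stress tensor is
    isotropic (orientation undefined).
    """
    s1, s2, ori, degenerate = principal_decomposition(np.asarray(tensor))
    if degenerate:
        ang_s, _, _ = shortest_axis(points)
        return ang_s
    # sigma2 direction is perpendicular to the sigma1 direction
    return (ori + math.pi / 2.0) % math.pi
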