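"""Elimination rate, mortality, cellular/tissue fitness, response-curve fits.

The elimination rate eps = N_eliminated / N_produced counts eliminations per
newly born cell over windows of tissue-size increase.  Fitness is the slope
of the logarithmic growth curve: for a pure population growing with cycle
time T and elimination rate eps, the tissue gains a factor (2 - eps) per
cycle, so

    phi = log(2 - eps) / T = mu - m,   mu = log(2)/T,
    m   = -log(1 - eps/2) / T.

The one-parameter response of eps to any mechanical/growth parameter zeta is
well described by a Gaussian-type curve eps(zeta) = exp(-alpha (zeta-beta)^2)
+ gamma, which later feeds the mean-field competition model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.ndimage import median_filter

from .growth import EventLog

__all__ = [
    "GaussianFit",
    "REFERENCE_EPS_FITS",
    "elimination_rate",
    "mortality_from_eps",
    "fitness_from_eps",
    "tissue_fitness",
    "cellular_fitness",
    "fit_gaussian_response",
]


@dataclass
class GaussianFit:
    """eps(zeta) = exp(-alpha (zeta - beta)^2) + gamma."""

    alpha: float
    beta: float
    gamma: float
    residual: float = float("nan")
    param: str = ""
    degenerate: bool = False

    def __call__(self, zeta):
        z = np.asarray(zeta, float)
        out = np.exp(-self.alpha * (z - self.beta) ** 2) + self.gamma
        return float(out) if out.ndim == 0 else out


#: Calibrated response-curve constants for each parameter (alpha, beta, gamma).
REFERENCE_EPS_FITS = {
    "lam": GaussianFit(245.0, 0.24, 0.0, param="lam"),
    "gam": GaussianFit(1800.0, 0.076, 0.0, param="gam"),
    "theta_T1": GaussianFit(12.5, 0.465, 0.0875, param="theta_T1"),
    "kappa": GaussianFit(0.095, 5.2, 0.039, param="kappa"),
    "mu": GaussianFit(0.0016, 24.3, -0.31, param="mu"),
}


def elimination_rate(log: EventLog, window_cells: int = 250
                     ) -> Tuple[np.ndarray, float]:
    """Windowed elimination rate and its temporal mean.

    The growth range is cut into windows of ``window_cells`` increase in
    tissue size; within each window eps = #eliminations / #divisions.
    Windows without a division are skipped.  Returns (per-window eps array,
    temporal mean).
    """
    if window_cells <= 0:
        raise ValueError("window_cells must be positive")
    times, sizes = log.size_series()
    if times.size == 0:
        return np.empty(0), float("nan")
    # map each event time to the tissue size at that moment
    edges = np.arange(sizes[0], sizes[-1] + window_cells, window_cells)
    div_t = np.array([e.time for e in log.of_kind("division")])
    t2_t = np.array([e.time for e in log.of_kind("t2")])

    def counts(ts):
        if ts.size == 0:
            return np.zeros(len(edges) - 1)
        g_at = np.interp(ts, times, sizes)
        return np.histogram(g_at, bins=edges)[0]

    n_div = counts(div_t)
    n_t2 = counts(t2_t)
    valid = n_div > 0
    eps = n_t2[valid] / n_div[valid]
    mean = float(np.mean(eps)) if eps.size else (0.0 if t2_t.size == 0
                                                 else float("nan"))
    if eps.size == 0 and div_t.size == 0 and t2_t.size == 0:
        mean = 0.0
    return eps, mean


def mortality_from_eps(eps: float, T: float) -> float:
    """Mortality m = -log(1 - eps/2)/T implied by elimination rate eps.

    Follows from matching a (2-eps)-fold increase per cycle time T to an
    exponential growth curve with exponent mu - m and mu = log(2)/T.
    """
    if not (0.0 <= eps < 2.0):
        raise ValueError("eps must lie in [0, 2)")
    if T <= 0:
        raise ValueError("cycle time T must be positive")
    return -math.log(1.0 - eps / 2.0) / T


def fitness_from_eps(eps: float, T: float) -> float:
    """Net fitness phi = mu - m = log(2 - eps)/T of a pure population."""
    return math.log(2.0) / T - mortality_from_eps(eps, T)


def _log_derivative(times: np.ndarray, g: np.ndarray,
                    smooth: int = 5) -> np.ndarray:
    times = np.asarray(times, float)
    g = np.asarray(g, float)
    if times.size < 3:
        raise ValueError("need at least 3 samples of the growth curve")
    if np.any(g <= 0):
        raise ValueError("growth curve must be positive")
    if smooth > 1:
        g = median_filter(g, size=smooth, mode="nearest")
    return np.gradient(np.log(g), times)


def tissue_fitness(times: np.ndarray, g: np.ndarray,
                   smooth: int = 5) -> np.ndarray:
    """phi_Tissue(t) = d log g / dt via smoothed central differences."""
    return _log_derivative(times, g, smooth=smooth)


def cellular_fitness(times: np.ndarray, g_i: np.ndarray,
                     smooth: int = 5) -> np.ndarray:
    """phi_Cell,i(t) = d log g_i / dt for one trait's subpopulation.

    Reported up to the trait's extinction time (nan afterwards).
    """
    times = np.asarray(times, float)
    g_i = np.asarray(g_i, float)
    out = np.full(times.size, np.nan)
    alive = g_i > 0
    if alive.sum() >= 3:
        # contiguous alive prefix (extinction is absorbing)
        last = int(np.flatnonzero(alive)[-1])
        seg = slice(0, last + 1)
        if np.all(g_i[seg] > 0):
            out[seg] = _log_derivative(times[seg], g_i[seg], smooth=smooth)
    return out


def fitness_decomposition(times: np.ndarray, counts: np.ndarray,
                          smooth: int = 5):
    """Check that tissue fitness equals the frequency-weighted cellular sum.

    counts[t, i] are per-trait cell numbers.  Returns (phi_total,
    phi_weighted) where phi_total differentiates log sum_i g_i and
    phi_weighted is sum_i f_i dlog g_i/dt; the two agree identically up to
    differentiation error.
    """
    counts = np.asarray(counts, float)
    total = counts.sum(axis=1)
    phi_total = tissue_fitness(times, total, smooth=smooth)
    f = counts / total[:, None]
    phi_w = np.zeros_like(phi_total)
    for i in range(counts.shape[1]):
        phi_i = cellular_fitness(times, counts[:, i], smooth=smooth)
        phi_w += np.where(np.isnan(phi_i), 0.0, f[:, i] * phi_i)
    return phi_total, phi_w


def fit_gaussian_response(zeta: Sequence[float], eps: Sequence[float],
                          param: str = "",
                          beta_grid: Optional[Sequence[float]] = None
                          ) -> GaussianFit:
    """Least-squares fit of eps(zeta) = exp(-alpha (zeta-beta)^2) + gamma.

    Multi-started over a grid of beta values to escape local minima.  A flat
    response collapses to alpha ~ 0 and is flagged degenerate.
    """
    z = np.asarray(zeta, float)
    y = np.asarray(eps, float)
    ok = np.isfinite(z) & np.isfinite(y)
    z, y = z[ok], y[ok]
    if z.size < 4:
        raise ValueError("need at least 4 points")
    if np.ptp(y) < 1e-12:
        return GaussianFit(0.0, float(np.mean(z)), float(np.mean(y)) - 1.0,
                           residual=0.0, param=param, degenerate=True)
    span = np.ptp(z) if np.ptp(z) > 0 else 1.0
    if beta_grid is None:
        beta_grid = np.linspace(z.min() - 0.5 * span, z.max() + 0.5 * span, 9)

    def model(zz, a, b, g):
        return np.exp(-a * (zz - b) ** 2) + g

    best = None
    for b0 in beta_grid:
        for a0 in (1.0 / span ** 2, 10.0 / span ** 2, 100.0 / span ** 2):
            try:
                popt, _ = curve_fit(model, z, y, p0=(a0, b0, 0.0),
                                    bounds=([0.0, -np.inf, -1.0],
                                            [np.inf, np.inf, 1.0]),
                                    maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            res = float(np.linalg.norm(model(z, *popt) - y))
            if best is None or res < best[1]:
                best = (popt, res)
    if best is None:
        raise RuntimeError("Gaussian response fit failed from every start")
    (a, b, g), res = best
    return GaussianFit(float(a), float(b), float(g), residual=res,
                       param=param, degenerate=a < 1e-9)
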