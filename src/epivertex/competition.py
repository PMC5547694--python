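"""Heritable mechanical traits and the trait-competition dynamics.

At division a daughter keeps its parent's trait with probability q and draws
a uniformly random trait (out of N) otherwise, so the probability of matching
the parent is q + (1-q)/N.  Writing x(t) for the per-trait cell counts, the
expected dynamics are

    dx/dt = Q_q Phi(t) x(t),

where Q_q has diagonal q + (1-q)/N and off-diagonal (1-q)/N, and Phi is the
diagonal matrix of per-trait cellular fitnesses.  Three tractable regimes:

* closed_form -- high heritability: clones cluster, each trait's fitness is
  its pure-population value, and x(t) = expm(Q Phi t) x(0);
* mean_field -- traits are spatially well mixed, so the effective line
  tension of trait i under the max-combination rule is the frequency-weighted
  Lam_i sum_{k<=i} f_k + sum_{k>i} Lam_k f_k, and Phi(t) is recomputed from
  the calibrated elimination-rate response eps(Lam) each step;
* uniform_limit -- no heritability: f stays ~uniform, the effective traits
  are constants, and the system is again linear.

For this copying rule the parent-offspring regression slope (the heritability
h^2 as estimated below) equals q in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .fitness import GaussianFit, mortality_from_eps

__all__ = [
    "TraitSystem",
    "inherit_trait",
    "inheritance_matrix",
    "estimate_heritability",
    "mean_field_effective_trait",
    "fitness_from_eps_fn",
    "tradeoff_growth_rate",
    "solve_competition",
    "CompetitionResult",
]


def inherit_trait(parent_trait: int, q: float, n_traits: int,
                  rng: np.random.Generator) -> int:
    """Daughter trait: parental with probability q, uniform otherwise."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    if parent_trait < 0:
        return parent_trait
    if rng.random() < q:
        return int(parent_trait)
    return int(rng.integers(0, n_traits))


def inheritance_matrix(q: float, n_traits: int) -> np.ndarray:
    """Q_q with diagonal q + (1-q)/N and off-diagonal (1-q)/N."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    n = int(n_traits)
    return q * np.eye(n) + (1.0 - q) / n * np.ones((n, n))


def estimate_heritability(parent_traits: Sequence[float],
                          offspring_traits: Sequence[float],
                          n_boot: int = 200,
                          rng: Optional[np.random.Generator] = None
                          ) -> Tuple[float, Tuple[float, float]]:
    """h^2 as the offspring-on-parent regression slope, with bootstrap CI.

    For asexual copying the single parent plays the role of the midparent, so
    the slope itself estimates the heritability (no doubling).
    """
    p = np.asarray(parent_traits, float)
    o = np.asarray(offspring_traits, float)
    if p.size < 100:
        raise ValueError("need at least 100 parent-offspring pairs")
    if np.var(p) == 0:
        raise ValueError("zero parental variance: h^2 undefined")
    slope = float(np.cov(p, o, ddof=0)[0, 1] / np.var(p))
    rng = rng or np.random.default_rng(0)
    boots = []
    for _ in range(n_boot):
        i = rng.integers(0, p.size, p.size)
        vp = np.var(p[i])
        if vp > 0:
            boots.append(np.cov(p[i], o[i], ddof=0)[0, 1] / vp)
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots
              else (float("nan"), float("nan")))
    return slope, (float(lo), float(hi))


def mean_field_effective_trait(f: np.ndarray,
                               trait_grid: np.ndarray) -> np.ndarray:
    """Effective line tension per trait under the max rule, mean-field mixed.

    With the grid ascending, a cell of trait i touching a random cell of
    trait k feels max(Lam_i, Lam_k), so on average
    Lam_eff_i = Lam_i sum_{k<=i} f_k + sum_{k>i} Lam_k f_k.
    """
    lam = np.asarray(trait_grid, float)
    f = np.asarray(f, float)
    if np.any(np.diff(lam) < 0):
        raise ValueError("trait grid must be ascending")
    csum_f = np.cumsum(f)
    # reversed cumulative sum of Lam_k f_k for k > i
    lf = lam * f
    tail = np.concatenate([np.cumsum(lf[::-1])[::-1][1:], [0.0]])
    return lam * csum_f + tail


def fitness_from_eps_fn(lam_eff: Union[float, np.ndarray],
                        eps_fn: Callable, T: float):
    """phi = log(2 - eps(Lam_eff)) / T (eps clipped to [0, 2))."""
    eps = np.clip(np.asarray(eps_fn(np.asarray(lam_eff, float)), float),
                  0.0, 2.0 - 1e-12)
    out = np.log(2.0 - eps) / T
    return float(out) if out.ndim == 0 else out


def tradeoff_growth_rate(lam: Union[float, np.ndarray],
                         base_rate: float) -> Union[float, np.ndarray]:
    """Proliferation rate rising with line tension: base / (1 + exp(-10 Lam)).

    Encodes the adhesion-proliferation tradeoff: low-tension (highly adhesive)
    cells are rarely eliminated but also divide more slowly.
    """
    out = base_rate / (1.0 + np.exp(-10.0 * np.asarray(lam, float)))
    return float(out) if np.ndim(lam) == 0 else out


@dataclass
class TraitSystem:
    """Trait grid plus everything needed to drive the competition ODE."""

    trait_grid: np.ndarray
    q: float
    eps_fn: Callable = field(default_factory=lambda: GaussianFit(245.0, 0.24,
                                                                 0.0))
    T: float = math.log(2.0) / 3.47e-3
    tradeoff: bool = False          # Lam-dependent proliferation rate

    def __post_init__(self):
        self.trait_grid = np.sort(np.asarray(self.trait_grid, float))

    @property
    def n(self) -> int:
        return self.trait_grid.size

    @property
    def Q(self) -> np.ndarray:
        return inheritance_matrix(self.q, self.n)

    def phi(self, f: np.ndarray) -> np.ndarray:
        """Per-trait cellular fitness at trait frequencies f."""
        lam_eff = mean_field_effective_trait(f, self.trait_grid)
        eps = np.clip(self.eps_fn(lam_eff), 0.0, 2.0 - 1e-12)
        if self.tradeoff:
            mu = tradeoff_growth_rate(self.trait_grid, math.log(2.0) / self.T)
            t_i = np.log(2.0) / mu
            return np.log(2.0 - eps) / t_i
        return np.log(2.0 - eps) / self.T

    def mortality(self, f: np.ndarray) -> np.ndarray:
        lam_eff = mean_field_effective_trait(f, self.trait_grid)
        eps = np.clip(self.eps_fn(lam_eff), 0.0, 2.0 - 1e-12)
        if self.tradeoff:
            mu = tradeoff_growth_rate(self.trait_grid, math.log(2.0) / self.T)
            t_i = np.log(2.0) / mu
            return np.array([mortality_from_eps(e, t)
                             for e, t in zip(eps, t_i)])
        return np.array([mortality_from_eps(e, self.T) for e in eps])


@dataclass
class CompetitionResult:
    t: np.ndarray
    x: np.ndarray            # counts, shape (n_times, n_traits)
    f: np.ndarray            # frequencies
    phi_tissue: np.ndarray   # frequency-weighted mean cellular fitness
    eliminated: np.ndarray   # cumulative expected eliminations


def solve_competition(x0: Sequence[float], system: TraitSystem,
                      t_grid: Sequence[float],
                      mode: str = "mean_field") -> CompetitionResult:
    """Integrate the trait-competition dynamics dx/dt = Q_q Phi x.

    Modes: ``closed_form`` (constant pure-population fitness per trait;
    matrix exponential), ``mean_field`` (fitness recomputed each step from
    the frequency-dependent effective traits), and ``uniform_limit``
    (effective traits frozen at the uniform-frequency value; again linear).
    """
    x0 = np.asarray(x0, float)
    t_grid = np.asarray(t_grid, float)
    if x0.size != system.n:
        raise ValueError("x0 must have one entry per trait")
    if np.any(x0 < 0):
        raise ValueError("counts must be non-negative")
    Q = system.Q

    if mode in {"closed_form", "uniform_limit"}:
        if mode == "closed_form":
            # each trait at its pure-population fitness (f concentrated on i)
            phi = np.empty(system.n)
            for i in range(system.n):
                f_pure = np.zeros(system.n)
                f_pure[i] = 1.0
                phi[i] = system.phi(f_pure)[i]
        else:
            phi = system.phi(np.full(system.n, 1.0 / system.n))
        A = Q @ np.diag(phi)
        x = np.array([expm(A * t) @ x0 for t in t_grid])
    elif mode == "mean_field":
        def rhs(_t, x):
            xx = np.maximum(x, 0.0)
            total = xx.sum()
            f = xx / total if total > 0 else np.full(system.n, 1.0 / system.n)
            return Q @ (system.phi(f) * xx)

        sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), x0, t_eval=t_grid,
                        method="RK45", rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise RuntimeError(f"competition ODE failed: {sol.message}")
        x = sol.y.T
    else:
        raise ValueError("mode must be closed_form, mean_field, or "
                         "uniform_limit")

    totals = x.sum(axis=1)
    f = x / totals[:, None]
    phi_t = np.array([float(np.dot(f[k], _phi_at(system, f[k], mode)))
                      for k in range(len(t_grid))])
    # cumulative expected eliminations: integral of sum_i m_i x_i dt
    m = np.array([_mortality_at(system, f[k], mode) for k in range(len(
        t_grid))])
    loss_rate = np.sum(m * x, axis=1)
    eliminated = np.concatenate([[0.0], np.cumsum(
        0.5 * (loss_rate[1:] + loss_rate[:-1]) * np.diff(t_grid))])
    return CompetitionResult(t=t_grid, x=x, f=f, phi_tissue=phi_t,
                             eliminated=eliminated)


def _phi_at(system: TraitSystem, f: np.ndarray, mode: str) -> np.ndarray:
    if mode == "closed_form":
        phi = np.empty(system.n)
        for i in range(system.n):
            fp = np.zeros(system.n)
            fp[i] = 1.0
            phi[i] = system.phi(fp)[i]
        return phi
    if mode == "uniform_limit":
        return system.phi(np.full(system.n, 1.0 / system.n))
    return system.phi(f)


def _mortality_at(system: TraitSystem, f: np.ndarray, mode: str) -> np.ndarray:
    if mode == "closed_form":
        m = np.empty(system.n)
        for i in range(system.n):
            fp = np.zeros(system.n)
            fp[i] = 1.0
            m[i] = system.mortality(fp)[i]
        return m
    if mode == "uniform_limit":
        return system.mortality(np.full(system.n, 1.0 / system.n))
    return system.mortality(f)
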