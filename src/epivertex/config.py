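"""Simulation configuration containers.

All quantities are dimensionless: lengths are measured in units of the square
root of the natural cell area, energies in units of the area-elasticity scale,
and time in units of the viscous relaxation time.  With that choice the area
elastic constant and the natural area are both 1 and the remaining free
mechanical parameters are the line-tension coefficient ``lam`` and the
perimeter-contractility coefficient ``gam``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

__all__ = ["SimConfig", "FeedbackConfig", "REFERENCE_PARAMS"]

#: Reference parameter set used throughout: Λ=0.14, Γ=0.04, θ_T1=0.1, κ=0,
#: μ=3.47e-3 (cell-cycle mean T = log2/μ ≈ 199.8) and θ_T2=0.2.
REFERENCE_PARAMS = dict(
    lam0=0.14, gam0=0.04, theta_T1=0.1, theta_T2=0.2, kappa=0.0, mu=3.47e-3
)


@dataclass
class FeedbackConfig:
    """Stress-dependent regulation of growth, fluidity, or division axis.

    mode:
        ``"none"``            no feedback (default).
        ``"growth_gate"``     the cell-cycle clock only advances while the
                              cell's stress magnitude is at least the mean
                              magnitude of the initial (pre-growth) tissue.
        ``"fluidity_self"``   d chi/dt = c (S_a - S0) - d (chi_a - chi0).
        ``"fluidity_neighbor"`` d chi/dt = c (S_a - mean_neighbors(S)) -
                              d (chi_a - chi0).
        ``"division_align"``  the cleavage plane is placed along the minimum
                              principal-stress direction instead of being
                              sampled around the geometric shortest axis.
    """

    mode: str = "none"
    c: float = 0.0                 # feedback strength (signed)
    d: float = 0.01                # restoration rate toward the basal value
    chi0: Optional[float] = None   # basal value; defaults to gam0 or lam0
    target: str = "gam"            # which parameter chi regulates: "gam"|"lam"
    S0: float = 0.0                # reference stress magnitude (self mode)
    clock_const: float = 1.0       # clock speed in the open branch of the gate
    update_every: int = 5          # integrator steps between feedback updates

    def __post_init__(self) -> None:
        valid = {"none", "growth_gate", "fluidity_self", "fluidity_neighbor",
                 "division_align"}
        if self.mode not in valid:
            raise ValueError(f"unknown feedback mode {self.mode!r}")
        if self.target not in {"gam", "lam"}:
            raise ValueError("feedback target must be 'gam' or 'lam'")
        if self.d < 0:
            raise ValueError("restoration rate d must be >= 0")


@dataclass
class SimConfig:
    """All parameters of a growth simulation.

    The defaults are the reference set: Λ=0.14, Γ=0.04, θ_T1=0.1, θ_T2=0.2,
    κ=0 (uniformly random division orientation) and μ=3.47e-3.
    """

    lam0: float = 0.14            # reference line tension Λ
    gam0: float = 0.04            # reference perimeter contractility Γ
    theta_T1: float = 0.1         # edge-length threshold for rearrangement
    theta_T2: float = 0.2         # area threshold for elimination
    kappa: float = 0.0            # von Mises concentration of division axis
    mu: float = 3.47e-3           # proliferation rate; mean cycle T = log2/mu
    cycle_jitter: float = 0.2     # fractional uniform jitter on cycle times
    dt: float = 0.05              # explicit-Euler step
    eta: float = 1.0              # viscous coefficient (1 after rescaling)
    boundary_tension_mult: float = 3.0  # boundary edges carry 3x line tension
    lam_combination: str = "max"  # effective tension between unlike cells
    mitosis_mode: str = "ramp"    # "ramp" | "instant"
    mitosis_duration_frac: float = 0.1   # A0 ramps 1->2 over this fraction of T
    mitosis_cap_frac: float = 0.5        # force division after this fraction of T
    t1_expansion: float = 1.05    # new edge length = t1_expansion * theta_T1
    feedback: FeedbackConfig = field(default_factory=FeedbackConfig)
    q: float = 1.0                # trait inheritance probability
    trait_grid: Optional[Sequence[float]] = None  # heritable Λ values
    trait_target: str = "lam"     # which parameter the trait grid sets
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0.0 < self.theta_T2 < 1.0):
            raise ValueError("theta_T2 must lie in (0, 1)")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not (0.0 <= self.cycle_jitter < 1.0):
            raise ValueError("cycle_jitter must lie in [0, 1)")
        if self.lam_combination not in {"max", "mean"}:
            raise ValueError("lam_combination must be 'max' or 'mean'")
        if self.mitosis_mode not in {"ramp", "instant"}:
            raise ValueError("mitosis_mode must be 'ramp' or 'instant'")
        if isinstance(self.feedback, dict):
            self.feedback = FeedbackConfig(**self.feedback)

    @property
    def cycle_len_mean(self) -> float:
        """Mean cell-cycle time T = log 2 / mu."""
        return math.log(2.0) / self.mu

    @property
    def mitosis_ramp_rate(self) -> float:
        """Rate at which the natural area grows during mitosis."""
        return 1.0 / (self.mitosis_duration_frac * self.cycle_len_mean)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d.get("trait_grid") is not None:
            d["trait_grid"] = [float(v) for v in d["trait_grid"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)
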