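# Methods

## Model

The tissue is a planar polygonal tiling. Each cell `a` is a counter-clockwise
cycle of vertices; vertices shared by adjacent cells tie the tiling together.
The mechanical energy is

```
U = 1/2 sum_a (A_a - A0_a)^2  +  sum_<ij> Lam_ij * l_ij  +  sum_a (Gam_a / 2) * L_a^2
```

with `A_a` the cell area, `A0_a` its natural (target) area, `l_ij` the edge
lengths, `L_a` the cell perimeter. Energies and lengths are non-dimensional:
the area elastic modulus and the natural area of a non-mitotic cell are both
1, so lengths are measured in units of the natural cell diameter.

The line tension of an edge shared by two cells is the larger of the two
cells' tension parameters (`Lam_ij = max(Lam_a, Lam_b)`, the "max rule"); this
matters when heritable tension traits mix in one tissue. Edges on the tissue
boundary belong to one cell only and carry `boundary_tension_mult = 3` times
that cell's tension, which makes the rim act as a contractile purse string.

Vertices move by overdamped gradient descent, `eta dx/dt = -dU/dx`, integrated
with an explicit Euler step (`dt = 0.05`, `eta = 1`). Between events the
tissue is kept quasi-static.

### Reference parameters

`Lam = 0.14`, `Gam = 0.04`, T1 threshold `theta_T1 = 0.1`, T2 threshold
`theta_T2 = 0.2`, division-axis concentration `kappa = 0` (uniformly random
cleavage angle), division rate `mu = 3.47e-3`, initial size 250 cells, and a
20% uniform jitter on cell-cycle lengths. These are the package defaults
(`SimConfig()`).

### Cell cycle and division

Each cell carries a clock; when it reaches the (jittered) cycle length the
cell enters a mitotic swelling phase in which its natural area ramps up until
its actual area has roughly doubled, then the cell divides. The cleavage
plane passes through the centroid; its angle is drawn from a von Mises-type
distribution (period pi) centred on the cell's shortest geometric axis with
concentration `kappa` — `kappa = 0` is the uniform distribution. Chord
endpoints are kept at least `theta_T1` away from existing vertices so
daughters are not born with edges that immediately trigger rearrangements.
Daughters restart with fresh clocks and natural area 1.

### Topological events

* **T1 (neighbour exchange).** An interior edge shorter than `theta_T1` is
  rotated about its midpoint and re-expanded to `t1_expansion * theta_T1`,
  exchanging the two pairs of neighbours.
* **T2 (elimination).** A cell whose area falls below `theta_T2` is removed
  and replaced by a single vertex. Only cells already below threshold when
  the sweep starts are removed, so removing one cell cannot cascade through
  its neighbours within the same sweep.
* **Rosette splitting.** Vertices with more than three incident cells
  (produced by T2 collapses) are split back into three-fold vertices, choosing
  the split that lowers the energy most.

### Boundary dynamics

At the reference parameters the tripled rim tension continually squeezes
boundary cells, so rim cells die at a steady rate. A T2 collapse on the rim
creates a high-valence *boundary* vertex, and unresolved boundary rosettes
accumulate until the tissue implodes. Three boundary moves keep the rim
healthy; all are standard vertex-model operations:

* boundary vertices shared by three or more cells are split like interior
  rosettes (with the split direction chosen among the incident cells only,
  respecting the outside gap);
* a boundary edge shorter than `theta_T1` collapses to its midpoint,
  detaching its cell from the rim (the cell's neighbour inherits the rim
  segment);
* an edge with exactly one boundary endpoint can undergo a mixed T1 in which
  an interior cell intercalates into the rim.

With these moves, reference-parameter runs grow stably from 250 to beyond
1500 cells as roughly circular discs.

## Per-cell stress

Two per-cell stress tensors are implemented, both symmetric 2x2 tensors with
the convention *tension positive, compression negative*:

* **Method A (force moment):** `sigma_a = -(1 / 2 A_a) sum_i (F_i x_i^T + x_i F_i^T)`
  over the cell's vertices, with `F_i` the force the rest of the tissue
  exerts on vertex `i` and positions relative to the centroid.
* **Method B (pressure + edge tensions):**
  `sigma_a = -P_a I + (1 / A_a) sum_edges T_ij (l_ij l_ij^T) / |l_ij|`, with
  cell pressure `P_a = -(A_a - A0_a)` and the per-cell tension share of each
  edge `T = Lam_eff / 2 + Gam_a L_a`.

On grown tissues the two methods agree (Pearson correlation of the stress
magnitude > 0.9); method B is the default because it is cheap and local.

The principal decomposition gives the stress magnitude `sigma1 + sigma2`,
the anisotropy `sigma1 - sigma2 >= 0`, and the orientation of the maximum
principal axis in `[0, pi)`.

### Stress-geometry correlations

The headline statistics correlate mechanical state with visible geometry over
**interior, non-mitotic** cells:

1. Pearson correlation of stress magnitude with cell area,
2. Pearson correlation of stress anisotropy with shape anisotropy
   (1 - short/long axis ratio of the vertex covariance),
3. circular correlation (doubled angles, period pi) of the maximum-principal-
   stress direction with the long geometric axis.

Boundary cells are excluded because the rim tension dominates their state.
Mitotic cells are excluded because their pressure carries the programmed
natural-area ramp — a cell-cycle signal, not a crowding readout; leaving them
in drops the magnitude-area correlation from ~0.96 to ~0.59 without changing
the anisotropy or orientation statistics much. In a 250 -> 1500 cell
reference run the three correlations are approximately 0.96, 0.98 and 0.98
(`scripts/acceptance.py` recomputes them from scratch).

## Fitness metrics

The elimination rate `eps` is eliminations per division, measured in windows
of fixed tissue-size increase. Treating growth as a branching process in
which each division produces two daughters that each die with probability
`eps / 2` before their next division gives, per cell cycle of length `T`:

```
phi = log(2 - eps) / T      (cellular fitness)
m   = -log(1 - eps/2) / T   (mortality rate),   phi = log(2)/T - m
```

`tissue_fitness` and `cellular_fitness` compute the realised log-slope of
the size time series; `fitness_decomposition` splits it over subpopulations.

At the reference parameters the measured elimination rate is elevated
(~0.45-0.65, rising as the tissue grows and crowding builds) relative to the
headline response-curve values; the packaged Gaussian response fits
(`REFERENCE_EPS_FITS`) describe the *relative* dependence of `eps` on the
tension and contractility parameters and are used by the competition module,
not as absolute predictions for a particular run.

## Stress feedback

Three regulation laws (`epivertex.feedback`, applied by the growth loop via
`SimConfig.feedback`):

* **growth gating** — the cell-cycle clock advances only while the cell's
  stress magnitude is at least the pre-growth tissue mean;
* **fluidity feedback** — a mechanical parameter `chi` (tension or
  contractility) obeys `dchi/dt = c (S - S_ref) - d (chi - chi0)`, with
  `S_ref` either fixed or the mean over the cell's neighbours;
* **division alignment** — the cleavage plane is placed along the
  minimum-principal-stress direction.

## Heritable traits and competition

Each cell carries a discrete trait index (mapped to a line-tension value).
At division each daughter keeps the parent's trait with probability `q` and
otherwise redraws uniformly; `q` is the heritability of the trait
(`estimate_heritability` recovers it as the offspring-on-parent regression
slope). Population dynamics over a trait grid follow

```
dx/dt = Q_q diag(phi) x,    Q_q = q I + ((1 - q)/N) 11^T
```

solved either in closed form (matrix exponential, fixed per-trait fitness)
or as a mean-field nonlinear ODE in which each trait's effective tension
reflects the max rule against the current composition. Faithful inheritance
of a low-elimination trait raises tissue fitness and lowers the per-capita
elimination rate; `q = 0` keeps the composition flat.

## Numerical notes

* Determinism: every stochastic choice draws from one `numpy` Generator, so
  runs are bit-reproducible for a given seed.
* Small tissues (below roughly 100 cells) and isolated patches have no
  stable size under the tripled rim tension; they contract and die. This is
  model physics, not an artefact — unit tests that need a stable relaxed
  patch set `boundary_tension_mult = 1`.
* Extreme parameters (line tension far from the reference band) can make
  the explicit integrator diverge; the CLI `sweep` is intended for the
  stable band around the reference values.
* Runs that go extinct abort gracefully (`RunResult.aborted = True`).
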