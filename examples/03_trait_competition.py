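"""Competition between heritable line-tension traits.

Four subpopulations with different line tensions compete inside one tissue.
Cells with lower tension are eliminated less often; when the trait is
inherited faithfully (q = 1) they sweep the population, while with random
reassignment at division (q = 0) the composition stays flat.
"""

import numpy as np

import epivertex as ev

grid = np.array([0.04, 0.09, 0.14, 0.19])
t_grid = np.linspace(0.0, 3000.0, 7)
x0 = np.full(4, 62.5)                      # 250 cells, equal frequencies
eps_fn = ev.REFERENCE_EPS_FITS["lam"]

for q in (1.0, 0.0):
    system = ev.TraitSystem(trait_grid=grid, q=q, eps_fn=eps_fn)
    res = ev.solve_competition(x0, system, t_grid, mode="mean_field")
    print(f"q = {q:g}:")
    print("  t      total   " + "  ".join(f"f({v:g})" for v in grid))
    for k in (0, 3, 6):
        row = "  ".join(f"{fi:6.3f}" for fi in res.f[k])
        print(f"  {t_grid[k]:6.0f} {res.x[k].sum():8.1f}  {row}")
    print(f"  tissue fitness: {res.phi_tissue[0]:.2e} -> "
          f"{res.phi_tissue[-1]:.2e}")
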