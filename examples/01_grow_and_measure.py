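"""Grow a tissue and read its mechanical state off cell geometry.

Starts from a relaxed 250-cell disc at the reference parameters, grows it to
600 cells, and then asks: how well do cell area, shape anisotropy and the
long geometric axis predict the per-cell stress tensor?
"""

import numpy as np

import epivertex as ev

config = ev.SimConfig()          # reference parameters
rng = np.random.default_rng(1)

res = ev.run_growth(config, n_target=600, n_initial=250, rng=rng)
n_div = res.log.count("division")
n_t2 = res.log.count("t2")
print(f"grown to {res.tissue.n_cells} cells at t = {res.t_end:.1f}")
print(f"{n_div} divisions, {n_t2} eliminations, "
      f"{res.log.count('t1')} T1 rearrangements")
print(f"eliminations per division: {n_t2 / n_div:.3f}")

stats = ev.geometry_stats(res.tissue, config)
print(f"interior size CV: {stats['cv_size']:.3f}; "
      f"mean shape anisotropy: {stats['mean_aniso']:.3f}")

r1, r2, r3 = ev.stress_geometry_correlations(res.tissue, config)
print(f"corr(stress magnitude, area)          = {r1:.3f}")
print(f"corr(stress anisotropy, shape aniso)  = {r2:.3f}")
print(f"circular corr(stress dir, long axis)  = {r3:.3f}")
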