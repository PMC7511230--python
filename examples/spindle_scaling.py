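"""Spindle length scales with cell length.

Cells from 44 to 54 um long are simulated with the per-half surface
density and 60/40 asymmetry of force generators held fixed (bigger cells
get proportionally more CFGs).  The printed regression slope (~0.5 um of
final spindle length per um of cell length) is the model's scaling
coefficient; smaller cells also elongate more slowly and position the
spindle less asymmetrically.
"""

from stoichspindle.scenarios import cell_size_sweep

res = cell_size_sweep((44.0, 48.0, 52.0), n_configs=2, seed=0)
table = res["table"]

for cl, grp in table.groupby("CL"):
    print(f"cell length {cl:.0f} um: final length "
          f"{grp['FL'].mean():5.2f} um, elongation rate "
          f"{grp['ER'].mean():.3f} um/s, centre offset "
          f"{grp['center_offset'].mean():+.2f} um")

fit = res["scaling_fit"]
print(f"\nscaling: FL = {fit.slope:.3f} * CL {fit.intercept:+.2f} "
      f"(slope se {fit.slope_se:.3f}, n={fit.n})")
print("each extra um of cell length adds about half a um of spindle.")
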