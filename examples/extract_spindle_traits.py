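"""Fit spindle traits from a simulated trajectory.

The pole-to-pole distance L(t) is fit with a rising sigmoid to give the
initial length IL, final length FL, and elongation rate
ER = (FL - IL)/(4 tau_s); the posterior pole's distance to the posterior
cell boundary is fit with a falling sigmoid whose plateau is the final
centrosome distance CD.  These are the model's counterparts of the
traits measured from microscopy of dividing embryos.
"""

from stoichspindle import CellGeometry, LayoutSpec, extract_traits, run_simulation
from stoichspindle.dynamics import SimulationConfig

geom = CellGeometry()
traj = run_simulation(SimulationConfig(geometry=geom,
                                       layout=LayoutSpec(seed=2)))
rec = extract_traits(traj, geom)

print(f"IL  (initial length)      {rec.IL:6.2f} um")
print(f"FL  (final length)        {rec.FL:6.2f} um")
print(f"ER  (elongation rate)     {rec.ER:6.3f} um/s")
print(f"CD  (pole-cortex dist.)   {rec.CD:6.2f} um")
print(f"CL  (cell length)         {rec.CL:6.1f} um")
print(f"centre offset             {rec.center_offset:+6.2f} um")
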