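"""Simulate one wild-type anaphase: two centrosomes in a 50x30x30 um
embryo with 100 cortical force generators split 60/40
posterior/anterior, starting 11 um apart at the cell centre.

The spindle elongates and shifts toward the posterior; the printed final
length (~23-24 um) and centre offset (~+2.5 um, posterior positive) are
the model's analogues of the measured final spindle length and
asymmetric spindle position in the one-cell nematode embryo.
"""

from stoichspindle import LayoutSpec, run_simulation
from stoichspindle.dynamics import SimulationConfig

config = SimulationConfig(layout=LayoutSpec(seed=7))
traj = run_simulation(config)

poles = traj.final_positions()
print(f"termination:       {traj.termination} at t = {traj.times[-1]:.0f} s")
print(f"final length:      {traj.final_length():.2f} um (starts at 11 um)")
print(f"pole positions x:  anterior {poles[:, 0].min():+.2f} um, "
      f"posterior {poles[:, 0].max():+.2f} um")
print(f"spindle centre x:  {traj.center[-1, 0]:+.2f} um "
      f"(posterior shift from the cell centre)")
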