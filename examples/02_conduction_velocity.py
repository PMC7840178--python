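"""Plane-wave conduction velocity and its slowing under global light.

Paces the 2.5 x 0.25 cm strip at 5 Hz, measures conduction velocity from
activation-time differences between two probes 1 cm apart, and repeats
under uniform 0.02 mW/mm^2 illumination.  The light-induced resting
depolarization inactivates a fraction of the Na+ channels and slows the
wave by about 5%.
"""

from optodrift import (Grid, IonicParams, StimulusProtocol, TissueSim,
                       lightfield)
from optodrift.wave_metrics import conduction_velocity

params = IonicParams()
results = {}
for li in (0.0, 0.02):
    sim = TissueSim(Grid(nx=100, ny=10), params, dt=0.0025)
    sim.init_resting()
    stim = StimulusProtocol(amplitude=60.0, pulse_ms=2.0, cl=200.0,
                            n_pulses=4, columns=2)
    light = lightfield.uniform(li) if li else lightfield.dark()
    rec = sim.run(800.0, light=light, stim=stim,
                  probes={"a": (0.75, 0.125), "b": (1.75, 0.125)},
                  probe_dt=0.1)
    results[li] = conduction_velocity(rec, "a", "b")
    print(f"LI = {li:5.3f} mW/mm^2:  CV = {results[li]:.2f} cm/s")

drop = 100.0 * (results[0.0] - results[0.02]) / results[0.0]
print(f"\nsub-threshold slowing: {drop:.1f} % "
      "(light raises resting V, reducing Na+ availability)")
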