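"""Single-cell response to sub-threshold light.

Finds the dark resting state of the mouse ventricular cell model, applies
increasing constant irradiances, and prints the light-induced shift of the
resting membrane potential together with the excitation threshold L*.
Irradiances below L* depolarize the cell without firing an action
potential — the regime every protocol in this package operates in.
"""

from optodrift import IonicParams, find_resting_state, find_threshold_light
from optodrift.ionic import I_V

params = IonicParams()

print("irradiance (mW/mm^2)   resting V (mV)")
v0 = None
for li in (0.0, 0.005, 0.01, 0.015, 0.02):
    v = find_resting_state(params, li)[I_V]
    v0 = v if v0 is None else v0
    print(f"  {li:8.3f}            {v:8.2f}   (+{v - v0:.2f} mV)")

lstar = find_threshold_light(params, tol=2e-3, LI_max=0.2)
print(f"\nexcitation threshold L* = {lstar:.3f} mW/mm^2")
print("all study intensities (<= 0.02) are sub-threshold:",
      0.02 < lstar)
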