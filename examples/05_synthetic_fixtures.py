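"""The synthetic-fixture suite: analysis operations vs analytic truth.

Generates a decaying-drift tip trajectory (parameters from the reported
single-step fits), a plane-wave movie, and a rotating-phase movie — each
carrying closed-form ground truth — and shows that the measurement
pipeline (core-series drift fit, conduction velocity, dominant frequency)
recovers the generating parameters.
"""

from optodrift.drift import core_series, fit_drift_decay
from optodrift.fixtures import FixtureSpec, make_movie, make_trajectory
from optodrift.wave_metrics import conduction_velocity, dominant_frequency

traj, truth = make_trajectory(FixtureSpec(
    "decaying_drift_traj",
    {"radius": 0.25, "freq_hz": 15.3, "V0_mm_s": 14.0, "tau_s": 0.39},
    dt_ms=1.0, duration_ms=2000.0))
core = core_series(traj, rotation_period=1000.0 / 15.3)
fit = fit_drift_decay(core)
print("decaying-drift trajectory:")
print(f"  truth  V0 = {truth['V0_mm_s']:.1f} mm/s, tau = {truth['tau_s']:.2f} s")
print(f"  fitted V0 = {fit.V0_mm_s:.2f} mm/s, tau = {fit.tau_s:.3f} s")

rec, truth = make_movie(FixtureSpec("plane_wave_movie",
                                    {"speed_cm_s": 43.9},
                                    duration_ms=400.0))
cv = conduction_velocity(rec, "a", "b")
print(f"\nplane-wave movie: truth {truth['speed_cm_s']} cm/s, "
      f"measured {cv:.2f} cm/s")

from optodrift.tissue import Grid

spec = FixtureSpec("rotating_phase_movie", {"freq_hz": 15.3},
                   grid=Grid(nx=60, ny=60), duration_ms=1000.0)
rec, truth = make_movie(spec)
df = dominant_frequency(rec.probe_times, rec.probe("a")).df_hz
print(f"rotating-phase movie: truth {truth['freq_hz']} Hz, "
      f"measured {df:.2f} Hz")
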