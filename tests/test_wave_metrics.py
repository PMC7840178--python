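"""Conduction velocity, dominant frequency and gradient-profile statistics
against analytic fixtures."""

import numpy as np
import pytest

from optodrift.fixtures import FixtureSpec, make_movie, make_quiescent_profile
from optodrift.recording import Recording
from optodrift.wave_metrics import (NoActivationError, ProfileSeries,
                                    activation_times, conduction_velocity,
                                    dominant_frequency,
                                    gradient_profile_stats)


def _two_probe_recording(ta, tb, dt=0.1, dur=60.0, dist=1.0):
    t = np.arange(dt, dur, dt)

    def upstroke(t0):
        return np.where(t >= t0, 30.0, -80.0)

    return Recording(probe_times=t,
                     probes={"a": upstroke(ta), "b": upstroke(tb)},
                     probe_positions={"a": (0.75, 0.1),
                                      "b": (0.75 + dist, 0.1)})


def test_cv_from_known_activation_times():
    # crossings 20 ms apart over 1.0 cm -> 50 cm/s
    rec = _two_probe_recording(10.0, 30.0, dist=1.0)
    assert conduction_velocity(rec, "a", "b") == pytest.approx(50.0, rel=1e-3)
    # probes closer than 0.5 cm are refused
    rec_close = _two_probe_recording(10.0, 20.0, dist=0.3)
    with pytest.raises(ValueError, match="0.5"):
        conduction_velocity(rec_close, "a", "b")


def test_cv_errors():
    rec = _two_probe_recording(10.0, 20.0, dist=1.0)
    rec.probes["b"][:] = -80.0
    with pytest.raises(NoActivationError):
        conduction_velocity(rec, "a", "b")


def test_activation_time_interpolation_is_subsample():
    t = np.arange(0.0, 10.0, 1.0)
    v = np.full_like(t, -80.0)
    v[5:] = 20.0  # crossing between 4 and 5, -20 at 4 + (60/100)
    at = activation_times(t, v)
    assert at[0] == pytest.approx(4.6)


def test_cv_on_synthetic_plane_wave_movie():
    rec, truth = make_movie(FixtureSpec("plane_wave_movie",
                                        {"speed_cm_s": 43.9},
                                        duration_ms=400.0))
    cv = conduction_velocity(rec, "a", "b")
    assert cv == pytest.approx(truth["speed_cm_s"], abs=0.5)


def test_cv_invariant_to_probe_placement():
    rec, _ = make_movie(FixtureSpec("plane_wave_movie",
                                    {"speed_cm_s": 40.0},
                                    duration_ms=400.0))
    # rebuild probes at other positions from snapshots
    g = rec.meta["grid"]
    dx = g["dx"]
    for (xa, xb) in ((0.5, 1.5), (1.0, 2.0)):
        ia, ib = int(xa / dx - 0.5), int(xb / dx - 0.5)
        r2 = Recording(
            probe_times=rec.probe_times,
            probes={"a": rec.snapshots[:, 4, ia].astype(float),
                    "b": rec.snapshots[:, 4, ib].astype(float)},
            probe_positions={"a": (xa, 0.1), "b": (xb, 0.1)})
        assert conduction_velocity(r2, "a", "b") == pytest.approx(40.0,
                                                                  rel=0.01)


@pytest.mark.parametrize("freq", [7.0, 15.3, 24.0])
def test_dominant_frequency_recovers_pure_tone(freq):
    t = np.arange(1.0, 1500.0, 1.0)
    v = np.sin(2 * np.pi * freq * t / 1000.0)
    sp = dominant_frequency(t, v)
    assert sp.df_hz == pytest.approx(freq, abs=sp.resolution_hz)
    assert sp.resolution_hz == pytest.approx(1000.0 / sp.window_ms)


def test_dominant_frequency_window_lengths():
    """A pure tone lands within one raw bin for any window >= 5 periods."""
    f = 15.3
    for window in (400.0, 700.0, 1200.0):
        t = np.arange(1.0, window + 0.5, 1.0)
        v = np.cos(2 * np.pi * f * t / 1000.0)
        sp = dominant_frequency(t, v, expected_hz=f)
        assert abs(sp.df_hz - f) <= sp.resolution_hz


def test_dominant_frequency_pulse_train_fundamental():
    t = np.arange(1.0, 2000.0, 1.0)
    v = np.where((t % 100.0) < 15.0, 20.0, -80.0)   # 10 Hz train
    assert dominant_frequency(t, v).df_hz == pytest.approx(10.0, abs=0.5)


def test_dominant_frequency_short_window_raises():
    t = np.arange(1.0, 200.0, 1.0)
    v = np.sin(2 * np.pi * 15.3 * t / 1000.0)
    with pytest.raises(ValueError, match="resolution"):
        dominant_frequency(t, v, expected_hz=15.3)


def test_nonuniform_sampling_rejected():
    t = np.array([0.0, 1.0, 2.5, 3.0])
    with pytest.raises(ValueError, match="uniform"):
        dominant_frequency(t, np.zeros(4))


def test_gradient_stats_gaussian_analytic():
    """|dV/dx| of a Gaussian has its peak at +-sigma; peak value and
    width at 10% checked against a dense numeric reference."""
    sigma, A = 0.1, 6.0
    x = (np.arange(200) + 0.5) * 0.0125
    mu = x.mean()
    V = -80.0 + A * np.exp(-((x - mu) ** 2) / (2 * sigma ** 2))
    prof = ProfileSeries(times=np.array([0.0]), x=x, V=V[None, :])
    stats = gradient_profile_stats(prof)
    # dense reference
    xd = np.linspace(x[0], x[-1], 200001)
    gd = np.abs(-A * (xd - mu) / sigma ** 2
                * np.exp(-((xd - mu) ** 2) / (2 * sigma ** 2)))
    peak_ref = gd.max()
    lvl = 0.1 * peak_ref
    above = np.where(gd >= lvl)[0]
    width_ref = xd[above[-1]] - xd[above[0]]
    assert stats.peak_mV_cm[0] == pytest.approx(peak_ref, rel=0.02)
    assert stats.width_cm[0] == pytest.approx(width_ref, rel=0.02)
    assert abs(abs(stats.x_peak_cm[0] - mu) - sigma) < 0.02


def test_gradient_stats_flat_profile():
    x = np.linspace(0, 2.5, 100)
    prof = ProfileSeries(times=np.array([0.0]), x=x,
                         V=np.full((1, 100), -80.0))
    stats = gradient_profile_stats(prof)
    assert stats.peak_mV_cm[0] == 0.0
    assert np.isnan(stats.width_cm[0])


def test_gradient_stats_invariant_to_voltage_offset():
    series, _ = make_quiescent_profile(FixtureSpec(
        "quiescent_profile", {"shape": "logistic", "amplitude_mv": 5.0},
        duration_ms=500.0))
    shifted = ProfileSeries(times=series.times, x=series.x, V=series.V + 17.3)
    a = gradient_profile_stats(series)
    b = gradient_profile_stats(shifted)
    np.testing.assert_allclose(a.peak_mV_cm, b.peak_mV_cm)
    np.testing.assert_allclose(a.width_cm, b.width_cm)


def test_step_interface_gradient_dominates_linear_gradient():
    """For equal voltage span, a logistic step concentrates |dV/dx| into an
    order-of-magnitude larger peak than a full-domain linear ramp."""
    step, t_step = make_quiescent_profile(FixtureSpec(
        "quiescent_profile", {"shape": "logistic", "scale_cm": 0.05,
                              "amplitude_mv": 5.0}))
    ramp, t_ramp = make_quiescent_profile(FixtureSpec(
        "quiescent_profile", {"shape": "ramp", "amplitude_mv": 5.0}))
    ps = gradient_profile_stats(step).peak_mV_cm.iloc[-1]
    pr = gradient_profile_stats(ramp).peak_mV_cm.iloc[-1]
    assert ps > 8.0 * pr
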