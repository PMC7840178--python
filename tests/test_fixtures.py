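"""Synthetic fixtures: determinism and ground-truth consistency with the
analysis operations (the fixture suite is the analysis test surface)."""

import numpy as np
import pytest

from optodrift.drift import core_series, curvature, fit_drift_decay, tip_speed
from optodrift.fixtures import (FixtureSpec, make_movie, make_quiescent_profile,
                                make_trajectory)
from optodrift.wave_metrics import (conduction_velocity, dominant_frequency,
                                    gradient_profile_stats)


def test_unknown_kind_rejected():
    with pytest.raises(ValueError, match="unknown fixture kind"):
        FixtureSpec("squiggle_traj")
    with pytest.raises(ValueError, match="movie"):
        make_movie(FixtureSpec("circle_traj"))
    with pytest.raises(ValueError, match="trajectory"):
        make_trajectory(FixtureSpec("plane_wave_movie"))


def test_generation_is_deterministic_per_seed():
    spec = FixtureSpec("decaying_drift_traj",
                       {"radius": 0.3, "noise": 0.05}, seed=42)
    a, _ = make_trajectory(spec)
    b, _ = make_trajectory(spec)
    np.testing.assert_array_equal(a.x, b.x)
    c, _ = make_trajectory(FixtureSpec("decaying_drift_traj",
                                       {"radius": 0.3, "noise": 0.05},
                                       seed=43))
    assert not np.array_equal(a.x, c.x)


def test_movie_noise_deterministic():
    spec = FixtureSpec("plane_wave_movie", {"noise_mv": 2.0},
                       duration_ms=50.0, seed=9)
    r1, _ = make_movie(spec)
    r2, _ = make_movie(spec)
    np.testing.assert_array_equal(r1.snapshots, r2.snapshots)


def test_circle_truth_reproduced_by_analysis():
    traj, truth = make_trajectory(FixtureSpec(
        "circle_traj", {"radius": 0.5, "freq_hz": 15.3},
        dt_ms=1.0, duration_ms=500.0))
    assert truth["curvature_cm"] == pytest.approx(2.0)
    np.testing.assert_allclose(np.abs(curvature(traj))[10:-10],
                               truth["curvature_cm"], rtol=0.01)
    np.testing.assert_allclose(tip_speed(traj)[10:-10],
                               truth["rot_speed_mm_s"], rtol=0.01)


def test_decaying_drift_truth_displacement():
    spec = FixtureSpec("decaying_drift_traj",
                       {"radius": 0.25, "freq_hz": 15.0,
                        "V0_mm_s": 20.0, "tau_s": 0.35},
                       dt_ms=1.0, duration_ms=2000.0)
    traj, truth = make_trajectory(spec)
    # closed form: V0 tau (1 - e^(-T/tau)) = 0.698 cm at T = 2 s
    assert truth["displacement_cm"] == pytest.approx(0.698, abs=2e-3)
    core = core_series(traj, rotation_period=1000.0 / 15.0)
    fit = fit_drift_decay(core)
    assert fit.V0_mm_s == pytest.approx(20.0, rel=0.02)
    assert fit.tau_s == pytest.approx(0.35, rel=0.03)
    # displacement relative to the known initial core position
    assert core.displacement_cm(origin=1.25) == pytest.approx(
        truth["displacement_cm"], rel=0.02)


def test_plane_wave_truth_recovered():
    rec, truth = make_movie(FixtureSpec("plane_wave_movie",
                                        {"speed_cm_s": 43.9},
                                        duration_ms=400.0))
    assert conduction_velocity(rec, "a", "b") == pytest.approx(
        truth["speed_cm_s"], abs=0.5)


def test_rotating_phase_truth_recovered():
    from optodrift.tissue import Grid

    spec = FixtureSpec("rotating_phase_movie", {"freq_hz": 15.3},
                       grid=Grid(nx=60, ny=60), duration_ms=1000.0)
    rec, truth = make_movie(spec)
    sp = dominant_frequency(rec.probe_times, rec.probe("a"))
    assert abs(sp.df_hz - truth["freq_hz"]) <= sp.resolution_hz


def test_logistic_profile_truth_within_two_percent():
    # fine grid so central differences resolve the 0.05 cm interface scale
    from optodrift.tissue import Grid

    series, truth = make_quiescent_profile(FixtureSpec(
        "quiescent_profile", {"shape": "logistic", "scale_cm": 0.05,
                              "amplitude_mv": 5.0},
        grid=Grid(nx=400, ny=4, dx=0.00625)))
    stats = gradient_profile_stats(series)
    assert stats.peak_mV_cm.iloc[-1] == pytest.approx(truth["peak_mV_cm"],
                                                      rel=0.02)
    assert stats.width_cm.iloc[-1] == pytest.approx(truth["width_cm"],
                                                    rel=0.02)


def test_ramp_profile_constant_gradient():
    series, truth = make_quiescent_profile(FixtureSpec(
        "quiescent_profile", {"shape": "ramp", "amplitude_mv": 4.0}))
    g = np.abs(series.dVdx()[-1])
    np.testing.assert_allclose(g, truth["peak_mV_cm"], rtol=1e-6)
    stats = gradient_profile_stats(series)
    assert stats.width_cm.iloc[-1] == pytest.approx(truth["width_cm"],
                                                    rel=0.02)


def test_zero_amplitude_profile_is_flat():
    series, _ = make_quiescent_profile(FixtureSpec(
        "quiescent_profile", {"shape": "logistic", "amplitude_mv": 0.0}))
    stats = gradient_profile_stats(series)
    assert stats.peak_mV_cm.iloc[-1] == 0.0


def test_fixture_recording_roundtrip(tmp_path):
    rec, _ = make_movie(FixtureSpec("plane_wave_movie", duration_ms=30.0))
    path = tmp_path / "fixture.h5"
    rec.save(path)
    from optodrift.recording import Recording

    back = Recording.load(path)
    np.testing.assert_array_equal(back.probe_times, rec.probe_times)
    np.testing.assert_allclose(back.snapshots, rec.snapshots)
    assert back.meta["fixture"] == "plane_wave_movie"
    assert back.probe_positions["a"] == (0.75, 0.125)
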