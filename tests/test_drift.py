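"""Tip detection, trajectory geometry (curvature/speed), core series,
exponential drift fits, against analytic fixtures."""

import numpy as np
import pytest

from optodrift.drift import (CoreSeries, DriftFit, TipTrajectory, core_series,
                             curvature, detect_tip, fit_drift_decay,
                             integrated_displacement, tip_speed, track_tips,
                             average_msd)
from optodrift.fixtures import FixtureSpec, make_movie, make_trajectory
from optodrift.tissue import Grid


# ---------------------------------------------------------------------------
# tip detection
# ---------------------------------------------------------------------------

def test_plane_wave_has_no_tips():
    rec, _ = make_movie(FixtureSpec("plane_wave_movie", duration_ms=50.0))
    g = Grid(nx=100, ny=10)
    tips = detect_tip(rec.snapshots[20], rec.snapshots[21], g)
    assert tips == []


def test_rotating_phase_singularity_located_within_one_cell():
    spec = FixtureSpec("rotating_phase_movie",
                       {"freq_hz": 15.3, "cx": 1.0, "cy": 1.2},
                       grid=Grid(nx=100, ny=100), duration_ms=80.0)
    rec, truth = make_movie(spec)
    g = spec.grid
    tips = detect_tip(rec.snapshots[30], rec.snapshots[31], g)
    assert len(tips) == 1
    x, y, q = tips[0]
    assert abs(x - truth["tip"][0]) <= g.dx
    assert abs(y - truth["tip"][1]) <= g.dx


def test_static_field_has_no_tips():
    spec = FixtureSpec("rotating_phase_movie", {"freq_hz": 0.0},
                       grid=Grid(nx=60, ny=60), duration_ms=10.0)
    rec, _ = make_movie(spec)
    tips = detect_tip(rec.snapshots[3], rec.snapshots[4], spec.grid)
    assert tips == []


def test_track_tips_follows_singularity():
    spec = FixtureSpec("rotating_phase_movie",
                       {"freq_hz": 15.3, "cx": 1.3, "cy": 0.9},
                       grid=Grid(nx=100, ny=100), duration_ms=100.0)
    rec, truth = make_movie(spec)
    traj = track_tips(rec.snapshots, rec.snap_times, spec.grid)
    assert len(traj) > 80
    assert np.all(np.hypot(traj.x - 1.3, traj.y - 0.9) < 2 * spec.grid.dx)


# ---------------------------------------------------------------------------
# curvature and speed
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("radius", [0.05, 0.1, 0.3, 0.5, 1.0])
def test_circle_curvature_is_inverse_radius(radius):
    traj, truth = make_trajectory(FixtureSpec(
        "circle_traj", {"radius": radius, "freq_hz": 15.3},
        dt_ms=1.0, duration_ms=400.0))
    k = curvature(traj)
    mid = k[20:-20]
    np.testing.assert_allclose(np.abs(mid), 1.0 / radius, rtol=0.01)


def test_straight_line_curvature_zero():
    t = np.arange(0.0, 200.0, 1.0)
    traj = TipTrajectory(t=t, x=0.001 * t, y=0.0005 * t)
    k = curvature(traj)
    np.testing.assert_allclose(k[5:-5], 0.0, atol=1e-9)


def test_cycloid_curvature_matches_symbolic_oracle():
    """Signed curvature of a cycloidal trajectory against exact symbolic
    differentiation of the parametrization."""
    import sympy as sp

    R, f, vx = 0.3, 12.0, 30.0          # cm, Hz, mm/s
    traj, _ = make_trajectory(FixtureSpec(
        "cycloid_traj", {"radius": R, "freq_hz": f, "vx_mm_s": vx},
        dt_ms=1.0, duration_ms=500.0))
    ts = sp.symbols("t")                 # ms
    w = 2 * sp.pi * f / 1000
    xs = sp.Float(1.25) + (vx / 1.0e4) * ts + R * sp.cos(w * ts)
    ys = sp.Float(1.25) + R * sp.sin(w * ts)
    x1, y1 = sp.diff(xs, ts), sp.diff(ys, ts)
    x2, y2 = sp.diff(x1, ts), sp.diff(y1, ts)
    k_sym = sp.lambdify(ts, (x1 * y2 - y1 * x2) / (x1 ** 2 + y1 ** 2) ** sp.Rational(3, 2))
    k_num = curvature(traj)
    sel = slice(25, -25)
    np.testing.assert_allclose(k_num[sel], k_sym(traj.t[sel]), rtol=0.02)


def test_circle_speed_closed_form():
    traj, truth = make_trajectory(FixtureSpec(
        "circle_traj", {"radius": 0.5, "freq_hz": 15.3},
        dt_ms=1.0, duration_ms=400.0))
    sp_ = tip_speed(traj)
    np.testing.assert_allclose(sp_[10:-10], truth["rot_speed_mm_s"],
                               rtol=0.01)
    assert truth["rot_speed_mm_s"] == pytest.approx(2 * np.pi * 0.5 * 15.3
                                                    * 10.0)


def test_stationary_point_speed_zero_curvature_undefined():
    traj, _ = make_trajectory(FixtureSpec(
        "circle_traj", {"radius": 0.0, "freq_hz": 15.3},
        dt_ms=1.0, duration_ms=100.0))
    assert np.all(tip_speed(traj) < 1e-9)
    assert np.all(np.isnan(curvature(traj)))


def test_geometry_invariant_under_rigid_motion():
    traj, _ = make_trajectory(FixtureSpec(
        "decaying_drift_traj", {"radius": 0.3, "freq_hz": 15.0,
                                "V0_mm_s": 14.0, "tau_s": 0.39},
        dt_ms=1.0, duration_ms=600.0))
    th, dx, dy = 0.7, 0.9, -0.4
    xr = np.cos(th) * traj.x - np.sin(th) * traj.y + dx
    yr = np.sin(th) * traj.x + np.cos(th) * traj.y + dy
    moved = TipTrajectory(t=traj.t, x=xr, y=yr)
    np.testing.assert_allclose(np.abs(curvature(moved)),
                               np.abs(curvature(traj)), rtol=1e-6)
    np.testing.assert_allclose(tip_speed(moved), tip_speed(traj), rtol=1e-6)


def test_speed_minima_coincide_with_curvature_maxima():
    """On a drifting spiral-tip trajectory the cusps (curvature peaks) are
    the slow points of the tip."""
    traj, _ = make_trajectory(FixtureSpec(
        "cycloid_traj", {"radius": 0.2, "freq_hz": 15.0, "vx_mm_s": 60.0},
        dt_ms=1.0, duration_ms=500.0))
    k = np.abs(curvature(traj))[20:-20]
    v = tip_speed(traj)[20:-20]
    # at curvature peaks, speed is near its minimum
    peaks = np.where((k[1:-1] > k[:-2]) & (k[1:-1] > k[2:]))[0] + 1
    assert len(peaks) >= 5
    v_lo, v_hi = v.min(), v.max()
    assert np.all(v[peaks] < v_lo + 0.25 * (v_hi - v_lo))


# ---------------------------------------------------------------------------
# core series
# ---------------------------------------------------------------------------

def test_core_of_perfect_circle():
    traj, _ = make_trajectory(FixtureSpec(
        "circle_traj", {"radius": 0.4, "freq_hz": 10.0},
        dt_ms=1.0, duration_ms=1000.0))
    core = core_series(traj, rotation_period=100.0)
    np.testing.assert_allclose(core.d_core, 0.8, rtol=0.01)
    assert core.displacement_cm() < 1e-6
    _, msd = core.msd_cm2()
    assert np.all(msd < 1e-10)
    assert core.termination_ms is None


def test_core_msd_of_constant_drift():
    v_mm_s = 10.0
    traj, _ = make_trajectory(FixtureSpec(
        "cycloid_traj", {"radius": 0.2, "freq_hz": 10.0, "vx_mm_s": v_mm_s},
        dt_ms=1.0, duration_ms=2000.0))
    core = core_series(traj, rotation_period=100.0)
    ts, msd = core.msd_cm2()
    v_cm_ms = v_mm_s / 1.0e4
    np.testing.assert_allclose(msd[1:], (v_cm_ms * ts[1:]) ** 2, rtol=0.02)


def test_core_requires_two_rotations():
    traj, _ = make_trajectory(FixtureSpec(
        "circle_traj", {"radius": 0.4, "freq_hz": 10.0},
        dt_ms=1.0, duration_ms=150.0))
    with pytest.raises(ValueError, match="rotation"):
        core_series(traj, rotation_period=100.0)


def test_average_msd_truncates_and_averages():
    cores = []
    for v in (10.0, 20.0):
        traj, _ = make_trajectory(FixtureSpec(
            "cycloid_traj", {"radius": 0.2, "freq_hz": 10.0, "vx_mm_s": v},
            dt_ms=1.0, duration_ms=1000.0 if v == 10.0 else 1400.0))
        cores.append(core_series(traj, rotation_period=100.0))
    ts, m = average_msd(cores)
    assert len(ts) == min(len(c.t) for c in cores)
    v1, v2 = 10.0 / 1e4, 20.0 / 1e4
    np.testing.assert_allclose(m[1:], 0.5 * ((v1 * ts[1:]) ** 2
                                             + (v2 * ts[1:]) ** 2), rtol=0.03)


# ---------------------------------------------------------------------------
# drift decay fits
# ---------------------------------------------------------------------------

def _core_from_decay(V0, tau_s, duration_ms=2000.0, period=65.0, noise=0.0,
                     seed=0):
    traj, _ = make_trajectory(FixtureSpec(
        "decaying_drift_traj", {"radius": 0.25, "freq_hz": 1000.0 / period,
                                "V0_mm_s": V0, "tau_s": tau_s},
        dt_ms=1.0, duration_ms=duration_ms, seed=seed))
    core = core_series(traj, rotation_period=period)
    if noise > 0:
        rng = np.random.default_rng(seed)
        cx = core.cx[0] + np.concatenate(
            [[0.0], np.cumsum(np.diff(core.cx)
                              * (1 + noise * rng.standard_normal(len(core.cx) - 1)))])
        core = CoreSeries(t=core.t, cx=cx, cy=core.cy, d_core=core.d_core,
                          rotation_period=core.rotation_period)
    return core


def test_exact_speed_samples_recovered_to_machine_precision():
    """Exact samples of 14 exp(-t/0.39) mm/s placed on per-rotation center
    spacings are fitted back to the generating parameters to 1e-6."""
    V0, tau, T = 14.0, 0.39, 65.0
    t_centers = (np.arange(31) + 0.5) * T
    t_mid = 0.5 * (t_centers[1:] + t_centers[:-1])
    v = V0 * np.exp(-t_mid / (tau * 1000.0))            # mm/s
    dx_cm = v * (T / 1000.0) / 10.0
    cx = 1.0 + np.concatenate([[0.0], np.cumsum(dx_cm)])
    core = CoreSeries(t=t_centers, cx=cx, cy=np.full_like(cx, 1.2),
                      d_core=np.full_like(cx, 0.5), rotation_period=T)
    fit = fit_drift_decay(core)
    assert fit.ok
    assert fit.V0_mm_s == pytest.approx(V0, rel=1e-6)
    assert fit.tau_s == pytest.approx(tau, rel=1e-6)
    assert fit.residual < 1e-9


def test_decay_recovered_through_trajectory_pipeline():
    """The full pipeline (tip trajectory -> per-rotation centers -> fit)
    recovers the generating decay to within the per-rotation
    discretization (~1%)."""
    core = _core_from_decay(14.0, 0.39)
    fit = fit_drift_decay(core)
    assert fit.ok
    assert fit.V0_mm_s == pytest.approx(14.0, rel=0.01)
    assert fit.tau_s == pytest.approx(0.39, rel=0.02)


@pytest.mark.parametrize("V0,tau", [(1.0, 1.1), (8.0, 0.49), (14.0, 0.39),
                                    (20.0, 0.35)])
def test_noisy_recovery_within_ten_percent_median(V0, tau):
    """5% multiplicative speed noise, 50 replicates: median recovered
    (V0, tau) within 10% of truth across the studied parameter range."""
    v0s, taus = [], []
    for rep in range(50):
        core = _core_from_decay(V0, tau, noise=0.05, seed=rep)
        fit = fit_drift_decay(core)
        v0s.append(fit.V0_mm_s)
        taus.append(fit.tau_s)
    assert abs(np.median(v0s) - V0) / V0 < 0.10
    assert abs(np.median(taus) - tau) / tau < 0.10


def test_constant_speed_fit_flagged():
    core = _core_from_decay(10.0, 1e9, duration_ms=1500.0)
    fit = fit_drift_decay(core)
    assert not fit.ok
    assert "decay" in fit.note


def test_fit_requires_enough_samples():
    core = _core_from_decay(14.0, 0.39, duration_ms=400.0)
    with pytest.raises(ValueError, match="6"):
        fit_drift_decay(core)


def test_integrated_displacement_closed_forms():
    fit = DriftFit(V0_mm_s=1.0, tau_s=1.1, residual=0.0, window_s=(0, 2))
    # 1 mm/s * 1.1 s * (1 - e^(-2/1.1)) = 0.9214 mm = 0.0921 cm (~0.09)
    assert integrated_displacement(fit, 2.0) == pytest.approx(0.09214,
                                                              abs=1e-4)
    assert integrated_displacement(fit, 1e-12) == pytest.approx(0.0,
                                                                abs=1e-9)
    assert integrated_displacement(fit, 1e9) == pytest.approx(
        1.0 * 1.1 / 10.0, rel=1e-9)


def test_trajectory_validation():
    with pytest.raises(ValueError, match="increasing"):
        TipTrajectory(t=np.array([0.0, 2.0, 1.0]), x=np.zeros(3),
                      y=np.zeros(3))
    with pytest.raises(ValueError, match="length"):
        TipTrajectory(t=np.array([0.0, 1.0]), x=np.zeros(3), y=np.zeros(2))
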