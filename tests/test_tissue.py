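"""Monodomain solver: discrete Laplacian, conservation, homogeneity,
isotropy, determinism and sub-threshold soundness."""

import numpy as np
import pytest

from optodrift import cell
from optodrift.ionic import I_V, IonicParams
from optodrift.lightfield import dark, linear_gradient, single_step, uniform
from optodrift.tissue import (Grid, QuadrantInit, StimulusProtocol,
                              SubThresholdViolationError, TissueSim,
                              laplacian_noflux, quiescent_profile_run)
from optodrift.wave_metrics import activation_times


def test_laplacian_constant_field_is_zero_everywhere():
    g = Grid(nx=7, ny=5, dx=1.0, D=1e-3)
    f = np.full((5, 7), 3.7)
    np.testing.assert_array_equal(laplacian_noflux(f, g), 0.0)


def test_laplacian_point_source_stencil():
    g = Grid(nx=5, ny=5, dx=1.0, D=1e-3)
    f = np.zeros((5, 5))
    f[2, 2] = 1.0
    lap = laplacian_noflux(f, g)
    assert lap[2, 2] == -4.0
    for r, c in ((1, 2), (3, 2), (2, 1), (2, 3)):
        assert lap[r, c] == 1.0
    assert lap[0, 0] == 0.0


def test_laplacian_linear_ramp_mirror_boundaries():
    """On f = c*x the interior Laplacian vanishes; the boundary columns
    carry the one-sided second difference of the face-mirrored ghost
    (ghost = edge node), hand-computed for a 5x5 case."""
    c, dx = 2.0, 0.5
    g = Grid(nx=5, ny=5, dx=dx, D=1e-3)
    x = (np.arange(5) + 0.5) * dx
    f = np.tile(c * x, (5, 1))
    lap = laplacian_noflux(f, g)
    np.testing.assert_allclose(lap[:, 1:-1][1:-1], 0.0, atol=1e-12)
    # at ix=0: ghost = f[:,0]  ->  (f0 + f1 - 2 f0)/dx^2 = c/dx
    np.testing.assert_allclose(lap[:, 0], c / dx, rtol=1e-12)
    np.testing.assert_allclose(lap[:, -1], -c / dx, rtol=1e-12)


def test_laplacian_shape_mismatch():
    g = Grid(nx=5, ny=5, dx=1.0, D=1e-3)
    with pytest.raises(ValueError, match="shape"):
        laplacian_noflux(np.zeros((4, 5)), g)


def test_explicit_diffusion_conserves_total():
    """With no reaction, the mirrored-ghost diffusion update conserves the
    field total to round-off (no-flux boundaries leak nothing)."""
    g = Grid(nx=30, ny=20, dx=0.025, D=0.00157)
    rng = np.random.default_rng(3)
    f = rng.uniform(-80.0, 20.0, size=(20, 30))
    total0 = f.sum()
    dt = 0.05
    for _ in range(200):
        f = f + dt * g.D * laplacian_noflux(f, g)
    assert f.sum() == pytest.approx(total0, rel=1e-12)


def test_grid_validation_and_stability_bound():
    with pytest.raises(ValueError):
        Grid(nx=2, ny=5)
    with pytest.raises(ValueError):
        Grid(dx=-1.0)
    g = Grid()
    assert g.max_stable_dt() == pytest.approx(0.25 * g.dx ** 2 / g.D)
    with pytest.warns(UserWarning, match="stability"):
        TissueSim(g, IonicParams(), dt=10.0)


def test_homogeneous_state_stays_homogeneous_under_uniform_light(params):
    sim = TissueSim(Grid(nx=8, ny=8), params, dt=0.005)
    sim.init_resting()
    rec = sim.run(100.0, light=uniform(0.01), probes={}, probe_dt=100.0,
                  snapshot_dt=50.0)
    v = rec.snapshots[-1].astype(np.float64)
    assert v.max() - v.min() < 1e-9
    # voltage rose under light
    assert v.mean() > cell.find_resting_state(params, 0.0)[I_V] + 0.05


def test_run_is_deterministic(params):
    def go():
        sim = TissueSim(Grid(nx=20, ny=6), params, dt=0.005)
        sim.init_resting()
        stim = StimulusProtocol(amplitude=60.0, pulse_ms=2.0, cl=100.0,
                                n_pulses=1, columns=2)
        return sim.run(60.0, stim=stim, probes={"a": (0.25, 0.075)},
                       probe_dt=0.5).probe("a")

    a, b = go(), go()
    np.testing.assert_array_equal(a, b)


def test_snapshot_stride_must_divide_steps(params):
    sim = TissueSim(Grid(nx=5, ny=5), params, dt=0.005)
    sim.init_resting()
    with pytest.raises(ValueError, match="stride"):
        sim.run(10.0, snapshot_dt=3.0)


def test_conduction_is_isotropic(params):
    """CV along x in a horizontal strip equals CV along y in the transposed
    strip to a small fraction of a percent."""
    def cv(nx, ny, along_x):
        g = Grid(nx=nx, ny=ny)
        sim = TissueSim(g, params, dt=0.005)
        sim.init_resting()
        if along_x:
            stim = StimulusProtocol(amplitude=60.0, pulse_ms=2.0, cl=200.0,
                                    n_pulses=1, columns=2)
            probes = {"a": (0.60, 0.075), "b": (1.30, 0.075)}
        else:
            mask = np.zeros((ny, nx), bool)
            mask[:2, :] = True
            stim = StimulusProtocol(amplitude=60.0, pulse_ms=2.0, cl=200.0,
                                    n_pulses=1, mask=mask)
            probes = {"a": (0.075, 0.60), "b": (0.075, 1.30)}
        rec = sim.run(80.0, stim=stim, probes=probes, probe_dt=0.05)
        ta = activation_times(rec.probe_times, rec.probe("a"))
        tb = activation_times(rec.probe_times, rec.probe("b"))
        return 0.70 / (tb[0] - ta[0]) * 1000.0

    cvx = cv(80, 6, True)
    cvy = cv(6, 80, False)
    assert abs(cvx - cvy) / cvx < 0.005


def test_cv_converges_under_dt_halving(params):
    def cv(dt):
        g = Grid(nx=80, ny=6)
        sim = TissueSim(g, params, dt=dt)
        sim.init_resting()
        stim = StimulusProtocol(amplitude=60.0, pulse_ms=2.0, cl=200.0,
                                n_pulses=1, columns=2)
        rec = sim.run(80.0, stim=stim,
                      probes={"a": (0.60, 0.075), "b": (1.30, 0.075)},
                      probe_dt=0.05)
        ta = activation_times(rec.probe_times, rec.probe("a"))
        tb = activation_times(rec.probe_times, rec.probe("b"))
        return 0.70 / (tb[0] - ta[0]) * 1000.0

    c1, c2 = cv(0.005), cv(0.0025)
    assert abs(c1 - c2) / c2 < 0.02


def test_cv_restitution_flattens_at_long_cycle_lengths(params):
    """The CV-restitution curve is flat between CL = 200 and 300 ms in the
    dark (difference below 2%), with 1:1 capture at both cycle lengths."""
    from optodrift.wave_metrics import cv_restitution

    curve = cv_restitution(0.0, (200.0, 300.0), params=params, n_beats=3)
    assert not np.any(np.isnan(curve.cv_cm_s))
    cv200, cv300 = curve.cv_cm_s
    assert abs(cv300 - cv200) / cv300 < 0.02


def test_quadrant_init_validation(templates):
    with pytest.raises(ValueError, match="missing"):
        QuadrantInit(templates={"rest": templates["rest"]})


def test_quiescent_profiles_shape_under_patterns(params):
    """A linear irradiance gradient produces a monotone quiescent V(x);
    a half-domain step produces a sigmoidal profile with its steepest
    gradient at the interface (run on a thin domain)."""
    g = Grid(nx=100, ny=8)
    prof_g = quiescent_profile_run(linear_gradient(0.0, 0.02), g,
                                   duration=300.0, params=params,
                                   y_line=0.1, sample_dt=150.0)
    v_end = prof_g.V[-1]
    assert v_end[-1] - v_end[0] > 0.5
    assert np.all(np.diff(v_end) > -1e-6)

    prof_s = quiescent_profile_run(single_step(0.01, 1.25), g,
                                   duration=300.0, params=params,
                                   y_line=0.1, sample_dt=150.0)
    grad = np.abs(np.gradient(prof_s.V[-1], prof_s.x))
    x_peak = prof_s.x[np.argmax(grad)]
    assert abs(x_peak - 1.25) < 0.15


def test_quiescent_run_flags_suprathreshold_light(params):
    g = Grid(nx=20, ny=8)
    with pytest.raises(SubThresholdViolationError):
        quiescent_profile_run(uniform(0.5), g, duration=200.0, params=params,
                              y_line=0.1, sample_dt=100.0)


def test_acceptance_patterns_are_subthreshold(params):
    """None of the illumination patterns used in the standard protocols fires
    a wave in quiescent tissue (thin-domain check)."""
    g = Grid(nx=60, ny=6)
    for light in (uniform(0.02), linear_gradient(0.0, 0.02, length=1.5),
                  single_step(0.015, 0.75, )):
        prof = quiescent_profile_run(light, g, duration=300.0, params=params,
                                     y_line=0.075, sample_dt=150.0)
        assert prof.V.max() < -20.0
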