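"""Irradiance patterns: geometry, schedules, closed forms, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from optodrift import lightfield as lf
from optodrift.tissue import Grid

GRID = Grid(nx=100, ny=100)
X, Y = GRID.node_coords()


def test_uniform_zero_is_dark():
    np.testing.assert_array_equal(lf.uniform(0.0).sample(X, Y),
                                  lf.dark().sample(X, Y))


def test_uniform_constant_everywhere():
    li = lf.uniform(0.02).sample(X, Y, t=123.0)
    assert np.all(li == 0.02)
    gx, gy = np.gradient(li)
    assert np.all(gx == 0) and np.all(gy == 0)


def test_linear_gradient_midline_and_magnitude():
    g = lf.linear_gradient(0.0, 0.01, length=2.5)
    mid = g.sample(np.array(1.25), np.array(0.5))
    assert mid == pytest.approx(0.005, rel=1e-6)
    # 0.02 over 25 mm -> 8e-4 mW/mm^3
    g2 = lf.linear_gradient(0.0, 0.02, length=2.5)
    assert lf.gradient_magnitude(g2) == pytest.approx(8.0e-4)


def test_degenerate_gradient_is_uniform():
    g = lf.linear_gradient(0.007, 0.007)
    assert np.all(g.sample(X, Y) == pytest.approx(0.007))


def test_single_step_geometry_and_integral():
    s = lf.single_step(0.01, boundary=1.25)
    li = s.sample(X, Y)
    assert np.all(li[:, X[0] >= 1.25] == 0.01)
    assert np.all(li[:, X[0] < 1.25] == 0.0)
    # integral = LI_on x illuminated area
    cell_area = GRID.dx ** 2
    area = (li > 0).sum() * cell_area
    assert (li.sum() * cell_area) == pytest.approx(0.01 * area)


def test_single_step_zero_is_dark():
    assert np.all(lf.single_step(0.0, 1.25).sample(X, Y) == 0.0)


def test_multi_step_schedule_arithmetic():
    m = lf.multi_step(0.01, pulse_length=500.0)
    # default widths (1.25, 0.875, 0.50, 0.125): at t=750 the second strip
    li = m.sample(X, Y, t=750.0)
    lit_width = (li[0] > 0).sum() * GRID.dx
    assert lit_width == pytest.approx(0.875, abs=GRID.dx)
    # beyond the schedule the last strip persists
    m2 = lf.multi_step(0.01, pulse_length=1000.0)
    li2 = m2.sample(X, Y, t=3500.0)
    assert (li2[0] > 0).sum() * GRID.dx == pytest.approx(0.125, abs=GRID.dx)


def test_multi_step_equals_single_step_at_each_instant():
    m = lf.multi_step(0.01, pulse_length=400.0)
    for t in (0.0, 399.0, 401.0, 900.0, 1300.0):
        k = min(int(t // 400.0), 3)
        width = m.params["widths"][k]
        s = lf.single_step(0.01, boundary=2.5 - width)
        np.testing.assert_array_equal(m.sample(X, Y, t), s.sample(X, Y))


def test_multi_step_single_full_width_is_uniform():
    m = lf.LightField("multi_step", {"LI_on": 0.01, "widths": [2.5],
                                     "pulse_length": 500.0, "length": 2.5})
    for t in (0.0, 2000.0):
        assert np.all(m.sample(X, Y, t) == 0.01)


def test_multi_step_rejects_nondecreasing_widths():
    with pytest.raises(ValueError, match="decreasing"):
        lf.multi_step(0.01, widths=(1.0, 1.2, 0.5))


def test_exponential_decay_closed_form():
    e = lf.exponential_decay(0.07, space_constant=0.6, length=2.5)
    at = lambda x_cm: float(e.sample(np.array(x_cm), np.array(0.5)))
    assert at(2.5) == pytest.approx(0.07, rel=1e-9)          # surface
    assert at(2.5 - 0.06) == pytest.approx(0.07 / np.e, rel=1e-9)
    assert at(2.5 - 0.12) == pytest.approx(0.07 * np.exp(-2.0), rel=1e-6)


def test_breakpoints_only_for_multistep():
    assert lf.uniform(0.01).time_breakpoints(2000.0) == []
    m = lf.multi_step(0.01, pulse_length=500.0)
    assert m.time_breakpoints(2000.0) == [500.0, 1000.0, 1500.0]
    assert m.time_breakpoints(800.0) == [500.0]


@given(x=st.floats(-1.0, 3.5), y=st.floats(-1.0, 3.5), t=st.floats(0, 4000))
@settings(max_examples=200, deadline=None)
def test_patterns_never_negative_and_deterministic(x, y, t):
    fields = [lf.uniform(0.015), lf.linear_gradient(0.0, 0.02),
              lf.single_step(0.01, 1.25), lf.multi_step(0.02),
              lf.exponential_decay(0.07)]
    for f in fields:
        v1 = f.sample(np.array(x), np.array(y), t)
        v2 = f.sample(np.array(x), np.array(y), t)
        assert v1 >= 0.0
        assert v1 == v2


def test_negative_intensity_rejected():
    for ctor in (lf.uniform, lambda a: lf.linear_gradient(a, 0.0),
                 lambda a: lf.single_step(a, 1.0),
                 lambda a: lf.multi_step(a),
                 lambda a: lf.exponential_decay(a)):
        with pytest.raises(ValueError):
            ctor(-0.01)


def test_roundtrip_serialization():
    m = lf.multi_step(0.01, pulse_length=640.0)
    m2 = lf.LightField.from_dict(m.to_dict())
    np.testing.assert_array_equal(m.sample(X, Y, 700.0),
                                  m2.sample(X, Y, 700.0))
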