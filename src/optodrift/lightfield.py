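"""Spatiotemporal irradiance patterns LI(x, y, t).

Five pattern families cover every illumination protocol this package
simulates:
dark/uniform global light, a linear intensity gradient along one axis, a
half-plane (single-step) pattern, a shrinking multi-step schedule of
right-anchored strips, and an exponential transmural decay profile
(space constant ~0.6 mm for blue light in cardiac tissue).

Patterns are pure, deterministic functions of (x, y, t); x, y in cm, t in
ms, irradiance in mW/mm^2.  All patterns used here are piecewise constant
in time, which the tissue driver exploits: ``time_breakpoints`` lists the
instants where the spatial pattern switches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LightField", "dark", "uniform", "linear_gradient", "single_step",
           "multi_step", "exponential_decay", "DEFAULT_SUBTHRESHOLD_CAP"]

# highest irradiance treated as sub-threshold in the default calibration
DEFAULT_SUBTHRESHOLD_CAP = 0.02  # mW/mm^2


@dataclass(frozen=True)
class LightField:
    """A named spatiotemporal irradiance pattern.

    ``kind`` is one of dark/uniform/linear_gradient/single_step/multi_step/
    exponential_decay; ``params`` the kind-specific parameters.  Evaluation
    is vectorized over coordinate arrays.
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _EVALUATORS:
            raise ValueError(f"unknown light pattern kind: {self.kind!r}")

    def sample(self, x, y, t: float = 0.0) -> np.ndarray:
        """Irradiance at coordinates (cm) and time (ms); never negative."""
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        out = _EVALUATORS[self.kind](self.params, x, y, float(t))
        return np.maximum(np.broadcast_to(out, np.broadcast_shapes(
            x.shape, y.shape)).astype(np.float64, copy=True), 0.0)

    def on_grid(self, grid, t: float = 0.0) -> np.ndarray:
        """Irradiance sampled at node centers of a :class:`~optodrift.tissue.Grid`."""
        X, Y = grid.node_coords()
        return self.sample(X, Y, t)

    def time_breakpoints(self, duration: float) -> list[float]:
        """Times in (0, duration) at which the spatial pattern changes."""
        if self.kind != "multi_step":
            return []
        pl = self.params["pulse_length"]
        ks = np.arange(1, len(self.params["widths"]))
        return [float(k * pl) for k in ks if 0.0 < k * pl < duration]

    def max_intensity(self) -> float:
        p = self.params
        return {
            "dark": 0.0,
            "uniform": p.get("LI0", 0.0),
            "linear_gradient": max(p["LI_left"], p["LI_right"]),
            "single_step": p["LI_on"],
            "multi_step": p["LI_on"],
            "exponential_decay": p["LI_surface"],
        }[self.kind]

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "LightField":
        return cls(d["kind"], dict(d.get("params", {})))


def _eval_dark(p, x, y, t):
    return np.zeros(np.broadcast_shapes(x.shape, y.shape))


def _eval_uniform(p, x, y, t):
    return np.full(np.broadcast_shapes(x.shape, y.shape), p["LI0"])


def _eval_linear(p, x, y, t):
    lo, hi = p["LI_left"], p["LI_right"]
    length = p["length"]
    c = x if p.get("axis", "x") == "x" else y
    return lo + (hi - lo) * np.clip(c / length, 0.0, 1.0)


def _eval_step(p, x, y, t):
    c = x if p.get("axis", "x") == "x" else y
    return np.where(c >= p["boundary"], p["LI_on"], 0.0)


def _eval_multi(p, x, y, t):
    widths = p["widths"]
    k = min(int(t // p["pulse_length"]), len(widths) - 1) if t >= 0 else 0
    boundary = p["length"] - widths[k]
    return np.where(x >= boundary, p["LI_on"], 0.0)


def _eval_expdecay(p, x, y, t):
    c = x if p.get("axis", "x") == "x" else y
    depth_mm = (p["length"] - c) * 10.0 if p.get("from_right", True) \
        else c * 10.0
    return p["LI_surface"] * np.exp(-depth_mm / p["space_constant"])


_EVALUATORS = {
    "dark": _eval_dark,
    "uniform": _eval_uniform,
    "linear_gradient": _eval_linear,
    "single_step": _eval_step,
    "multi_step": _eval_multi,
    "exponential_decay": _eval_expdecay,
}


def dark() -> LightField:
    return LightField("dark")


def uniform(LI0: float) -> LightField:
    """Global constant illumination at LI0 (mW/mm^2)."""
    if LI0 < 0:
        raise ValueError("irradiance must be non-negative")
    return LightField("uniform", {"LI0": float(LI0)})


def linear_gradient(LI_left: float, LI_right: float, length: float = 2.5,
                    axis: str = "x") -> LightField:
    """Linear irradiance ramp between the two domain boundaries.

    ``length`` is the domain extent along ``axis`` in cm.  The gradient
    magnitude in mW/mm^3 is |LI_right - LI_left| / (10 * length).
    """
    if LI_left < 0 or LI_right < 0:
        raise ValueError("irradiance must be non-negative")
    return LightField("linear_gradient", {
        "LI_left": float(LI_left), "LI_right": float(LI_right),
        "length": float(length), "axis": axis})


def gradient_magnitude(lf: LightField) -> float:
    """|dLI/dx| of a linear_gradient field, in mW/mm^3."""
    p = lf.params
    return abs(p["LI_right"] - p["LI_left"]) / (10.0 * p["length"])


def single_step(LI_on: float, boundary: float, axis: str = "x") -> LightField:
    """Uniform illumination of the half-domain beyond ``boundary`` (cm).

    The irradiance itself is discontinuous at the interface; the quiescent
    voltage profile across it is smoothed by tissue diffusion only.
    """
    if LI_on < 0:
        raise ValueError("irradiance must be non-negative")
    return LightField("single_step", {"LI_on": float(LI_on),
                                      "boundary": float(boundary),
                                      "axis": axis})


def multi_step(LI_on: float, widths=(1.25, 0.875, 0.50, 0.125),
               pulse_length: float = 500.0, length: float = 2.5) -> LightField:
    """Shrinking sequence of right-anchored illuminated strips.

    Each strip width (cm) is held for ``pulse_length`` ms; the default
    schedule shrinks from half to a twentieth of the domain in steps of
    0.375 cm.  The final width persists once the schedule is exhausted.
    """
    if LI_on < 0:
        raise ValueError("irradiance must be non-negative")
    widths = [float(w) for w in widths]
    if any(b >= a for a, b in zip(widths, widths[1:])):
        raise ValueError("strip widths must be strictly decreasing")
    if pulse_length <= 0:
        raise ValueError("pulse_length must be positive")
    return LightField("multi_step", {"LI_on": float(LI_on), "widths": widths,
                                     "pulse_length": float(pulse_length),
                                     "length": float(length)})


def exponential_decay(LI_surface: float, space_constant: float = 0.6,
                      length: float = 2.5, axis: str = "x",
                      from_right: bool = True) -> LightField:
    """Exponential transmural attenuation from an illuminated surface.

    ``space_constant`` in mm (~0.6 for blue light in cardiac tissue); the
    illuminated surface is the right domain boundary by default.
    """
    if space_constant <= 0:
        raise ValueError("space constant must be positive")
    if LI_surface < 0:
        raise ValueError("irradiance must be non-negative")
    return LightField("exponential_decay", {
        "LI_surface": float(LI_surface), "space_constant": float(space_constant),
        "length": float(length), "axis": axis, "from_right": bool(from_right)})
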