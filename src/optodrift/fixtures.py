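"""Synthetic inputs with analytic ground truth for the analysis stages.

Everything the measurement pipeline consumes — tip trajectories, voltage
movies, quiescent profiles — can be generated here with known geometry, so
conduction-velocity, spectral, curvature and drift-fit estimators are
testable without running the tissue solver.  Fixtures are written into the
same containers as real solver output (:class:`~optodrift.recording.Recording`,
:class:`~optodrift.drift.TipTrajectory`, :class:`~optodrift.wave_metrics.ProfileSeries`)
so analysis code cannot distinguish them, and each carries its analytic
ground truth in ``truth``.  Generation is deterministic: a spec with the
same seed reproduces identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drift import TipTrajectory
from .recording import Recording
from .tissue import Grid
from .wave_metrics import ProfileSeries

__all__ = ["FixtureSpec", "make_trajectory", "make_movie",
           "make_quiescent_profile"]

_TRAJ_KINDS = {"circle_traj", "cycloid_traj", "decaying_drift_traj"}
_MOVIE_KINDS = {"plane_wave_movie", "rotating_phase_movie"}


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one synthetic fixture.

    ``kind`` selects the family; ``params`` the geometry (radii in cm,
    frequencies in Hz, speeds in cm/s, drift V0 in mm/s, tau in s, noise
    levels relative); ``dt_ms``/``duration_ms`` the sampling; ``grid`` the
    domain for movie fixtures; ``seed`` the noise stream.
    """

    kind: str
    params: dict = field(default_factory=dict)
    dt_ms: float = 1.0
    duration_ms: float = 1000.0
    grid: Grid | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in (_TRAJ_KINDS | _MOVIE_KINDS
                             | {"quiescent_profile"}):
            raise ValueError(f"unknown fixture kind: {self.kind!r}")


def _times(spec: FixtureSpec) -> np.ndarray:
    return np.arange(0.0, spec.duration_ms + spec.dt_ms / 2, spec.dt_ms)


def make_trajectory(spec: FixtureSpec):
    """Synthetic tip trajectory with analytic speed/curvature/drift truth.

    circle: (cx + R cos wt, cy + R sin wt); cycloid adds a constant-velocity
    center; decaying_drift adds a center moving at V0 exp(-t/tau) along +x.
    The ``noise`` parameter applies multiplicative Gaussian noise to the
    drift (center-motion) speed.  Returns (TipTrajectory, truth dict).
    """
    if spec.kind not in _TRAJ_KINDS:
        raise ValueError(f"not a trajectory kind: {spec.kind!r}")
    p = spec.params
    t = _times(spec)                       # ms
    R = float(p.get("radius", 0.5))        # cm
    f = float(p.get("freq_hz", 15.3))
    cx0 = float(p.get("cx", 1.25))
    cy0 = float(p.get("cy", 1.25))
    w = 2.0 * np.pi * f / 1000.0           # rad/ms
    cx = np.full_like(t, cx0)
    cy = np.full_like(t, cy0)
    truth = {"radius_cm": R, "freq_hz": f,
             "curvature_cm": (1.0 / R if R > 0 else np.nan),
             "rot_speed_mm_s": 2.0 * np.pi * R * f * 10.0}
    if spec.kind == "cycloid_traj":
        vx = float(p.get("vx_mm_s", 10.0)) / 1.0e4   # cm/ms
        vy = float(p.get("vy_mm_s", 0.0)) / 1.0e4
        cx = cx + vx * t
        cy = cy + vy * t
        truth["drift_mm_s"] = np.hypot(vx, vy) * 1.0e4
    elif spec.kind == "decaying_drift_traj":
        V0 = float(p.get("V0_mm_s", 14.0))           # mm/s
        tau = float(p.get("tau_s", 0.39))            # s
        tau_ms = tau * 1000.0
        # x_c(t) = int_0^t V0 e^(-s/tau) ds, V0 in mm/s = 1e-4 cm/ms
        cx = cx + (V0 * 1e-4) * tau_ms * (1.0 - np.exp(-t / tau_ms))
        truth["V0_mm_s"] = V0
        truth["tau_s"] = tau
        T_s = spec.duration_ms / 1000.0
        truth["displacement_cm"] = V0 * tau * (1 - np.exp(-T_s / tau)) / 10.0
    # multiplicative Gaussian noise on the drift (center-motion) speed:
    # each center increment is scaled by 1 + noise*N(0,1)
    noise = float(p.get("noise", 0.0))
    if noise > 0:
        rng = np.random.default_rng(spec.seed)
        fac = 1.0 + noise * rng.standard_normal(len(t) - 1)
        cx = cx[0] + np.concatenate([[0.0], np.cumsum(np.diff(cx) * fac)])
        cy = cy[0] + np.concatenate([[0.0], np.cumsum(np.diff(cy) * fac)])
    x = cx + R * np.cos(w * t)
    y = cy + R * np.sin(w * t)
    traj = TipTrajectory(t=t, x=x, y=y, method=f"fixture:{spec.kind}",
                         stride_ms=spec.dt_ms)
    return traj, truth


def _ap_waveform(phase: np.ndarray) -> np.ndarray:
    """Stereotyped action-potential shape on phase in [0, 1): sharp
    upstroke, brief plateau, exponential repolarization to rest."""
    v = np.full(phase.shape, -80.0)
    up = (phase >= 0) & (phase < 0.02)
    v[up] = -80.0 + 120.0 * (phase[up] / 0.02)
    plateau = (phase >= 0.02) & (phase < 0.3)
    v[plateau] = 40.0 - 110.0 * (phase[plateau] - 0.02) / 0.28
    tail = (phase >= 0.3) & (phase < 0.5)
    v[tail] = -70.0 - 10.0 * (phase[tail] - 0.3) / 0.2
    return v


def make_movie(spec: FixtureSpec):
    """Synthetic voltage movie as a :class:`Recording` (with ground truth).

    plane_wave_movie: a stereotyped AP waveform translating along +x at
    ``speed_cm_s``, repeating at ``cl_ms``; truth carries the speed.
    rotating_phase_movie: V = offset + A cos(theta - 2 pi f t) around a
    singularity at (cx, cy); truth carries the frequency and tip position.
    Probes are placed at (0.75, y_mid) and (1.75, y_mid).
    """
    if spec.kind not in _MOVIE_KINDS:
        raise ValueError(f"not a movie kind: {spec.kind!r}")
    p = spec.params
    grid = spec.grid or Grid(nx=100, ny=10)
    X, Y = grid.node_coords()
    t = _times(spec)[1:]
    frames = np.empty((len(t), grid.ny, grid.nx), dtype=np.float32)
    ymid = grid.ny * grid.dx / 2.0
    probes = {"a": (0.75, ymid), "b": (1.75, ymid)}
    truth: dict
    if spec.kind == "plane_wave_movie":
        c = float(p.get("speed_cm_s", 43.9)) / 1000.0     # cm/ms
        cl = float(p.get("cl_ms", 200.0))
        for k, tk in enumerate(t):
            phase = ((tk - X / c) % cl) / cl
            phase[X > c * tk] = 0.999               # not yet activated
            frames[k] = _ap_waveform(phase)
        truth = {"speed_cm_s": float(p.get("speed_cm_s", 43.9)),
                 "cl_ms": cl}
    else:
        f = float(p.get("freq_hz", 15.3))
        cx = float(p.get("cx", 1.0))
        cy = float(p.get("cy", 1.2))
        A = float(p.get("amplitude_mv", 40.0))
        off = float(p.get("offset_mv", -40.0))
        theta = np.arctan2(Y - cy, X - cx)
        for k, tk in enumerate(t):
            frames[k] = off + A * np.cos(theta - 2e-3 * np.pi * f * tk)
        truth = {"freq_hz": f, "tip": (cx, cy)}
    noise = float(p.get("noise_mv", 0.0))
    if noise > 0:
        rng = np.random.default_rng(spec.seed)
        frames = frames + noise * rng.standard_normal(frames.shape) \
            .astype(np.float32)
    probe_traces = {
        name: frames[:, grid.node_index(x, yy) // grid.nx,
                     grid.node_index(x, yy) % grid.nx].astype(np.float64)
        for name, (x, yy) in probes.items()}
    rec = Recording(probe_times=t, probes=probe_traces,
                    probe_positions=probes, snap_times=t, snapshots=frames,
                    meta={"fixture": spec.kind, "params": dict(p),
                          "seed": spec.seed,
                          "grid": {"nx": grid.nx, "ny": grid.ny,
                                   "dx": grid.dx, "D": grid.D}})
    return rec, truth


def make_quiescent_profile(spec: FixtureSpec):
    """Synthetic quiescent voltage profile series with analytic dV/dx truth.

    V(x, t) = baseline + amplitude(t) * S(x), S a linear ramp or a logistic
    step of scale ``scale_cm`` at ``x0``; amplitude ramps linearly from 0 to
    ``amplitude_mv``.  Truth carries peak |dV/dx| and width at 10% of peak
    for the final profile.
    """
    if spec.kind != "quiescent_profile":
        raise ValueError(f"not a profile kind: {spec.kind!r}")
    p = spec.params
    grid = spec.grid or Grid(nx=100, ny=10)
    x = (np.arange(grid.nx) + 0.5) * grid.dx
    t = _times(spec)
    base = float(p.get("baseline_mv", -82.4))
    amp = float(p.get("amplitude_mv", 5.0))
    shape = p.get("shape", "logistic")
    if shape == "logistic":
        s = float(p.get("scale_cm", 0.05))
        x0 = float(p.get("x0", grid.nx * grid.dx / 2.0))
        S = 1.0 / (1.0 + np.exp(-(x - x0) / s))
        # |dV/dx| of a logistic: peak amp/(4s); width@10% of a sech^2
        # profile: solve sech^2(u/2)/4 = 0.1 -> u = 2 acosh(sqrt(10)/... )
        # done numerically on a dense axis for an exact reference
        xd = np.linspace(x[0], x[-1], 20001)
        g = amp / s * np.exp(-(xd - x0) / s) / (1 + np.exp(-(xd - x0) / s)) ** 2
        peak = amp / (4.0 * s)
        lvl = 0.1 * peak
        above = np.where(g >= lvl)[0]
        width = float(xd[above[-1]] - xd[above[0]])
        truth = {"peak_mV_cm": peak, "width_cm": width}
    elif shape == "ramp":
        S = (x - x[0]) / (x[-1] - x[0])
        truth = {"peak_mV_cm": amp / (x[-1] - x[0]),
                 "width_cm": float(x[-1] - x[0])}
    else:
        raise ValueError(f"unknown profile shape: {shape!r}")
    ramp = t / t[-1] if t[-1] > 0 else np.ones_like(t)
    V = base + np.outer(ramp, amp * S)
    series = ProfileSeries(times=t, x=x, V=V)
    return series, truth
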