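"""Wavefront-level measurements: conduction velocity, CV restitution,
dominant frequency, and quiescent voltage-gradient profile statistics.

Conventions: activation time is the -20 mV upstroke crossing with linear
sub-sample interpolation; CV from paced trains averages the last three
captured beats.  The dominant frequency is the argmax above 1 Hz of a
mean-removed, Hann-tapered, zero-padded periodogram (the padding refines
the peak location well below the raw bin width).  Spatial derivatives use
central differences on the node grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NoActivationError", "RestitutionCurve", "SpectralResult",
           "ProfileSeries", "activation_times", "conduction_velocity",
           "cv_restitution", "dominant_frequency", "gradient_profile_stats"]

UPSTROKE_MV = -20.0


class NoActivationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RestitutionCurve:
    """(CL, CV) pairs at fixed irradiance; lost capture marked as NaN CV."""

    LI: float
    cls_ms: np.ndarray
    cv_cm_s: np.ndarray

    def __post_init__(self):
        cls_ms = np.asarray(self.cls_ms, float)
        if cls_ms.size > 1 and not np.all(np.diff(cls_ms) > 0):
            raise ValueError("cycle lengths must be strictly increasing")


@dataclass(frozen=True)
class SpectralResult:
    df_hz: float
    freqs_hz: np.ndarray
    power: np.ndarray
    window_ms: float

    @property
    def resolution_hz(self) -> float:
        """Raw Fourier bin width of the analysis window."""
        return 1000.0 / self.window_ms


@dataclass(frozen=True)
class ProfileSeries:
    """Quiescent voltage profiles V(x, t) along a fixed horizontal line."""

    times: np.ndarray        # ms
    x: np.ndarray            # cm
    V: np.ndarray            # (nt, nx) mV

    def __post_init__(self):
        if self.V.shape != (len(self.times), len(self.x)):
            raise ValueError("profile array shape mismatch")

    def dVdx(self) -> np.ndarray:
        """Central-difference spatial derivative, mV/cm, shape (nt, nx)."""
        return np.gradient(self.V, self.x, axis=1)


def activation_times(t: np.ndarray, v: np.ndarray,
                     threshold: float = UPSTROKE_MV) -> np.ndarray:
    """Upstroke crossing times with linear interpolation between samples."""
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    idx = np.where((v[:-1] < threshold) & (v[1:] >= threshold))[0]
    if idx.size == 0:
        return np.empty(0)
    return t[idx] + (threshold - v[idx]) * (t[idx + 1] - t[idx]) \
        / (v[idx + 1] - v[idx])


def conduction_velocity(recording, probe_a: str, probe_b: str,
                        threshold: float = UPSTROKE_MV,
                        n_beats: int = 3) -> float:
    """Plane-wave speed (cm/s) from activation-time differences.

    ``probe_a``/``probe_b`` name probes of the recording whose positions are
    at least 0.5 cm apart along the propagation direction; the estimate
    averages the last ``n_beats`` beats seen by both probes.
    """
    pa = np.asarray(recording.probe_positions[probe_a], float)
    pb = np.asarray(recording.probe_positions[probe_b], float)
    dist = float(np.hypot(*(pb - pa)))
    if dist < 0.5:
        raise ValueError(f"probes are {dist:.2f} cm apart; need >= 0.5 cm")
    ta = activation_times(recording.probe_times, recording.probe(probe_a),
                          threshold)
    tb = activation_times(recording.probe_times, recording.probe(probe_b),
                          threshold)
    if ta.size == 0 or tb.size == 0:
        raise NoActivationError(
            f"no upstroke at probe {'ab'[ta.size > 0]}: "
            "wavefront never crossed it")
    k = min(len(ta), len(tb), n_beats)
    dt_ms = tb[-k:] - ta[-k:]
    if np.any(dt_ms <= 0):
        raise NoActivationError("activation order inconsistent with probes")
    return float(np.mean(dist / dt_ms) * 1000.0)


def cv_restitution(LI: float, cls_ms, params=None, grid=None,
                   dt: float = 0.0025, n_beats: int = 4,
                   amplitude: float = 60.0) -> RestitutionCurve:
    """CV at each pacing cycle length on the 100x10 strip under uniform LI.

    Cycle lengths without 1:1 capture at the distal probe are reported as
    NaN rather than extrapolated.
    """
    from .ionic import IonicParams
    from .lightfield import dark, uniform
    from .tissue import Grid, StimulusProtocol, TissueSim

    params = params or IonicParams()
    grid = grid or Grid(nx=100, ny=10)
    light = uniform(LI) if LI > 0 else dark()
    cls_ms = np.asarray(sorted(cls_ms), float)
    cvs = np.full(cls_ms.shape, np.nan)
    ymid = grid.ny * grid.dx / 2.0
    for i, cl in enumerate(cls_ms):
        sim = TissueSim(grid, params, dt=dt)
        sim.init_resting()
        stim = StimulusProtocol(amplitude=amplitude, pulse_ms=2.0, cl=cl,
                                n_pulses=n_beats, columns=2)
        rec = sim.run(n_beats * cl, light=light, stim=stim,
                      probes={"a": (0.75, ymid), "b": (1.75, ymid)},
                      probe_dt=0.1)
        ta = activation_times(rec.probe_times, rec.probe("a"))
        tb = activation_times(rec.probe_times, rec.probe("b"))
        if len(ta) == n_beats and len(tb) == n_beats:
            cvs[i] = conduction_velocity(rec, "a", "b")
    return RestitutionCurve(LI=LI, cls_ms=cls_ms, cv_cm_s=cvs)


def dominant_frequency(t_ms: np.ndarray, v: np.ndarray,
                       window_ms: float | None = None,
                       fmin_hz: float = 1.0, pad: int = 8,
                       min_cycles: float = 5.0,
                       expected_hz: float | None = None) -> SpectralResult:
    """Dominant frequency of a uniformly sampled voltage timeseries.

    Uses the trailing ``window_ms`` of the trace (whole trace by default).
    Raises if the window holds fewer than ``min_cycles`` periods of
    ``expected_hz`` (when given).
    """
    t_ms = np.asarray(t_ms, float)
    v = np.asarray(v, float)
    dt = np.diff(t_ms)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("timeseries must be uniformly sampled")
    if window_ms is not None:
        n_keep = int(round(window_ms / dt[0]))
        v = v[-n_keep:]
    window_ms = len(v) * dt[0]
    if expected_hz is not None and window_ms < min_cycles * 1000.0 / expected_hz:
        raise ValueError(
            f"window of {window_ms:.0f} ms covers fewer than {min_cycles} "
            f"cycles at {expected_hz} Hz; frequency resolution insufficient")
    fs = 1000.0 / dt[0]
    x = (v - v.mean()) * np.hanning(len(v))
    nfft = int(2 ** np.ceil(np.log2(len(x) * pad)))
    spec = np.abs(np.fft.rfft(x, nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    sel = freqs >= fmin_hz
    df = float(freqs[sel][np.argmax(spec[sel])])
    return SpectralResult(df_hz=df, freqs_hz=freqs, power=spec,
                          window_ms=float(window_ms))


def _width_at_fraction(x: np.ndarray, f: np.ndarray, frac: float) -> float:
    """Distance between the outermost linear-interpolated crossings of
    frac * max(f)."""
    level = frac * f.max()
    above = f >= level
    idx = np.where(above)[0]
    i0, i1 = idx[0], idx[-1]
    xl = x[i0] if i0 == 0 else np.interp(
        level, [f[i0 - 1], f[i0]], [x[i0 - 1], x[i0]])
    xr = x[i1] if i1 == len(x) - 1 else np.interp(
        level, [f[i1 + 1], f[i1]], [x[i1 + 1], x[i1]])
    return float(xr - xl)


def gradient_profile_stats(profiles: ProfileSeries, frac: float = 0.1,
                           flat_tol: float = 1e-9):
    """Per-time peak |dV/dx| (mV/cm) and its width at 10% of peak (cm).

    Flat profiles give peak 0 and undefined (NaN) width.  Returns a pandas
    DataFrame with columns t_ms, peak_mV_cm, width_cm, x_peak_cm.
    """
    import pandas as pd

    if len(profiles.times) == 0:
        raise ValueError("need at least one profile")
    g = np.abs(profiles.dVdx())
    rows = []
    for k, t in enumerate(profiles.times):
        f = g[k]
        peak = float(f.max())
        if peak < flat_tol:
            rows.append((t, 0.0, np.nan, np.nan))
            continue
        xp = float(profiles.x[np.argmax(f)])
        rows.append((t, peak, _width_at_fraction(profiles.x, f, frac), xp))
    return pd.DataFrame(rows, columns=["t_ms", "peak_mV_cm", "width_cm",
                                       "x_peak_cm"])
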