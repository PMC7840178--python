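"""2D monodomain tissue solver with no-flux boundaries.

The membrane voltage obeys  dV/dt = D * lap(V) - (Iion + IChR2 - Istim)/Cm
on a regular grid of node-centered cells (default spacing 0.025 cm,
isotropic diffusion D = 0.0014 cm^2/ms, calibrated so a paced plane wave
travels at the reference 43.9 cm/s), stepped with operator splitting:
explicit 5-point diffusion on V, then the local reaction update of
:mod:`optodrift.kernels`.  Light patterns are evaluated at node centers and
are piecewise constant in time, so photocycle drive rates are recomputed
only at pattern breakpoints.

A spiral wave is initialized by partitioning the square domain into four
quadrants seeded with cell states sampled from four phases of a paced
action potential (clockwise from top-left: resting, depolarized, early
repolarization, late repolarization); the depolarized quarter then curls
into the recovering quarter and closes a rotation circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cell, kernels
from .cell import AP_DETECT_MV, IntegrationError
from .ionic import IonicParams, N_STATE, I_V
from .lightfield import LightField, dark
from .recording import Recording
from .tables import build_tables, pack_params, light_rate_arrays

__all__ = ["Grid", "StimulusProtocol", "QuadrantInit", "TissueSim",
           "laplacian_noflux", "quiescent_profile_run",
           "SubThresholdViolationError", "DEFAULT_PROBE"]

DEFAULT_PROBE = (0.75, 0.75)  # cm


class SubThresholdViolationError(RuntimeError):
    """An illumination pattern meant to be sub-threshold fired a wave."""


@dataclass(frozen=True)
class Grid:
    """Regular 2D grid; nx columns (x) by ny rows (y), spacing dx in cm."""

    nx: int = 100
    ny: int = 100
    dx: float = 0.025        # cm
    D: float = 0.00157       # cm^2/ms (calibrated to the 43.9 cm/s plane-wave CV)

    def __post_init__(self):
        if self.nx < 3 or self.ny < 3:
            raise ValueError("grid needs at least 3 nodes per dimension")
        if self.dx <= 0 or self.D <= 0:
            raise ValueError("dx and D must be positive")

    @property
    def n(self) -> int:
        return self.nx * self.ny

    @property
    def extent(self) -> tuple[float, float]:
        return (self.nx * self.dx, self.ny * self.dx)

    def node_coords(self):
        """Node-center coordinates (X, Y), each (ny, nx), in cm."""
        x = (np.arange(self.nx) + 0.5) * self.dx
        y = (np.arange(self.ny) + 0.5) * self.dx
        return np.meshgrid(x, y)

    def node_index(self, x: float, y: float) -> int:
        ix = int(np.clip(round(x / self.dx - 0.5), 0, self.nx - 1))
        iy = int(np.clip(round(y / self.dx - 0.5), 0, self.ny - 1))
        return iy * self.nx + ix

    def max_stable_dt(self) -> float:
        """Explicit diffusion bound D*dt/dx^2 <= 0.25."""
        return 0.25 * self.dx ** 2 / self.D


@dataclass(frozen=True)
class StimulusProtocol:
    """Pulse-train stimulus delivered to an electrode region.

    ``columns`` selects the leftmost columns as the electrode (paced-strip
    default); an explicit boolean ``mask`` overrides it.
    """

    amplitude: float = 60.0      # pA/pF during the pulse
    pulse_ms: float = 2.0
    cl: float = 200.0            # cycle length, ms
    n_pulses: int = 3
    columns: int = 2
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.cl <= self.pulse_ms:
            raise ValueError("cycle length must exceed pulse duration")

    def amp_field(self, grid: Grid) -> np.ndarray:
        amp = np.zeros(grid.n)
        if self.mask is not None:
            if self.mask.shape != (grid.ny, grid.nx):
                raise ValueError("stimulus mask shape mismatch")
            amp[self.mask.ravel()] = self.amplitude
        else:
            m = np.zeros((grid.ny, grid.nx), dtype=bool)
            m[:, :self.columns] = True
            amp[m.ravel()] = self.amplitude
        return amp


@dataclass(frozen=True)
class QuadrantInit:
    """Four-quadrant spiral initial condition.

    ``templates`` maps phase names (rest/depolarized/early_repol/late_repol)
    to full cell-state vectors sampled from one paced action potential;
    ``offset`` (cm) shifts the quadrant intersection off-center, the
    mechanism used to generate independent initial conditions.
    """

    templates: dict
    offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        missing = {"rest", "depolarized", "early_repol", "late_repol"} \
            - set(self.templates)
        if missing:
            raise ValueError(f"missing quadrant templates: {sorted(missing)}")
        for name, y in self.templates.items():
            if np.asarray(y).shape != (N_STATE,):
                raise ValueError(f"template {name!r} is not a cell state")


def laplacian_noflux(f: np.ndarray, grid: Grid) -> np.ndarray:
    """5-point Laplacian with mirrored ghost nodes (units of f per cm^2).

    Nodes are cell-centered, so the no-flux boundary lies half a spacing
    outside the edge node and the ghost mirrors across that face
    (ghost(-1) = f(0)).  This is the conservative form: with reaction off,
    the diffusion update preserves the field total to round-off.  Zero on
    constant fields everywhere including boundaries; the reference
    implementation against which the compiled kernel's diffusion is tested.
    """
    if f.shape != (grid.ny, grid.nx):
        raise ValueError(f"field shape {f.shape} does not match grid "
                         f"({grid.ny}, {grid.nx})")
    g = np.pad(f, 1, mode="edge")
    lap = (g[:-2, 1:-1] + g[2:, 1:-1] + g[1:-1, :-2] + g[1:-1, 2:]
           - 4.0 * f)
    return lap / grid.dx ** 2


class TissueSim:
    """Stateful monodomain simulation on a grid.

    Initialize with :meth:`init_resting` or :meth:`init_spiral`, then call
    :meth:`run` (repeatedly; state persists and the light/stimulus clocks
    restart at each call).  Runs are deterministic: identical configuration
    reproduces bit-identical output.
    """

    def __init__(self, grid: Grid, params: IonicParams | None = None,
                 dt: float = 0.005):
        self.grid = grid
        self.params = params or IonicParams()
        if dt <= 0:
            raise ValueError("dt must be positive")
        cap = grid.max_stable_dt()
        if dt > cap:
            import warnings
            warnings.warn(f"dt = {dt} ms above diffusion stability bound "
                          f"{cap:.4g} ms; capping", stacklevel=2)
            dt = cap
        self.dt = dt
        self.t = 0.0
        self._tab = build_tables(self.params, dt)
        self._prm = pack_params(self.params)
        n = grid.n
        self.y = np.empty((n, N_STATE))
        self._aux = tuple(np.empty(n) for _ in range(5))
        self._r_diff = grid.D * dt / grid.dx ** 2

    # ------------------------------------------------------------------
    # initial conditions
    # ------------------------------------------------------------------
    def init_resting(self, LI: float = 0.0) -> None:
        rest = cell.find_resting_state(self.params, LI)
        self.y[:] = rest[None, :]
        self.t = 0.0

    def init_from_template(self, state: np.ndarray) -> None:
        self.y[:] = np.asarray(state)[None, :]
        self.t = 0.0

    def init_spiral(self, init: QuadrantInit) -> None:
        """Four-quadrant initial condition (clockwise from top-left:
        rest, depolarized, early repolarization, late repolarization)."""
        g = self.grid
        X, Y = g.node_coords()
        lx, ly = g.extent
        cx = lx / 2.0 + init.offset[0]
        cy = ly / 2.0 + init.offset[1]
        left = (X < cx).ravel()
        top = (Y >= cy).ravel()
        t = init.templates
        self.y[left & top] = t["rest"]
        self.y[~left & top] = t["depolarized"]
        self.y[~left & ~top] = t["early_repol"]
        self.y[left & ~top] = t["late_repol"]
        self.t = 0.0

    @property
    def V(self) -> np.ndarray:
        return self.y[:, I_V].reshape(self.grid.ny, self.grid.nx)

    # ------------------------------------------------------------------
    # stepping
    # ------------------------------------------------------------------
    def run(self, duration: float, light: LightField | None = None,
            stim: StimulusProtocol | None = None,
            probes: dict | None = None, probe_dt: float = 1.0,
            snapshot_dt: float | None = None,
            meta: dict | None = None) -> Recording:
        """Advance ``duration`` ms and return a :class:`Recording`.

        ``probes`` maps names to (x, y) positions in cm; voltage there is
        sampled every ``probe_dt`` ms, full-field snapshots every
        ``snapshot_dt`` ms if given.  The light and stimulus clocks start
        at zero at the beginning of this call.
        """
        g = self.grid
        light = light or dark()
        dt = self.dt
        n_steps = int(round(duration / dt))
        probe_stride = max(int(round(probe_dt / dt)), 1)
        if probes is None:
            probes = {"probe": DEFAULT_PROBE}
        probe_idx = np.array([g.node_index(x, yy)
                              for x, yy in probes.values()], dtype=np.int64)
        n_probe_samples = n_steps // probe_stride
        probe_out = np.empty((len(probes), n_probe_samples))

        if snapshot_dt is not None:
            snap_stride = max(int(round(snapshot_dt / dt)), 1)
            if n_steps % snap_stride != 0:
                raise ValueError("snapshot stride must divide the step count")
            snap_out = np.empty((n_steps // snap_stride, g.n),
                                dtype=np.float32)
        else:
            snap_stride = 0
            snap_out = np.empty((0, g.n), dtype=np.float32)

        if stim is not None:
            stim_amp = stim.amp_field(g)
            stim_cl, stim_dur, stim_np = stim.cl, stim.pulse_ms, stim.n_pulses
        else:
            stim_amp = np.zeros(g.n)
            stim_cl, stim_dur, stim_np = 1.0, 0.0, 0

        # chunk at light-pattern breakpoints
        bps = [0.0] + light.time_breakpoints(duration) + [duration]
        edges = np.unique(np.round(np.array(bps) / dt).astype(np.int64))
        X, Y = g.node_coords()

        filled_p = 0
        filled_s = 0
        for s0, s1 in zip(edges[:-1], edges[1:]):
            li_grid = light.sample(X, Y, t=(s0 + 0.5) * dt)
            rates = light_rate_arrays(li_grid, self.params.chr2)
            np_, ns_, status = kernels.advance(
                self.y, g.nx, g.ny, int(s1 - s0), int(s0), dt, self._r_diff,
                self._tab, self._prm, rates, stim_amp,
                stim_cl, stim_dur, stim_np, self._aux,
                probe_idx, probe_stride, probe_out[:, filled_p:],
                snap_stride, snap_out[filled_s:])
            filled_p += np_
            filled_s += ns_
            if status != 0:
                raise IntegrationError(
                    f"non-finite voltage at t = {self.t + s1 * dt:.2f} ms")

        t_offset = self.t
        self.t += n_steps * dt
        probe_times = (np.arange(1, filled_p + 1) * probe_stride) * dt
        rec = Recording(
            probe_times=probe_times,
            probes={name: probe_out[k, :filled_p].copy()
                    for k, name in enumerate(probes)},
            probe_positions=dict(probes),
            snap_times=((np.arange(1, filled_s + 1) * snap_stride) * dt
                        if snap_stride else None),
            snapshots=(snap_out[:filled_s].reshape(filled_s, g.ny, g.nx)
                       if snap_stride else None),
            meta={
                "grid": {"nx": g.nx, "ny": g.ny, "dx": g.dx, "D": g.D},
                "dt": dt, "duration": duration, "t_offset": t_offset,
                "light": light.to_dict(),
                "stim": (None if stim is None else {
                    "amplitude": stim.amplitude, "pulse_ms": stim.pulse_ms,
                    "cl": stim.cl, "n_pulses": stim.n_pulses}),
                "ionic_variant": self.params.variant,
                "g_chr2": self.params.chr2.g_chr2,
                **(meta or {}),
            })
        return rec

    def step(self, light: LightField | None = None,
             stim_amp: np.ndarray | None = None) -> None:
        """Single operator-split step (diffusion then reaction)."""
        g = self.grid
        light = light or dark()
        li = light.on_grid(g, self.t)
        rates = light_rate_arrays(li, self.params.chr2)
        amp = np.zeros(g.n) if stim_amp is None else stim_amp.ravel()
        npulses = 1 if stim_amp is not None else 0
        _, _, status = kernels.advance(
            self.y, g.nx, g.ny, 1, 0, self.dt, self._r_diff,
            self._tab, self._prm, rates, amp, 1e9, 1e9, npulses,
            self._aux, np.zeros(0, dtype=np.int64), 0,
            np.empty((0, 0)), 0, np.empty((0, g.n), dtype=np.float32))
        if status != 0:
            raise IntegrationError(f"non-finite voltage at t = {self.t:.2f} ms")
        self.t += self.dt


def quiescent_profile_run(light: LightField, grid: Grid,
                          duration: float = 2000.0,
                          params: IonicParams | None = None,
                          y_line: float = 0.75, sample_dt: float = 50.0,
                          dt: float = 0.02):
    """Voltage profile V(x, t) along a horizontal line in a quiescent domain.

    No stimulus is applied; the light pattern alone shapes the resting
    voltage distribution.  Raises :class:`SubThresholdViolationError` if the
    pattern fires an action potential anywhere.  Returns a
    :class:`~optodrift.wave_metrics.ProfileSeries`.
    """
    from .wave_metrics import ProfileSeries

    sim = TissueSim(grid, params, dt=dt)
    sim.init_resting(LI=0.0)
    # watch probes along the line at 1 ms so even a brief rogue action
    # potential between snapshot instants is caught
    lx = grid.nx * grid.dx
    watch = {f"w{k}": (x, y_line)
             for k, x in enumerate(np.linspace(0.1, 0.9, 5) * lx)}
    rec = sim.run(duration, light=light, probes=watch, probe_dt=1.0,
                  snapshot_dt=sample_dt)
    vmax = max(float(rec.snapshots.max()),
               max(float(v.max()) for v in rec.probes.values()))
    if vmax > AP_DETECT_MV:
        raise SubThresholdViolationError(
            f"light pattern fired an action potential "
            f"(V reached {vmax:.1f} mV)")
    iy = int(np.clip(round(y_line / grid.dx - 0.5), 0, grid.ny - 1))
    x = (np.arange(grid.nx) + 0.5) * grid.dx
    profiles = rec.snapshots[:, iy, :].astype(np.float64)
    return ProfileSeries(times=rec.snap_times, x=x, V=profiles)
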