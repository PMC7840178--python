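"""Config-driven reproductions of the in-silico illumination experiments.

Each experiment reproduces one family of in-silico illumination protocols:

* ``fig1_cv_restitution`` — CV vs pacing cycle length on the paced strip at
  several uniform irradiances.
* ``fig1_df_vs_li`` — spiral dominant frequency under uniform global light.
* ``fig1_core_diameter`` — core diameter of the spiral vs irradiance.
* ``fig2_gradient_drift`` — drift and termination under linear gradients.
* ``fig3_step_drift`` — half-domain illumination: exponential drift decay
  (V0, tau) and maximal displacement per irradiance.
* ``fig4_multistep`` — shrinking multi-step illumination: termination time
  vs pulse length and the MSD comparison against the gradient protocol.
* ``quiescent_profiles`` — quiescent V(x, t) and |dV/dx| statistics for any
  pattern.

Two scale presets exist: ``desk`` (shortened durations, a single initial
condition) and ``paper`` (2 s protocols, the N = 10 seeded initial-condition
ensemble).  Every report records its preset, problem sizes and seeds; runs
are deterministic given the plan.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cell, drift
from .ionic import IonicParams
from .lightfield import (LightField, dark, uniform, linear_gradient,
                         single_step, multi_step, gradient_magnitude)
from .recording import Recording
from .tissue import Grid, QuadrantInit, StimulusProtocol, TissueSim
from .wave_metrics import (conduction_velocity, cv_restitution,
                           dominant_frequency, gradient_profile_stats)

__all__ = ["ExperimentPlan", "plan_and_run", "compare_to_targets",
           "EXPERIMENTS", "spiral_offsets", "run_spiral", "strip_cv",
           "spiral_recording_df", "DEFAULT_DT"]

DEFAULT_DT = 0.0025        # ms
TRANSIENT_MS = 200.0       # settled-spiral convention

EXPERIMENT_IDS = ("fig1_cv_restitution", "fig1_df_vs_li",
                  "fig1_core_diameter", "fig2_gradient_drift",
                  "fig3_step_drift", "fig4_multistep", "quiescent_profiles")


@dataclass(frozen=True)
class ExperimentPlan:
    experiment: str
    scale: str = "desk"                  # "desk" | "paper"
    li_levels: tuple = ()
    seed: int = 0
    n_seeds: int | None = None           # default: 1 desk, 10 paper
    outdir: str | None = None
    dt: float = DEFAULT_DT
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.experiment not in EXPERIMENT_IDS:
            raise ValueError(f"unknown experiment: {self.experiment!r}; "
                             f"choose one of {EXPERIMENT_IDS}")
        if self.scale not in ("desk", "paper"):
            raise ValueError("scale must be 'desk' or 'paper'")

    @property
    def seeds(self) -> int:
        if self.n_seeds is not None:
            return self.n_seeds
        return 10 if self.scale == "paper" else 1


# ---------------------------------------------------------------------------
# shared protocol building blocks
# ---------------------------------------------------------------------------

def spiral_offsets(n: int, seed: int, max_offset: float = 0.2) -> np.ndarray:
    """Deterministic quadrant-intersection offsets (cm) for the seeded
    initial-condition ensemble; the first entry is always centered."""
    rng = np.random.default_rng(seed)
    offs = rng.uniform(-max_offset, max_offset, size=(n, 2))
    offs[0] = (0.0, 0.0)
    return offs


def strip_cv(params: IonicParams, LI: float = 0.0, D: float | None = None,
             dt: float = DEFAULT_DT, n_beats: int = 4,
             cl: float = 200.0) -> float:
    """Plane-wave CV (cm/s) on the 100x10 paced strip under uniform LI."""
    grid = Grid(nx=100, ny=10, **({"D": D} if D else {}))
    sim = TissueSim(grid, params, dt=dt)
    sim.init_resting()
    stim = StimulusProtocol(amplitude=60.0, pulse_ms=2.0, cl=cl,
                            n_pulses=n_beats, columns=2)
    rec = sim.run(n_beats * cl, light=(uniform(LI) if LI > 0 else dark()),
                  stim=stim, probes={"a": (0.75, 0.125), "b": (1.75, 0.125)},
                  probe_dt=0.1)
    return conduction_velocity(rec, "a", "b")


def run_spiral(params: IonicParams, light: LightField, duration: float,
               offset=(0.0, 0.0), dt: float = DEFAULT_DT,
               settle_ms: float = TRANSIENT_MS,
               snapshot_dt: float | None = 2.0,
               grid: Grid | None = None) -> Recording:
    """Four-quadrant spiral, settled ``settle_ms`` in the dark, then run
    ``duration`` ms under ``light`` with probe and snapshot recording."""
    grid = grid or Grid(nx=100, ny=100)
    tpl = cell.default_templates(params)
    sim = TissueSim(grid, params, dt=dt)
    sim.init_spiral(QuadrantInit(templates=tpl, offset=tuple(offset)))
    if settle_ms > 0:
        sim.run(settle_ms, probes={}, probe_dt=settle_ms)
    rec = sim.run(duration, light=light, probes={"p": (0.75, 0.75)},
                  probe_dt=1.0, snapshot_dt=snapshot_dt,
                  meta={"offset_cm": list(offset), "settle_ms": settle_ms})
    return rec


def spiral_recording_df(rec: Recording, skip_ms: float = 100.0):
    """Dominant frequency of a spiral recording's probe trace."""
    t = rec.probe_times
    sel = t >= skip_ms
    return dominant_frequency(t[sel], rec.probe("p")[sel])


def _grid_of(rec: Recording) -> Grid:
    g = rec.meta["grid"]
    return Grid(nx=g["nx"], ny=g["ny"], dx=g["dx"], D=g["D"])


def _core_analysis(rec: Recording, fallback_period_ms: float = 65.0):
    """Tip trajectory, rotation period and core series of a recording."""
    grid = _grid_of(rec)
    traj = drift.track_tips(rec.snapshots, rec.snap_times, grid)
    try:
        period = 1000.0 / spiral_recording_df(rec).df_hz
    except ValueError:
        period = fallback_period_ms
    core = drift.core_series(traj, rotation_period=period,
                             snapshots=rec.snapshots,
                             snap_times=rec.snap_times)
    return traj, period, core


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def _exp_cv_restitution(plan: ExperimentPlan, params: IonicParams):
    lis = plan.li_levels or (0.0, 0.01, 0.02)
    cls_ms = plan.overrides.get(
        "cls_ms", (100.0, 150.0, 200.0, 250.0, 300.0) if plan.scale == "paper"
        else (150.0, 200.0, 300.0))
    rows = []
    for li in lis:
        curve = cv_restitution(li, cls_ms, params=params, dt=plan.dt)
        for cl, cv in zip(curve.cls_ms, curve.cv_cm_s):
            rows.append({"LI": li, "CL_ms": cl, "CV_cm_s": cv})
    summary = {"cv_5hz": {str(li): next(
        (r["CV_cm_s"] for r in rows
         if r["LI"] == li and r["CL_ms"] == 200.0), None) for li in lis}}
    return rows, summary


def _exp_df_vs_li(plan: ExperimentPlan, params: IonicParams):
    lis = plan.li_levels or (0.0, 0.01, 0.02)
    duration = plan.overrides.get(
        "duration", 1500.0 if plan.scale == "paper" else 800.0)
    rows = []
    for li in lis:
        rec = run_spiral(params, uniform(li) if li > 0 else dark(),
                         duration, dt=plan.dt, snapshot_dt=None)
        sp = spiral_recording_df(rec)
        rows.append({"LI": li, "DF_hz": sp.df_hz,
                     "window_ms": sp.window_ms})
    df0 = rows[0]["DF_hz"]
    summary = {"df_dark": df0,
               "df_reduction_pct": {str(r["LI"]):
                                    100.0 * (df0 - r["DF_hz"]) / df0
                                    for r in rows[1:]}}
    return rows, summary


def _exp_core_diameter(plan: ExperimentPlan, params: IonicParams):
    lis = plan.li_levels or (0.0, 0.01, 0.02)
    duration = plan.overrides.get(
        "duration", 1500.0 if plan.scale == "paper" else 800.0)
    rows = []
    for li in lis:
        rec = run_spiral(params, uniform(li) if li > 0 else dark(),
                         duration, dt=plan.dt)
        _, period, core = _core_analysis(rec)
        # stationary-state core: median over the last half of rotations
        half = len(core.d_core) // 2
        rows.append({"LI": li, "d_core_cm": float(np.median(
            core.d_core[half:])), "period_ms": period})
    return rows, {"d_core_cm": {str(r["LI"]): r["d_core_cm"] for r in rows}}


def _exp_gradient_drift(plan: ExperimentPlan, params: IonicParams):
    lis = plan.li_levels or (0.005, 0.01, 0.02)
    duration = plan.overrides.get(
        "duration", 2000.0 if plan.scale == "paper" else 1200.0)
    offsets = spiral_offsets(plan.seeds, plan.seed)
    rows = []
    for li in lis:
        light = linear_gradient(0.0, li)
        for k, off in enumerate(offsets):
            rec = run_spiral(params, light, duration, offset=off, dt=plan.dt)
            traj, period, core = _core_analysis(rec)
            rows.append({
                "LI_right": li,
                "grad_mW_mm3": gradient_magnitude(light),
                "seed_index": k,
                "displacement_cm": core.displacement_cm(),
                "terminated": core.termination_ms is not None,
                "termination_ms": core.termination_ms,
                "mean_drift_x_mm_s": float(np.mean(np.diff(core.cx))
                                           / (period / 1000.0) * 10.0)
                if len(core.cx) > 1 else np.nan,
            })
    import pandas as pd

    frame = pd.DataFrame(rows)
    agg = frame.groupby("grad_mW_mm3")["displacement_cm"] \
        .agg(["mean", "std"]).reset_index()
    summary = {
        "displacement_mean_cm": dict(zip(agg["grad_mW_mm3"].astype(str),
                                         agg["mean"])),
        "terminated_by_li": {str(li): bool(
            frame[frame.LI_right == li]["terminated"].any()) for li in lis},
    }
    return rows, summary


def _exp_step_drift(plan: ExperimentPlan, params: IonicParams):
    lis = plan.li_levels or (0.001, 0.005, 0.01, 0.015)
    duration = plan.overrides.get(
        "duration", 2000.0 if plan.scale == "paper" else 1200.0)
    offsets = spiral_offsets(plan.seeds, plan.seed)
    boundary = plan.overrides.get("boundary", 1.25)
    rows = []
    for li in lis:
        light = single_step(li, boundary)
        for k, off in enumerate(offsets):
            rec = run_spiral(params, light, duration, offset=off, dt=plan.dt)
            traj, period, core = _core_analysis(rec)
            try:
                fit = drift.fit_drift_decay(core)
            except ValueError:
                fit = None
            rows.append({
                "LI": li, "seed_index": k,
                "V0_mm_s": fit.V0_mm_s if fit else np.nan,
                "tau_s": fit.tau_s if fit else np.nan,
                "fit_ok": bool(fit.ok) if fit else False,
                "displacement_cm": core.displacement_cm(),
                "calculated_d_cm": (drift.integrated_displacement(
                    fit, duration / 1000.0) if fit and fit.ok else np.nan),
            })
    import pandas as pd

    frame = pd.DataFrame(rows)
    agg = frame.groupby("LI").agg(
        V0=("V0_mm_s", "mean"), tau=("tau_s", "mean"),
        d=("displacement_cm", "mean")).reset_index()
    summary = {str(r.LI): {"V0_mm_s": r.V0, "tau_s": r.tau,
                           "displacement_cm": r.d}
               for r in agg.itertuples()}
    return rows, summary


def _exp_multistep(plan: ExperimentPlan, params: IonicParams):
    lis = plan.li_levels or (0.01, 0.02)
    pls = plan.overrides.get(
        "pulse_lengths", (250.0, 500.0, 1000.0) if plan.scale == "paper"
        else (500.0,))
    offsets = spiral_offsets(plan.seeds, plan.seed)
    rows = []
    msd_curves = {}
    for li in lis:
        for pl in pls:
            light = multi_step(li, pulse_length=pl)
            duration = plan.overrides.get("duration", max(2000.0, 4 * pl))
            cores = []
            for k, off in enumerate(offsets):
                rec = run_spiral(params, light, duration, offset=off,
                                 dt=plan.dt)
                traj, period, core = _core_analysis(rec)
                cores.append(core)
                rows.append({
                    "LI": li, "PL_ms": pl, "seed_index": k,
                    "displacement_cm": core.displacement_cm(),
                    "terminated": core.termination_ms is not None,
                    "termination_ms": core.termination_ms,
                })
            ts, m = drift.average_msd(cores)
            msd_curves[f"LI{li}_PL{pl}"] = {"t_ms": ts.tolist(),
                                            "msd_cm2": m.tolist()}
    import pandas as pd

    frame = pd.DataFrame(rows)
    summary = {
        "termination_ms": {
            f"LI{li}_PL{pl}": (lambda s: float(s.mean()) if len(s) else None)(
                frame.query("LI == @li and PL_ms == @pl and terminated")
                ["termination_ms"].dropna())
            for li in lis for pl in pls},
        "msd": msd_curves,
    }
    return rows, summary


def _exp_quiescent_profiles(plan: ExperimentPlan, params: IonicParams):
    from .tissue import quiescent_profile_run

    duration = plan.overrides.get(
        "duration", 2000.0 if plan.scale == "paper" else 1000.0)
    grid = Grid(nx=100, ny=plan.overrides.get("ny", 100))
    patterns = plan.overrides.get("patterns") or {
        "gradient_0.01": linear_gradient(0.0, 0.01),
        "step_0.01": single_step(0.01, 1.25),
    }
    rows = []
    for name, light in patterns.items():
        if isinstance(light, dict):
            light = LightField.from_dict(light)
        prof = quiescent_profile_run(light, grid, duration, params,
                                     sample_dt=plan.overrides.get(
                                         "sample_dt", 100.0))
        stats = gradient_profile_stats(prof)
        for r in stats.itertuples():
            rows.append({"pattern": name, "t_ms": r.t_ms,
                         "peak_mV_cm": r.peak_mV_cm,
                         "width_cm": r.width_cm})
    import pandas as pd

    frame = pd.DataFrame(rows)
    summary = {name: {
        "final_peak_mV_cm": float(
            frame[frame.pattern == name]["peak_mV_cm"].iloc[-1])}
        for name in frame["pattern"].unique()}
    return rows, summary


EXPERIMENTS = {
    "fig1_cv_restitution": _exp_cv_restitution,
    "fig1_df_vs_li": _exp_df_vs_li,
    "fig1_core_diameter": _exp_core_diameter,
    "fig2_gradient_drift": _exp_gradient_drift,
    "fig3_step_drift": _exp_step_drift,
    "fig4_multistep": _exp_multistep,
    "quiescent_profiles": _exp_quiescent_profiles,
}


def plan_and_run(plan: ExperimentPlan,
                 params: IonicParams | None = None) -> dict:
    """Run one experiment plan; returns {rows, summary, provenance} and, if
    ``plan.outdir`` is set, writes rows as CSV plus a JSON summary."""
    params = params or IonicParams()
    t0 = time.time()
    rows, summary = EXPERIMENTS[plan.experiment](plan, params)
    report = {
        "experiment": plan.experiment,
        "rows": rows,
        "summary": summary,
        "provenance": {
            "scale": plan.scale, "dt": plan.dt, "seed": plan.seed,
            "n_seeds": plan.seeds,
            "ionic_variant": params.variant,
            "na_recovery_scale": params.na_recovery_scale,
            "g_chr2": params.chr2.g_chr2,
            "elapsed_s": round(time.time() - t0, 1),
        },
    }
    if plan.outdir:
        import pandas as pd

        out = Path(plan.outdir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(out / f"{plan.experiment}.csv", index=False)
        with open(out / f"{plan.experiment}.json", "w") as fh:
            json.dump({k: report[k] for k in ("experiment", "summary",
                                              "provenance")}, fh, indent=2,
                      default=str)
    return report


def compare_to_targets(report_metrics: dict, targets: list[dict]):
    """Evaluate measured metrics against machine-readable targets.

    Each target is {id, metric, value, cmp, rel_tol}; ``metric`` keys into
    ``report_metrics``.  Missing metrics are reported as 'untested', never
    as passes.  Returns (DataFrame, all_passed).
    """
    import pandas as pd

    rows = []
    for t in targets:
        got = report_metrics.get(t["metric"])
        if got is None or (isinstance(got, float) and np.isnan(got)):
            rows.append({**{k: t[k] for k in ("id", "metric", "value")},
                         "measured": None, "status": "untested",
                         "deviation_pct": None})
            continue
        ref = t["value"]
        dev = 100.0 * (got - ref) / ref if ref != 0 else np.inf * np.sign(got)
        cmp_ = t.get("cmp", "eq")
        tol = 100.0 * t.get("rel_tol", 0.05)
        if cmp_ == "eq":
            ok = abs(dev) <= tol
        elif cmp_ == "le":
            ok = got <= ref * (1 + t.get("rel_tol", 0.0))
        elif cmp_ == "ge":
            ok = got >= ref * (1 - t.get("rel_tol", 0.0))
        else:
            raise ValueError(f"unknown cmp: {cmp_!r}")
        rows.append({**{k: t[k] for k in ("id", "metric", "value")},
                     "measured": got, "status": "pass" if ok else "fail",
                     "deviation_pct": round(dev, 2)})
    frame = pd.DataFrame(rows)
    return frame, bool((frame.status != "fail").all()
                       and (frame.status == "pass").any())
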