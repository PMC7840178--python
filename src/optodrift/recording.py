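"""Simulation recordings: probe traces, voltage snapshots, provenance.

A :class:`Recording` bundles everything an analysis stage needs — probe
voltage timeseries, optional full-field snapshots at a fixed stride, and a
metadata document (grid geometry, dt, light pattern, stimulus protocol,
seed, package version) — and round-trips through HDF5 (probes and snapshots
as datasets, metadata as a JSON attribute).  Synthetic fixtures are written
in the same container so analysis code cannot distinguish them from solver
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Recording"]


@dataclass
class Recording:
    probe_times: np.ndarray                  # ms
    probes: dict                             # name -> V(t) array (mV)
    probe_positions: dict = field(default_factory=dict)   # name -> (x, y) cm
    snap_times: np.ndarray | None = None     # ms
    snapshots: np.ndarray | None = None      # (nt, ny, nx) float32 voltage
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.probe_times, dtype=float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("probe timestamps must be strictly increasing")
        if self.snap_times is not None and len(self.snap_times) > 1:
            if not np.all(np.diff(self.snap_times) > 0):
                raise ValueError("snapshot timestamps must be strictly increasing")

    @property
    def dt_probe(self) -> float:
        return float(np.median(np.diff(self.probe_times)))

    def probe(self, name: str) -> np.ndarray:
        return self.probes[name]

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("probe_times", data=self.probe_times)
            g = f.create_group("probes")
            for name, v in self.probes.items():
                d = g.create_dataset(name, data=v)
                if name in self.probe_positions:
                    d.attrs["position_cm"] = self.probe_positions[name]
            if self.snapshots is not None:
                f.create_dataset("snap_times", data=self.snap_times)
                f.create_dataset("snapshots", data=self.snapshots,
                                 compression="gzip", compression_opts=4)
            f.attrs["meta"] = json.dumps(self.meta, default=_json_default)

    @classmethod
    def load(cls, path) -> "Recording":
        import h5py

        with h5py.File(path, "r") as f:
            probes = {}
            positions = {}
            for name, d in f["probes"].items():
                probes[name] = d[...]
                if "position_cm" in d.attrs:
                    positions[name] = tuple(d.attrs["position_cm"])
            snap_times = f["snap_times"][...] if "snap_times" in f else None
            snapshots = f["snapshots"][...] if "snapshots" in f else None
            return cls(probe_times=f["probe_times"][...], probes=probes,
                       probe_positions=positions, snap_times=snap_times,
                       snapshots=snapshots, meta=json.loads(f.attrs["meta"]))

    def probes_frame(self):
        """Probe traces as a tidy DataFrame (one column per probe)."""
        import pandas as pd

        return pd.DataFrame({"t_ms": self.probe_times, **self.probes})


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
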