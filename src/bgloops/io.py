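"""Serialization of runs: trajectories, event logs, weights, summaries.

The canonical on-disk record of a run is plain text: a tidy CSV trajectory
table (t, group, channel, u, y, d), a CSV event log (t, event, target), one
CSV per plastic weight matrix, a JSON summary and a copy of the resolved
configuration (provenance).  An HDF5 container mirroring the same content
can be written alongside when requested.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .core import TimeSeries

__all__ = ["write_run", "read_summary", "events_frame"]


def events_frame(events) -> pd.DataFrame:
    """Normalize a list of board/agent events into a (t, event, target) frame."""
    rows = []
    for e in events:
        target = getattr(e, "target", None)
        if target is None and hasattr(e, "detail"):
            d = e.detail
            target = d.get("box", d.get("button")) if isinstance(d, dict) else None
        rows.append({"t": e.t, "event": e.event, "target": target})
    return pd.DataFrame(rows, columns=["t", "event", "target"])


def write_run(
    outdir,
    trajectories: Optional[Dict[str, TimeSeries]] = None,
    events=None,
    weights: Optional[Dict[str, np.ndarray]] = None,
    summary: Optional[dict] = None,
    config=None,
    hdf5: bool = False,
) -> Dict[str, Path]:
    """Write a run's artifacts into ``outdir``; returns the file map.

    Every output directory carries the exact resolved config that generated
    it.  All writers emit valid files (headers only) for empty runs.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: Dict[str, Path] = {}

    frames = []
    for name, ts in (trajectories or {}).items():
        df = ts.to_frame()
        df.insert(0, "run", name)
        frames.append(df)
    traj = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["run", "t", "group", "channel", "u", "y", "d"])
    )
    files["trajectories"] = out / "trajectories.csv"
    traj.to_csv(files["trajectories"], index=False)

    files["events"] = out / "events.csv"
    events_frame(events or []).to_csv(files["events"], index=False)

    for name, w in (weights or {}).items():
        p = out / f"weights_{name}.csv"
        np.savetxt(p, np.atleast_2d(w), delimiter=",")
        files[f"weights_{name}"] = p

    files["summary"] = out / "summary.json"
    files["summary"].write_text(
        json.dumps(summary or {}, indent=2, sort_keys=True, default=_jsonable)
    )

    if config is not None:
        files["config"] = out / "config.yaml"
        config.to_yaml(files["config"])

    if hdf5:
        files["container"] = _write_hdf5(out / "trajectories.h5",
                                         trajectories or {})
    return files


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_hdf5(path: Path, trajectories: Dict[str, TimeSeries]) -> Path:
    import h5py  # optional, only needed for the binary container

    with h5py.File(path, "w") as f:
        for name, ts in trajectories.items():
            run = f.create_group(f"series/{name}")
            run.create_dataset("t", data=ts.t)
            run.create_dataset("d", data=ts.d)
            for group, sl in ts.index.items():
                g = run.create_group(group)
                g.create_dataset("u", data=ts.u[:, sl])
                g.create_dataset("y", data=ts.y[:, sl])
    return path


def read_summary(outdir) -> dict:
    return json.loads((Path(outdir) / "summary.json").read_text())
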