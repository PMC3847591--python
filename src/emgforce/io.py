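"""Trial file I/O.

Trials are delimited text: columns ``time_s``, ``emg_gas``, ``emg_sol``
and optionally ``torque_Nm`` (EMG-only trials omit it), plus a JSON
sidecar ``<name>.segments.json`` carrying the labelled segments and the
generator seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .series import UniformSeries
from .synth import Trial

EMG_PREFIX = "emg_"


def write_trial(path: str | Path, trial: Trial, float_format: str = "%.9g") -> Path:
    """Write a trial CSV and its segments sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    first = next(iter(trial.emg.values()))
    cols: dict[str, np.ndarray] = {"time_s": first.times}
    for name, series in trial.emg.items():
        cols[f"{EMG_PREFIX}{name}"] = series.values
    if trial.torque is not None:
        cols["torque_Nm"] = trial.torque.values
    pd.DataFrame(cols).to_csv(path, index=False, float_format=float_format)
    sidecar = path.with_suffix(".segments.json")
    sidecar.write_text(
        json.dumps(
            {"segments": [list(s) for s in trial.segments], "seed": trial.seed, "fs": trial.fs},
            indent=2,
        )
        + "\n"
    )
    return path


def read_trial(path: str | Path) -> Trial:
    """Read a trial CSV (header required) and its sidecar if present."""
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column time_s")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = float(np.median(np.diff(t)))
    emg = {}
    for col in df.columns:
        if col.startswith(EMG_PREFIX):
            emg[col[len(EMG_PREFIX):]] = UniformSeries(dt=dt, values=df[col].to_numpy(), t0=float(t[0]))
    if not emg:
        raise ValueError(f"{path}: no EMG channels found")
    torque = None
    if "torque_Nm" in df.columns:
        torque = UniformSeries(dt=dt, values=df["torque_Nm"].to_numpy(), t0=float(t[0]))
    segments: tuple = ()
    seed, fs = 0, 1.0 / dt
    sidecar = path.with_suffix(".segments.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        segments = tuple((s[0], int(s[1]), int(s[2])) for s in meta.get("segments", []))
        seed = int(meta.get("seed", 0))
        fs = float(meta.get("fs", fs))
    return Trial(emg=emg, torque=torque, segments=segments, seed=seed, fs=fs)
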