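"""Plain-text serialization of sessions, spike trains and models.

A session (optionally with an aligned spike train) is stored as a
tab-separated table with one row per 1 ms bin and columns

    time_ms  trial  angle_deg  curvature_invmm  dcurvature_invmm
    touch  pole_pos_mm  [spike]

plus a JSON sidecar ``<path>.meta.json`` recording the protocol, seed and
generator parameters.  The round trip is lossless to float-formatting
precision.  Delimited text was chosen over binary containers for
diffability at these sizes (at most a few hundred thousand rows).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Session, SpikeTrain

__all__ = ["write_session", "read_session", "meta_path"]

_COLUMNS = [
    "time_ms", "trial", "angle_deg", "curvature_invmm",
    "dcurvature_invmm", "touch", "pole_pos_mm",
]


def meta_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_session(session: Session, path, spikes: SpikeTrain = None) -> None:
    """Write a session (and optional aligned spike train) to delimited text."""
    path = Path(path)
    trial = session.trial_index()
    frame = pd.DataFrame({
        "time_ms": np.arange(session.n_bins),
        "trial": trial,
        "angle_deg": session.angle_deg,
        "curvature_invmm": session.curvature_invmm,
        "dcurvature_invmm": session.curvature_change_invmm,
        "touch": session.touch,
        "pole_pos_mm": session.pole_pos_mm[trial],
    })
    if spikes is not None:
        if spikes.counts.shape[0] != session.n_bins:
            raise ValueError("spike train length does not match session")
        frame["spike"] = spikes.counts
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {
        "protocol": session.protocol,
        "seed": session.seed,
        "params": _jsonable(session.params),
        "trial_bounds": [list(b) for b in session.trial_bounds],
    }
    with open(meta_path(path), "w") as f:
        json.dump(meta, f, indent=1)


def read_session(path):
    """Read a session written by :func:`write_session`.

    Returns ``(session, spikes_or_None)``.  Malformed tables raise a
    ``ValueError`` naming the offending line or column.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    expected = np.arange(len(frame))
    if not np.array_equal(frame["time_ms"].to_numpy(), expected):
        bad = int(np.argmax(frame["time_ms"].to_numpy() != expected))
        raise ValueError(f"{path}: non-contiguous time_ms at data line {bad + 1}")
    mp = meta_path(path)
    if mp.exists():
        with open(mp) as f:
            meta = json.load(f)
        trial_bounds = [tuple(b) for b in meta["trial_bounds"]]
        protocol, seed, params = meta["protocol"], meta["seed"], meta.get("params", {})
    else:
        # reconstruct bounds from the trial column
        trial = frame["trial"].to_numpy()
        changes = np.flatnonzero(np.diff(trial)) + 1
        starts = np.concatenate(([0], changes))
        stops = np.concatenate((changes, [len(trial)]))
        trial_bounds = list(zip(starts.tolist(), stops.tolist()))
        protocol, seed, params = "active_pole", -1, {}
    trial = frame["trial"].to_numpy()
    pole = np.full(len(trial_bounds), np.nan)
    for i, (a0, _) in enumerate(trial_bounds):
        pole[i] = frame["pole_pos_mm"].iloc[a0]
    session = Session(
        angle_deg=frame["angle_deg"].to_numpy(),
        curvature_invmm=frame["curvature_invmm"].to_numpy(),
        curvature_change_invmm=frame["dcurvature_invmm"].to_numpy(),
        trial_bounds=trial_bounds,
        pole_pos_mm=pole,
        touch=frame["touch"].to_numpy(),
        protocol=protocol,
        seed=seed,
        params=params,
    )
    spikes = None
    if "spike" in frame.columns:
        spikes = SpikeTrain(counts=frame["spike"].to_numpy(), session_id=session.session_id)
    return session, spikes


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
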