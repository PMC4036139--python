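"""Plain-text file formats: TSV tables, JSON models, text grids.

All tables are tab-separated with mandatory headers, '.' decimal
separators and no locale dependence. Frame indices are 0-based and
intervals half-open.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chains import Chain, TriggeredTrace
from .simulate import TrackedSession

SESSION_COLUMNS = ["session_id", "fish_id", "night_id", "condition",
                   "frame", "t_s", "x_cm", "y_cm", "heading_deg"]


class FormatError(ValueError):
    pass


def write_session_tsv(sessions, path) -> None:
    frames = [s.to_frame() for s in (sessions if isinstance(sessions, (list, tuple)) else [sessions])]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_session_table(path) -> list[TrackedSession]:
    """Read a session TSV into typed, validated sessions.

    Raises :class:`FormatError` naming the offending row for missing
    columns or non-monotonic timestamps within a session.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    sessions = []
    for sid, grp in df.groupby("session_id", sort=False):
        grp = grp.reset_index()
        t = grp["t_s"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(t) <= 0)
        if len(bad):
            row = int(grp.loc[bad[0] + 1, "index"]) + 2  # 1-based incl. header
            raise FormatError(f"non-monotonic t_s in session {sid!r} at file row {row}")
        sessions.append(
            TrackedSession(
                session_id=str(sid),
                fish_id=str(grp["fish_id"].iloc[0]),
                night_id=str(grp["night_id"].iloc[0]),
                condition=str(grp["condition"].iloc[0]),
                frame_index=grp["frame"].to_numpy(dtype=int),
                t=t,
                x=grp["x_cm"].to_numpy(dtype=float),
                y=grp["y_cm"].to_numpy(dtype=float),
                heading=grp["heading_deg"].to_numpy(dtype=float),
                gt_pm=grp["gt_pm"].to_numpy(dtype=int) if "gt_pm" in grp else None,
                gt_behavior=grp["gt_behavior"].to_numpy(dtype=str) if "gt_behavior" in grp else None,
            )
        )
    return sessions


def write_kinematics_tsv(kin, path, labels=None, z=None) -> None:
    df = kin.to_frame()
    if z is not None:
        df["z_thrust"], df["z_slip"], df["z_yaw"] = z[:, 0], z[:, 1], z[:, 2]
    if labels is not None:
        df["pm"] = labels
    df.to_csv(path, sep="\t", index=False)


def read_kinematics_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_chains_tsv(chains: Sequence[Chain], path) -> None:
    pd.DataFrame(
        [
            {
                "session_id": c.session_id, "start": c.start, "end": c.end,
                "pm": c.pm_id, "n_frames": c.n_frames, "duration_s": c.duration_s,
                "mean_thrust": c.mean_thrust, "behavior": c.behavior,
                "onset_t": c.onset_t,
            }
            for c in chains
        ]
    ).to_csv(path, sep="\t", index=False)


def write_trace_tsv(trace, path, signal: str = "signal") -> None:
    """Write a triggered or distance-referenced trace; the x column is
    ``t_rel`` (s) for onset-triggered traces, ``bin_centers`` (cm) for
    distance-referenced ones."""
    x = trace.t_rel if hasattr(trace, "t_rel") else trace.bin_centers
    xname = "t_rel" if hasattr(trace, "t_rel") else "distance_cm"
    pd.DataFrame(
        {
            xname: x,
            "signal": signal,
            "mean": trace.mean,
            "sd": trace.sd,
            "ci_lo": trace.ci_lo,
            "ci_hi": trace.ci_hi,
            "n": trace.n,
        }
    ).to_csv(path, sep="\t", index=False)


def write_grid(path, grid: np.ndarray, header: dict) -> None:
    """Plain-text matrix with a one-line JSON header (prefixed '#')."""
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        np.savetxt(fh, grid, fmt="%.6g")


def read_grid(path) -> tuple[np.ndarray, dict]:
    with open(path) as fh:
        header = json.loads(fh.readline().lstrip("# "))
    return np.loadtxt(path, skiprows=1), header


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
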