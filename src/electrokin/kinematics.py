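"""Egocentric kinematics from tracked head positions and headings.

For each interval between successive EOD-triggered frames the head
displacement is rotated into the animal's frame of reference at the
leading frame: thrust is the component along the heading, slip the
component 90 degrees counterclockwise of it (positive to the animal's
left), and yaw the wrapped heading change, each divided by the interval
duration. Velocities are assigned to the leading frame; the last frame
of a contiguous segment carries none.

Before clustering, the three channels are z-scored with thrust and slip
sharing one mean/SD (they are commensurate translational velocities)
and yaw getting its own, which puts translational and rotational
kinematics on a common dimensionless scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .simulate import TrackedSession, wrap_deg


class KinematicsError(ValueError):
    pass


@dataclass
class KinematicSeries:
    """Per-interval velocities aligned to the leading frame.

    ``segment`` identifies contiguous stretches of frames: removed frames
    (gaps in ``frame_index``) split the series and no velocity spans a gap.
    """

    session_id: str
    frame_index: np.ndarray  # leading frame of each interval
    t: np.ndarray            # time of the leading frame (s)
    dt: np.ndarray           # interval duration (s)
    thrust: np.ndarray       # cm/s
    slip: np.ndarray         # cm/s
    yaw: np.ndarray          # deg/s
    segment: np.ndarray      # contiguous-segment id per interval

    def __len__(self) -> int:
        return len(self.dt)

    def values(self) -> np.ndarray:
        """(n, 3) array of (thrust, slip, yaw)."""
        return np.column_stack([self.thrust, self.slip, self.yaw])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "session_id": self.session_id,
                "frame": self.frame_index,
                "t_s": self.t,
                "dt_s": self.dt,
                "thrust": self.thrust,
                "slip": self.slip,
                "yaw": self.yaw,
                "segment": self.segment,
            }
        )


@dataclass
class ScalerParams:
    """Z-scoring parameters: one mean/SD pooled over thrust and slip
    jointly, a separate mean/SD for yaw. SDs are sample SDs (ddof=1)."""

    trans_mean: float
    trans_sd: float
    rot_mean: float
    rot_sd: float

    def to_dict(self) -> dict:
        return {
            "trans_mean": self.trans_mean,
            "trans_sd": self.trans_sd,
            "rot_mean": self.rot_mean,
            "rot_sd": self.rot_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(**{k: float(d[k]) for k in ("trans_mean", "trans_sd", "rot_mean", "rot_sd")})


def compute_kinematics(session: TrackedSession) -> KinematicSeries:
    """Convert a tracked session into per-interval thrust/slip/yaw.

    Raises :class:`KinematicsError` on non-monotonic timestamps or zero
    intervals. Gaps in ``frame_index`` split the series into segments.
    """
    t = np.asarray(session.t, dtype=float)
    if len(t) < 2:
        raise KinematicsError("need at least 2 frames")
    dt_all = np.diff(t)
    if np.any(dt_all < 0):
        bad = int(np.flatnonzero(dt_all < 0)[0]) + 1
        raise KinematicsError(f"non-monotonic timestamps at frame {bad}")
    fi = np.asarray(session.frame_index)
    seg_break = np.diff(fi) != 1
    intra = ~seg_break  # intervals within a contiguous segment
    if np.any(dt_all[intra] <= 0):
        bad = int(np.flatnonzero(intra & (dt_all <= 0))[0]) + 1
        raise KinematicsError(f"zero or negative dt at frame {bad}")

    dx = np.diff(np.asarray(session.x, dtype=float))
    dy = np.diff(np.asarray(session.y, dtype=float))
    head = np.asarray(session.heading, dtype=float)
    th = np.radians(head[:-1])
    thrust = (dx * np.cos(th) + dy * np.sin(th)) / dt_all
    slip = (-dx * np.sin(th) + dy * np.cos(th)) / dt_all
    yaw = wrap_deg(head[1:] - head[:-1]) / dt_all

    seg_id = np.concatenate([[0], np.cumsum(seg_break)])[:-1]
    keep = intra
    return KinematicSeries(
        session_id=session.session_id,
        frame_index=fi[:-1][keep],
        t=t[:-1][keep],
        dt=dt_all[keep],
        thrust=thrust[keep],
        slip=slip[keep],
        yaw=yaw[keep],
        segment=seg_id[keep],
    )


def _stack_values(kinematics) -> np.ndarray:
    if isinstance(kinematics, KinematicSeries):
        return kinematics.values()
    if isinstance(kinematics, (list, tuple)):
        return np.concatenate([_stack_values(k) for k in kinematics])
    arr = np.asarray(kinematics, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise KinematicsError("expected (n, 3) kinematic triples")
    return arr


def fit_scaler(kinematics) -> ScalerParams:
    """Fit z-scoring parameters on one series, a list of series, or an
    (n, 3) array of (thrust, slip, yaw) triples."""
    v = _stack_values(kinematics)
    if len(v) < 2:
        raise KinematicsError("need at least 2 records to fit a scaler")
    trans = np.concatenate([v[:, 0], v[:, 1]])
    tm, ts = float(np.mean(trans)), float(np.std(trans, ddof=1))
    rm, rs = float(np.mean(v[:, 2])), float(np.std(v[:, 2], ddof=1))
    if ts == 0.0:
        raise KinematicsError("zero variance in the translational (thrust/slip) channel")
    if rs == 0.0:
        raise KinematicsError("zero variance in the rotational (yaw) channel")
    return ScalerParams(tm, ts, rm, rs)


def apply_scaler(params: ScalerParams, kinematics, inverse: bool = False) -> np.ndarray:
    """Z-score (or, with ``inverse=True``, un-z-score) kinematic triples."""
    v = _stack_values(kinematics)
    out = np.empty_like(v)
    if inverse:
        out[:, 0] = v[:, 0] * params.trans_sd + params.trans_mean
        out[:, 1] = v[:, 1] * params.trans_sd + params.trans_mean
        out[:, 2] = v[:, 2] * params.rot_sd + params.rot_mean
    else:
        out[:, 0] = (v[:, 0] - params.trans_mean) / params.trans_sd
        out[:, 1] = (v[:, 1] - params.trans_mean) / params.trans_sd
        out[:, 2] = (v[:, 2] - params.rot_mean) / params.rot_sd
    return out
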