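"""Synthetic EOD-triggered tracking sessions with ground truth.

Sessions are built from a script of macro-behaviors (cruise, object
approach, stationary probing, backwards swimming, departure). Within a
behavior, per-frame prototypical-movement (PM) labels follow a
first-order Markov chain over the PMs assigned to that behavior;
per-interval velocities are Gaussian emissions around the PM means;
inter-pulse intervals are gamma-distributed with a mean set by the PM's
EOD rate (raised near the object); head position and heading are
integrated from the body-frame velocities over each realized interval.

All randomness flows through a single :class:`numpy.random.Generator`,
so identical seeds give identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import BEHAVIORS, ConfigError, GeneratorConfig

#: Distance (cm) below which an approach segment counts as completed.
APPROACH_ARRIVAL_CM = 2.5
#: Hard timeout (s) for approach segments that fail to reach the object.
APPROACH_TIMEOUT_S = 4.0
#: Distance (cm) inside which approach/departure thrust means ramp down.
THRUST_RAMP_CM = 10.0
#: Floor of the thrust ramp (fraction of the PM's thrust mean).
THRUST_RAMP_FLOOR = 0.85
#: Assumed mean frame rate (Hz) when sizing behavior scripts.
NOMINAL_RATE_HZ = 25.0

_STAY_P = {"cruise": 0.85, "approach": 0.70, "departure": 0.70,
           "stationary": 1.0, "backwards": 1.0}
#: Occupancy preference over cruise PMs (0-based indices 1..9):
#: intermediate amplitudes are favored, extremes are rare.
_CRUISE_PREF = np.array([0.14, 0.10, 0.10, 0.13, 0.13, 0.12, 0.12, 0.08, 0.08])
_CRUISE_STATES = np.arange(1, 10)
_BAND = {1: 0, 2: 1, 3: 1, 4: 2, 5: 2, 6: 3, 7: 3, 8: 4, 9: 4}


@dataclass
class TrackedSession:
    """One EOD-triggered tracking session.

    Frames are ordered by strictly increasing EOD time; positions are in
    cm within the camera view, headings in degrees in (-180, 180].
    Ground-truth PM labels (1-based) and macro-behavior labels are kept
    when the session was generated synthetically.
    """

    session_id: str
    fish_id: str
    night_id: str
    condition: str
    frame_index: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    gt_pm: Optional[np.ndarray] = None
    gt_behavior: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def locate(self, frames: np.ndarray) -> np.ndarray:
        """Positional indices of the given frame numbers (frame numbers
        are not positional once out-of-view frames have been removed)."""
        return np.searchsorted(self.frame_index, np.asarray(frames))

    def to_frame(self):
        import pandas as pd

        d = {
            "session_id": self.session_id,
            "fish_id": self.fish_id,
            "night_id": self.night_id,
            "condition": self.condition,
            "frame": self.frame_index,
            "t_s": self.t,
            "x_cm": self.x,
            "y_cm": self.y,
            "heading_deg": self.heading,
        }
        if self.gt_pm is not None:
            d["gt_pm"] = self.gt_pm
        if self.gt_behavior is not None:
            d["gt_behavior"] = self.gt_behavior
        return pd.DataFrame(d)


def wrap_deg(a):
    """Wrap angles (deg) into (-180, 180]."""
    w = np.mod(np.asarray(a, dtype=float), 360.0)
    return np.where(w > 180.0, w - 360.0, w)


def sample_behavior_script(config: GeneratorConfig, rng: np.random.Generator,
                           target_duration_s: Optional[float] = None):
    """Draw an ordered list of (macro_behavior, duration_s) segments.

    Behaviors are drawn independently from ``behavior_script_weights``;
    durations are log-normal around the per-behavior medians. Without an
    object, object-directed behaviors are never emitted and the script
    consists of (shelter-biased) cruise segments only. The script covers
    at least ``target_duration_s`` (default: the session target length
    at the nominal frame rate, with margin).
    """
    weights = dict(config.behavior_script_weights)
    if any(v < 0 for v in weights.values()) or sum(weights.values()) <= 0:
        raise ConfigError("behavior weights must be nonnegative and normalizable")
    if not config.object_present:
        weights = {"cruise": 1.0}
    names = [b for b in BEHAVIORS if weights.get(b, 0.0) > 0]
    p = np.array([weights[b] for b in names], dtype=float)
    p /= p.sum()
    if target_duration_s is None:
        target_duration_s = 1.25 * config.n_frames_target / NOMINAL_RATE_HZ + 10.0
    script = []
    total = 0.0
    sigma = config.behavior_duration_sigma
    while total < target_duration_s:
        b = names[rng.choice(len(names), p=p)]
        dur = config.behavior_duration_medians[b] * np.exp(sigma * rng.standard_normal())
        script.append((b, float(dur)))
        total += dur
    return script


class _PMChain:
    """Per-behavior first-order Markov chain over PM indices (0-based)."""

    def __init__(self, config: GeneratorConfig, generic: bool):
        self.generic = generic
        self.k = config.n_prototypes
        if not generic:
            # cruise switch kernel: prefer neighboring amplitude bands
            w = np.zeros((9, 9))
            for a, i in enumerate(_CRUISE_STATES):
                for b, j in enumerate(_CRUISE_STATES):
                    if i != j:
                        w[a, b] = _CRUISE_PREF[b] * np.exp(-abs(_BAND[i] - _BAND[j]) / 1.5)
            self._cruise_switch = w / w.sum(axis=1, keepdims=True)

    def init(self, behavior: str, rng: np.random.Generator) -> int:
        if self.generic:
            return int(rng.integers(self.k))
        if behavior in ("stationary", "backwards"):
            return 0
        if behavior in ("approach", "departure"):
            return 1
        return int(_CRUISE_STATES[rng.choice(9, p=_CRUISE_PREF / _CRUISE_PREF.sum())])

    def step(self, behavior: str, pm: int, rng: np.random.Generator,
             steer_sign: float = 0.0, p_steer: float = 0.85) -> int:
        """Advance one frame. ``steer_sign`` biases the choice between
        mirror-pair members toward the yaw sign that reduces the heading
        error to the current target (+1 = turn counterclockwise)."""
        if self.generic:
            if rng.random() < 0.8 or self.k == 1:
                return pm
            others = [i for i in range(self.k) if i != pm]
            return int(others[rng.integers(len(others))])
        if rng.random() < _STAY_P[behavior]:
            return pm
        if behavior in ("stationary", "backwards"):
            return 0
        if behavior in ("approach", "departure"):
            if pm == 1:  # PM 02 -> one of PM 07/08
                return self._pick_member(6, 7, steer_sign, rng, p_steer)
            if rng.random() < 0.85:
                return 1
            return self._pick_member(6, 7, steer_sign, rng, p_steer)
        # cruise
        a = int(np.flatnonzero(_CRUISE_STATES == pm)[0])
        j = int(_CRUISE_STATES[rng.choice(9, p=self._cruise_switch[a])])
        if steer_sign != 0.0:
            partner = {2: 3, 3: 2, 4: 5, 5: 4, 6: 7, 7: 6, 8: 9, 9: 8}.get(j)
            if partner is not None and rng.random() < 0.9:
                j = self._pick_member(min(j, partner), max(j, partner), steer_sign, rng, 1.0)
        return j

    @staticmethod
    def _pick_member(left: int, right: int, steer_sign: float,
                     rng: np.random.Generator, p_steer: float) -> int:
        """``left`` has positive yaw (counterclockwise), ``right`` negative."""
        if steer_sign == 0.0 or rng.random() >= p_steer:
            return left if rng.random() < 0.5 else right
        return left if steer_sign > 0 else right


def _reflect(v: float, lo: float, hi: float) -> tuple[float, int]:
    n = 0
    while v < lo or v > hi:
        v = 2 * lo - v if v < lo else 2 * hi - v
        n += 1
    return v, n


def generate_session(config: GeneratorConfig, seed: Optional[int] = None,
                     session_id: str = "S00", fish_id: str = "F00",
                     night_id: str = "N00") -> TrackedSession:
    """Generate one tracked session under ``config``.

    Trajectories leaving the recorded view are reflected at its walls
    (never silently clipped); the number of reflections is logged in
    ``session.meta['n_reflections']``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    table = np.asarray(config.prototype_table, dtype=float)
    sds = np.asarray(config.emission_sd, dtype=float)
    rates = np.asarray(config.feod_base_table, dtype=float)
    generic = not config.check_prototype_structure
    chain = _PMChain(config, generic)
    ox, oy = config.object_position
    half_w = config.view_extent[0] / 2.0
    half_h = config.view_extent[1] / 2.0
    shelters = np.asarray(config.shelter_positions, dtype=float)

    script = iter(sample_behavior_script(config, rng))

    def next_segment():
        nonlocal script
        try:
            return next(script)
        except StopIteration:
            script = iter(sample_behavior_script(config, rng, target_duration_s=60.0))
            return next(script)

    # start pose: near a shelter without an object, anywhere in view with one
    if config.object_present or len(shelters) == 0 or generic:
        x = rng.uniform(-half_w + 2, half_w - 2)
        y = rng.uniform(-half_h + 2, half_h - 2)
    else:
        sx, sy = shelters[rng.integers(len(shelters))]
        x = float(np.clip(sx + 3 * rng.standard_normal(), -half_w + 1, half_w - 1))
        y = float(np.clip(sy + 3 * rng.standard_normal(), -half_h + 1, half_h - 1))
    theta = float(rng.uniform(-180.0, 180.0))

    n = config.n_frames_target
    t = np.empty(n)
    xs = np.empty(n)
    ys = np.empty(n)
    heads = np.empty(n)
    gt_pm = np.empty(n, dtype=int)
    gt_beh = np.empty(n, dtype=object)
    dropped = np.zeros(n, dtype=bool)
    n_reflections = 0

    behavior, seg_dur = next_segment()
    seg_elapsed = 0.0
    pm = chain.init(behavior, rng)
    now = 0.0

    for i in range(n):
        d_obj = float(np.hypot(x - ox, y - oy))
        # segment bookkeeping (checked at frame boundaries)
        done = seg_elapsed >= seg_dur
        if behavior == "approach" and not generic:
            done = d_obj < APPROACH_ARRIVAL_CM or seg_elapsed >= max(seg_dur, APPROACH_TIMEOUT_S)
        if done:
            behavior, seg_dur = next_segment()
            seg_elapsed = 0.0
            pm = chain.init(behavior, rng)
        else:
            steer = 0.0
            if not generic:
                if behavior == "approach":
                    steer = np.sign(wrap_deg(np.degrees(np.arctan2(oy - y, ox - x)) - theta))
                elif behavior == "departure":
                    steer = np.sign(wrap_deg(np.degrees(np.arctan2(y - oy, x - ox)) - theta))
                elif behavior == "cruise" and not config.object_present and len(shelters):
                    ds = np.hypot(shelters[:, 0] - x, shelters[:, 1] - y)
                    jmin = int(np.argmin(ds))
                    if ds[jmin] > 10.0:
                        tgt = np.degrees(np.arctan2(shelters[jmin, 1] - y,
                                                    shelters[jmin, 0] - x))
                        steer = np.sign(wrap_deg(tgt - theta))
            pm = chain.step(behavior, pm, rng, steer_sign=steer)

        # emission
        mean = table[pm].copy()
        if not generic:
            if behavior == "stationary":
                mean[0] = -0.4
            elif behavior == "backwards":
                mean[0] = -2.9
            elif behavior in ("approach", "departure") and config.object_present:
                if d_obj < THRUST_RAMP_CM:
                    mean[0] *= max(THRUST_RAMP_FLOOR, d_obj / THRUST_RAMP_CM)
        thrust, slip, yaw = mean + sds[pm] * rng.standard_normal(3)

        rate = rates[pm]
        if config.object_present and d_obj < config.feod_near_radius_cm:
            rate = rate * config.feod_near_gain
        ipi = rng.gamma(config.ipi_shape, 1.0 / (rate * config.ipi_shape))

        t[i] = now
        xs[i] = x
        ys[i] = y
        heads[i] = wrap_deg(theta)
        gt_pm[i] = pm + 1
        gt_beh[i] = behavior

        # integrate in the body frame at the current heading
        th = np.radians(theta)
        x = x + (thrust * np.cos(th) - slip * np.sin(th)) * ipi
        y = y + (thrust * np.sin(th) + slip * np.cos(th)) * ipi
        theta = float(wrap_deg(theta + yaw * ipi))
        x, bx = _reflect(x, -half_w, half_w)
        y, by = _reflect(y, -half_h, half_h)
        if bx % 2:
            theta = float(wrap_deg(180.0 - theta))
        if by % 2:
            theta = float(wrap_deg(-theta))
        if bx + by:
            # the fish touched the view boundary: the landing frame is
            # removed from the track (as out-of-view frames are), which
            # leaves a contiguity gap instead of a spurious velocity
            n_reflections += bx + by
            if i + 1 < n:
                dropped[i + 1] = True
        now += ipi
        seg_elapsed += ipi

    keep = ~dropped
    return TrackedSession(
        session_id=session_id,
        fish_id=fish_id,
        night_id=night_id,
        condition=config.condition,
        frame_index=np.arange(n)[keep],
        t=t[keep],
        x=xs[keep],
        y=ys[keep],
        heading=heads[keep],
        gt_pm=gt_pm[keep],
        gt_behavior=gt_beh[keep].astype(str),
        meta={
            "n_reflections": int(n_reflections),
            "n_dropped_frames": int(dropped.sum()),
            "seed": int(config.seed if seed is None else seed),
        },
    )


def generate_dataset(config: GeneratorConfig, n_sessions: int, seed: int,
                     fish_per_night: int = 1) -> list[TrackedSession]:
    """Generate ``n_sessions`` sessions with seeds derived from ``seed``
    by fixed offsets; session/fish/night ids are synthesized."""
    out = []
    for s in range(n_sessions):
        out.append(
            generate_session(
                config,
                seed=seed + 101 * s,
                session_id=f"S{s:02d}",
                fish_id=f"F{s % max(1, fish_per_night):02d}",
                night_id=f"N{s // max(1, fish_per_night):02d}",
            )
        )
    return out
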