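"""Homogeneous PM chains and onset-triggered averages.

A chain is a maximal run of consecutive frames sharing one PM label
(within a contiguous tracking segment), subject to a minimum length.
Chains of the backward/low-thrust prototype (PM 01) are split by their
mean thrust velocity into "stationary behavior" (near-zero thrust,
object probing) and "backwards swimming" (reversed thrust) at a
threshold of -2 cm/s, with the boundary value counting as stationary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .kinematics import KinematicSeries

STATIONARY_THRESHOLD = -2.0  # cm/s
MIN_CHAIN_LEN = 10           # frames


@dataclass
class Chain:
    """A maximal homogeneous PM run over interval records, 0-based and
    half-open in the record index."""

    session_id: str
    start: int
    end: int
    pm_id: int
    n_frames: int
    duration_s: float
    mean_thrust: float
    behavior: str = "unclassified"
    onset_t: float = 0.0


@dataclass
class TriggeredTrace:
    """Mean/SD/95% CI of a signal on a regular grid around chain onsets."""

    t_rel: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n: np.ndarray


def extract_runs(labels: np.ndarray, pm_id: int, min_len: int = MIN_CHAIN_LEN,
                 segments: Optional[np.ndarray] = None) -> list[tuple[int, int]]:
    """Maximal runs of ``pm_id`` of at least ``min_len`` frames.

    ``segments`` (same length as ``labels``) splits runs at contiguity
    gaps. Returns 0-based half-open (start, end) index pairs.
    """
    lab = np.asarray(labels)
    n = len(lab)
    if n == 0:
        return []
    seg = np.zeros(n) if segments is None else np.asarray(segments)
    hit = lab == pm_id
    # boundaries where the run state or the segment changes
    brk = np.flatnonzero((hit[1:] != hit[:-1]) | (seg[1:] != seg[:-1])) + 1
    edges = np.concatenate([[0], brk, [n]])
    out = []
    for s, e in zip(edges[:-1], edges[1:]):
        if hit[s] and e - s >= min_len:
            out.append((int(s), int(e)))
    return out


def extract_chains(kin: KinematicSeries, labels: np.ndarray, pm_id: int,
                   min_len: int = MIN_CHAIN_LEN) -> list[Chain]:
    """Runs of ``pm_id`` in a labeled kinematic series, annotated with
    duration, mean thrust, and onset time."""
    runs = extract_runs(labels, pm_id, min_len=min_len, segments=kin.segment)
    chains = []
    for s, e in runs:
        chains.append(
            Chain(
                session_id=kin.session_id,
                start=s,
                end=e,
                pm_id=pm_id,
                n_frames=e - s,
                duration_s=float(np.sum(kin.dt[s:e])),
                mean_thrust=float(np.mean(kin.thrust[s:e])),
                onset_t=float(kin.t[s]),
            )
        )
    return chains


def split_pm01(chains: Sequence[Chain], threshold: float = STATIONARY_THRESHOLD) -> list[Chain]:
    """Label PM 01 chains as backwards (mean thrust < threshold) or
    stationary (>= threshold; the boundary is inclusive on the
    stationary side). Raises on chains of any other PM."""
    out = []
    for c in chains:
        if c.pm_id != 1:
            raise ValueError(f"split_pm01 got a PM {c.pm_id:02d} chain")
        c.behavior = "backwards" if c.mean_thrust < threshold else "stationary"
        out.append(c)
    return out


def chain_statistics(chains: Sequence[Chain]) -> dict:
    """Count, mean +/- SD of length (frames) and duration (s). A single
    chain reports SD 0; an empty set reports count 0 with NaN moments."""
    n = len(chains)
    if n == 0:
        return {"count": 0, "mean_length": float("nan"), "sd_length": float("nan"),
                "mean_duration_s": float("nan"), "sd_duration_s": float("nan")}
    lengths = np.array([c.n_frames for c in chains], dtype=float)
    durs = np.array([c.duration_s for c in chains], dtype=float)
    sd_l = float(np.std(lengths, ddof=1)) if n > 1 else 0.0
    sd_d = float(np.std(durs, ddof=1)) if n > 1 else 0.0
    return {
        "count": n,
        "mean_length": float(np.mean(lengths)),
        "sd_length": sd_l,
        "mean_duration_s": float(np.mean(durs)),
        "sd_duration_s": sd_d,
    }


def triggered_average(signals: Sequence[tuple[np.ndarray, np.ndarray]],
                      onsets: Sequence[tuple[int, float]],
                      window: tuple[float, float] = (1.0, 1.5),
                      step: float = 0.04,
                      tol: Optional[float] = None) -> TriggeredTrace:
    """Average a signal around chain onsets on a regular time grid.

    ``signals`` is one (t, value) pair per session; ``onsets`` is a list
    of (session_index, onset_time_s). Each onset contributes its
    session's signal resampled by nearest-frame lookup onto the grid
    ``-window[0] .. +window[1]`` (step 0.04 s by default); grid points
    with no frame within ``tol`` (default: one step) do not contribute.
    Per grid point the mean, sample SD, and t-based 95% CI of the mean
    are returned; bins with fewer than 2 contributions are masked (NaN).
    """
    if len(onsets) == 0:
        raise ValueError("no onsets supplied")
    if tol is None:
        tol = step
    pre, post = window
    grid = np.arange(-pre, post + step / 2, step)
    rows = np.full((len(onsets), len(grid)), np.nan)
    for r, (si, t0) in enumerate(onsets):
        t, v = signals[si]
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        targets = t0 + grid
        idx = np.searchsorted(t, targets)
        idx_lo = np.clip(idx - 1, 0, len(t) - 1)
        idx_hi = np.clip(idx, 0, len(t) - 1)
        pick = np.where(
            np.abs(t[idx_hi] - targets) < np.abs(t[idx_lo] - targets), idx_hi, idx_lo
        )
        ok = np.abs(t[pick] - targets) <= tol
        rows[r, ok] = v[pick[ok]]
    n = np.sum(~np.isnan(rows), axis=0)
    good = n >= 2
    mean = np.full(len(grid), np.nan)
    sd = np.full(len(grid), np.nan)
    if good.any():
        mean[good] = np.nanmean(rows[:, good], axis=0)
        sd[good] = np.nanstd(rows[:, good], axis=0, ddof=1)
    tcrit = np.full(len(grid), np.nan)
    tcrit[good] = stats.t.ppf(0.975, n[good] - 1)
    half = tcrit * sd / np.sqrt(np.maximum(n, 1))
    return TriggeredTrace(
        t_rel=grid, mean=mean, sd=sd, ci_lo=mean - half, ci_hi=mean + half, n=n
    )
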