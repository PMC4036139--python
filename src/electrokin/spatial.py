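"""Spatial occupancy, EOD-frequency analytics, and group statistics.

Instantaneous EOD frequency (fEOD) is the reciprocal of the preceding
inter-pulse interval and is z-scored per recording night to remove
between-night shifts in basal emission rate. Maps accumulate frames in
1 cm^2 bins; distance profiles express flagged frames relative to all
frames at each distance to the object; spatial conditionals select
sequence occurrences that end close to the object after closing in
(approach) or start close and recede (departure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

APPROACH_DMAX_CM = 4.0
MAP_BIN_CM = 1.0


@dataclass
class SpatialConfig:
    object_position: tuple[float, float] = (0.0, 0.0)
    object_edge_cm: float = 2.0
    map_extent: tuple[float, float] = (64.0, 48.0)
    map_bin_cm: float = MAP_BIN_CM
    distance_bin_cm: float = 1.0
    approach_dmax_cm: float = APPROACH_DMAX_CM
    near_radius_cm: float = 5.0

    def __post_init__(self):
        if self.map_bin_cm <= 0 or self.distance_bin_cm <= 0:
            raise ValueError("bins must be > 0")
        if self.approach_dmax_cm <= 0 or self.near_radius_cm <= 0:
            raise ValueError("distance limits must be > 0")


def object_distance(x, y, object_position=(0.0, 0.0), object_edge_cm: float = 0.0,
                    surface: bool = False) -> np.ndarray:
    """Head-to-object distance (cm). Default is the distance to the
    object's center; ``surface=True`` subtracts the half edge (clipped
    at zero) for a surface-referenced variant."""
    d = np.hypot(np.asarray(x) - object_position[0], np.asarray(y) - object_position[1])
    if surface:
        d = np.maximum(d - object_edge_cm / 2.0, 0.0)
    return d


# ---------------------------------------------------------------------------
# EOD trains


def instantaneous_feod(eod_times: np.ndarray) -> np.ndarray:
    """Per-frame fEOD (Hz): frame n carries 1/(t_n - t_{n-1}); the first
    frame is NaN. Duplicate timestamps raise."""
    t = np.asarray(eod_times, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 pulses")
    ipi = np.diff(t)
    if np.any(ipi == 0):
        raise ValueError("duplicate EOD timestamps")
    if np.any(ipi < 0):
        raise ValueError("EOD timestamps must be increasing")
    return np.concatenate([[np.nan], 1.0 / ipi])


def zscore_per_night(freqs: np.ndarray, night_ids: Sequence) -> np.ndarray:
    """Z-score fEOD within each recording night (NaN-aware). A night
    with zero variance maps to z = 0."""
    f = np.asarray(freqs, dtype=float)
    nights = np.asarray(night_ids)
    out = np.full_like(f, np.nan)
    for night in np.unique(nights):
        m = nights == night
        vals = f[m]
        ok = ~np.isnan(vals)
        if ok.sum() < 2:
            raise ValueError(f"night {night!r} has fewer than 2 pulses")
        mu = float(np.mean(vals[ok]))
        sd = float(np.std(vals[ok], ddof=1))
        # a numerically constant night maps to z = 0
        constant = sd <= 1e-9 * max(1.0, abs(mu))
        z = np.full_like(vals, np.nan)
        z[ok] = 0.0 if constant else (vals[ok] - mu) / sd
        out[m] = z
    return out


# ---------------------------------------------------------------------------
# Maps and profiles


@dataclass
class SpatialMaps:
    counts: np.ndarray
    mean_value: Optional[np.ndarray]
    x_edges: np.ndarray
    y_edges: np.ndarray
    n_dropped: int


def occupancy_and_value_maps(x, y, values=None,
                             extent: tuple[float, float] = (64.0, 48.0),
                             bin_cm: float = MAP_BIN_CM,
                             center: tuple[float, float] = (0.0, 0.0)) -> SpatialMaps:
    """Two-dimensional occupancy histogram (counts per ``bin_cm``^2 bin)
    and, if ``values`` is given, the mean value per bin with empty bins
    masked as NaN. Out-of-extent frames are dropped and counted."""
    if bin_cm <= 0:
        raise ValueError("bin must be > 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    hw, hh = extent[0] / 2.0, extent[1] / 2.0
    x_edges = center[0] + np.arange(-hw, hw + bin_cm / 2, bin_cm)
    y_edges = center[1] + np.arange(-hh, hh + bin_cm / 2, bin_cm)
    inside = (x >= x_edges[0]) & (x <= x_edges[-1]) & (y >= y_edges[0]) & (y <= y_edges[-1])
    if values is not None:
        v = np.asarray(values, dtype=float)
        inside = inside & ~np.isnan(v)
    n_dropped = int((~inside).sum())
    counts, _, _ = np.histogram2d(x[inside], y[inside], bins=[x_edges, y_edges])
    mean = None
    if values is not None:
        sums, _, _ = np.histogram2d(x[inside], y[inside], bins=[x_edges, y_edges],
                                    weights=np.asarray(values, dtype=float)[inside])
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(counts > 0, sums / counts, np.nan)
    return SpatialMaps(counts=counts, mean_value=mean, x_edges=x_edges,
                       y_edges=y_edges, n_dropped=n_dropped)


@dataclass
class DistanceProfile:
    bin_centers: np.ndarray
    fraction: np.ndarray       # flagged / all frames per bin (NaN where empty)
    fraction_of_total: np.ndarray  # flagged per bin / all frames in the dataset
    denominator: np.ndarray    # frames per bin (the gray background histogram)


def distance_profile(flags, distances, bin_cm: float = 1.0,
                     d_max: Optional[float] = None) -> DistanceProfile:
    """Relative frequency of flagged frames per object-distance bin.

    Returns both normalizations: per-bin (flagged / all frames in that
    bin) and relative to the size of the complete dataset.
    """
    flags = np.asarray(flags, dtype=bool)
    d = np.asarray(distances, dtype=float)
    if d_max is None:
        d_max = float(np.nanmax(d)) + bin_cm
    edges = np.arange(0.0, d_max + bin_cm / 2, bin_cm)
    denom, _ = np.histogram(d, bins=edges)
    num, _ = np.histogram(d[flags], bins=edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, num / denom, np.nan)
    return DistanceProfile(
        bin_centers=(edges[:-1] + edges[1:]) / 2.0,
        fraction=frac,
        fraction_of_total=num / max(1, len(d)),
        denominator=denom,
    )


# ---------------------------------------------------------------------------
# Spatial conditionals


def approach_filter(occurrences: Sequence[dict], distances: np.ndarray,
                    d_max: float = APPROACH_DMAX_CM, invert: bool = False) -> list[dict]:
    """Select occurrences that approach (or, inverted, depart from) the
    object: approach keeps those whose final frame lies within ``d_max``
    of the object and closer than the first frame; departure keeps those
    starting within ``d_max`` and ending farther than they started.
    Approach and departure subsets are disjoint by construction."""
    d = np.asarray(distances, dtype=float)
    out = []
    for o in occurrences:
        d0 = d[o["start"]]
        d1 = d[o["end"] - 1]
        if invert:
            keep = (d0 < d_max) and (d1 > d0)
        else:
            keep = (d1 < d_max) and (d1 < d0)
        if keep:
            out.append(o)
    return out


@dataclass
class DistanceTrace:
    bin_centers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n: np.ndarray


def distance_referenced_average(values: np.ndarray, occurrences: Sequence[dict],
                                distances: np.ndarray, bin_cm: float = 1.0,
                                d_max: Optional[float] = None) -> DistanceTrace:
    """Pool the frames of all occurrences by object distance and return
    per-bin mean, sample SD, and t-based 95% CI (SD/CI masked for bins
    with fewer than 2 frames)."""
    if len(occurrences) == 0:
        raise ValueError("no occurrences supplied")
    v = np.asarray(values, dtype=float)
    d = np.asarray(distances, dtype=float)
    idx = np.concatenate([np.arange(o["start"], o["end"]) for o in occurrences])
    vv, dd = v[idx], d[idx]
    ok = ~np.isnan(vv)
    vv, dd = vv[ok], dd[ok]
    if d_max is None:
        d_max = float(dd.max()) + bin_cm if len(dd) else bin_cm
    edges = np.arange(0.0, d_max + bin_cm / 2, bin_cm)
    which = np.digitize(dd, edges) - 1
    nb = len(edges) - 1
    mean = np.full(nb, np.nan)
    sd = np.full(nb, np.nan)
    n = np.zeros(nb, dtype=int)
    for b in range(nb):
        vals = vv[which == b]
        n[b] = len(vals)
        if n[b] >= 1:
            mean[b] = float(np.mean(vals))
        if n[b] >= 2:
            sd[b] = float(np.std(vals, ddof=1))
    half = np.full(nb, np.nan)
    good = n >= 2
    half[good] = stats.t.ppf(0.975, n[good] - 1) * sd[good] / np.sqrt(n[good])
    return DistanceTrace(bin_centers=(edges[:-1] + edges[1:]) / 2.0, mean=mean,
                         sd=sd, ci_lo=mean - half, ci_hi=mean + half, n=n)


# ---------------------------------------------------------------------------
# Post-chain transition shift


def post_chain_transitions(labels: np.ndarray, chain_ends: Sequence[int],
                           horizon: int = 10, n_perm: int = 999, seed: int = 0,
                           pm_ids: Optional[Sequence[int]] = None) -> pd.DataFrame:
    """PM frequencies in the ``horizon`` frames following chain ends,
    against a permutation null of equally many uniformly placed windows.

    Windows running past the end of the sequence are truncated. Per PM a
    two-sided empirical p-value (with add-one correction) is reported
    together with a Holm adjustment across PMs.
    """
    lab = np.asarray(labels)
    n = len(lab)
    ends = np.asarray(chain_ends, dtype=int)
    if np.any(ends < 0) or np.any(ends > n):
        raise ValueError("chain end index out of range")
    rng = np.random.default_rng(seed)
    if pm_ids is None:
        pm_ids = np.unique(lab)

    def window_freq(starts):
        votes = np.concatenate([lab[s:min(s + horizon, n)] for s in starts]) \
            if len(starts) else np.array([], dtype=lab.dtype)
        tot = max(1, len(votes))
        return np.array([(votes == pm).sum() / tot for pm in pm_ids])

    obs = window_freq(ends)
    null = np.empty((n_perm, len(pm_ids)))
    max_start = max(1, n - 1)
    for p in range(n_perm):
        starts = rng.integers(0, max_start, size=len(ends))
        null[p] = window_freq(starts)
    null_mean = null.mean(axis=0)
    dev = np.abs(obs - null_mean)
    pvals = (1 + (np.abs(null - null_mean) >= dev[None, :] - 1e-12).sum(axis=0)) / (n_perm + 1)
    p_holm = multipletests(pvals, method="holm")[1]
    return pd.DataFrame({
        "pm": pm_ids,
        "observed_freq": obs,
        "null_mean": null_mean,
        "excess": obs - null_mean,
        "p": pvals,
        "p_holm": p_holm,
    })


# ---------------------------------------------------------------------------
# Group statistics


def _dunn_posthoc(groups: dict) -> pd.DataFrame:
    """Dunn's rank-based pairwise z statistics with tie correction and
    Holm adjustment."""
    names = list(groups)
    all_vals = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    ranks = stats.rankdata(all_vals)
    N = len(all_vals)
    mean_ranks = {}
    i = 0
    for g in names:
        ng = len(groups[g])
        mean_ranks[g] = ranks[i:i + ng].mean()
        i += ng
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (N - 1))
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ga, gb = names[a], names[b]
            na, nb = len(groups[ga]), len(groups[gb])
            se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
            z = (mean_ranks[ga] - mean_ranks[gb]) / se
            rows.append({"group_a": ga, "group_b": gb, "z": z,
                         "p": 2 * stats.norm.sf(abs(z))})
    df = pd.DataFrame(rows)
    df["p_holm"] = multipletests(df["p"], method="holm")[1]
    return df


def group_compare(values: Sequence[float], group_labels: Sequence) -> dict:
    """Nonparametric group comparison.

    Two groups: two-sided Mann-Whitney rank-sum test (exact for small
    samples without ties). More: Kruskal-Wallis with tie correction,
    then Dunn pairwise z statistics with Holm adjustment. Groups with
    fewer than 2 values are excluded (logged in the report).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    groups = {}
    excluded = []
    for name in pd.unique(g):
        vals = v[g == name]
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            excluded.append(name)
        else:
            groups[name] = vals
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 values")
    report = {
        "groups": {str(k): {"n": int(len(x)), "median": float(np.median(x))}
                   for k, x in groups.items()},
        "excluded": [str(e) for e in excluded],
    }
    if len(groups) == 2:
        (a, b) = groups.values()
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        report.update({"test": "mann-whitney-u", "statistic": float(stat), "p": float(p)})
    else:
        stat, p = stats.kruskal(*groups.values())
        report.update({"test": "kruskal-wallis", "statistic": float(stat), "p": float(p)})
        report["posthoc"] = _dunn_posthoc(groups).to_dict(orient="records")
    return report
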