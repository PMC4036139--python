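"""Prototypical-movement (PM) clustering of z-scored kinematic triples.

The cluster count is chosen by a replicate-based post-hoc evaluation of
k-means partitions scanned over a range of k: a hierarchical (Ward)
pre-scan brackets plausible cluster counts, then for each k a number of
independently seeded k-means fits is scored for stability (mean pairwise
adjusted Rand index between replicate partitions) and quality (mean
silhouette on a fixed seeded subsample). The selected k is the largest k
whose stability reaches the threshold and whose quality stays within a
small slack of the running maximum — i.e. the finest partition that is
still reproducible and does not degrade cluster separation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .kinematics import ScalerParams, apply_scaler

logger = logging.getLogger(__name__)


@dataclass
class KScanResult:
    """Trace of the cluster-count scan."""

    ks: np.ndarray
    stability: np.ndarray       # mean pairwise ARI across replicates, in [~0, 1]
    quality: np.ndarray         # mean silhouette, in [-1, 1]
    selected_k: int
    eligible: np.ndarray        # per-k: passed stability & quality rule
    replicate_centroids: dict   # k -> list of (k, 3) arrays
    params: dict = field(default_factory=dict)


@dataclass
class PMModel:
    """A fitted PM catalog: centroids in z-units and raw units, the
    scaler that links them, the mirror pairing, and per-PM data share.
    PM ids are 1-based; PM 01 is the backward-thrust prototype."""

    selected_k: int
    centroids_z: np.ndarray
    centroids_raw: np.ndarray
    scaler: ScalerParams
    mirror_pairs: list  # list of (pm_i, pm_j), 1-based
    data_fraction: np.ndarray
    kscan: Optional[KScanResult] = None

    def to_json(self) -> str:
        d = {
            "selected_k": int(self.selected_k),
            "centroids_z": self.centroids_z.tolist(),
            "centroids_raw": self.centroids_raw.tolist(),
            "scaler": self.scaler.to_dict(),
            "mirror_pairs": [list(map(int, p)) for p in self.mirror_pairs],
            "data_fraction": self.data_fraction.tolist(),
        }
        if self.kscan is not None:
            d["kscan"] = {
                "ks": self.kscan.ks.tolist(),
                "stability": self.kscan.stability.tolist(),
                "quality": self.kscan.quality.tolist(),
                "selected_k": int(self.kscan.selected_k),
                "eligible": self.kscan.eligible.tolist(),
                "params": self.kscan.params,
            }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PMModel":
        d = json.loads(text)
        kscan = None
        if "kscan" in d:
            ks = d["kscan"]
            kscan = KScanResult(
                ks=np.asarray(ks["ks"]),
                stability=np.asarray(ks["stability"]),
                quality=np.asarray(ks["quality"]),
                selected_k=int(ks["selected_k"]),
                eligible=np.asarray(ks["eligible"], dtype=bool),
                replicate_centroids={},
                params=ks.get("params", {}),
            )
        return cls(
            selected_k=int(d["selected_k"]),
            centroids_z=np.asarray(d["centroids_z"], dtype=float),
            centroids_raw=np.asarray(d["centroids_raw"], dtype=float),
            scaler=ScalerParams.from_dict(d["scaler"]),
            mirror_pairs=[tuple(p) for p in d["mirror_pairs"]],
            data_fraction=np.asarray(d["data_fraction"], dtype=float),
            kscan=kscan,
        )


def hierarchical_k_range(zdata: np.ndarray, max_k: int = 50,
                         subsample: int = 5000, seed: int = 0) -> tuple[int, int]:
    """Bracket plausible cluster counts with a Ward-linkage pre-scan.

    Agglomerates a seeded subsample under the Ward criterion and returns
    the interval of cluster counts at which the relative jump in merge
    cost (height ratio between successive merges) falls in the top
    decile, i.e. where agglomeration starts fusing well-separated groups.
    """
    z = np.asarray(zdata, dtype=float)
    rng = np.random.default_rng(seed)
    if len(z) > subsample:
        z = z[rng.choice(len(z), subsample, replace=False)]
    if len(z) <= max_k:
        raise ValueError(f"subsample of {len(z)} points cannot resolve up to k={max_k}")
    Z = linkage(z, method="ward")
    h = Z[:, 2]
    n = len(z)
    ks = np.arange(2, max_k + 1)
    # merge m reduces the partition from n-m to n-m-1 clusters; the merge
    # *leaving* k clusters has index n-k-1, the one destroying them n-k.
    ratios = np.array(
        [h[n - k] / h[n - k - 1] if h[n - k - 1] > 0 else np.inf for k in ks]
    )
    cutoff = np.quantile(ratios[np.isfinite(ratios)], 0.9) if np.any(np.isfinite(ratios)) else 1.0
    cand = ks[ratios >= cutoff]
    if len(cand) == 0:
        cand = ks[[int(np.argmax(ratios))]]
    return int(cand.min()), int(cand.max())


def kmeans_fit(zdata: np.ndarray, k: int, seed: int = 0, n_init: int = 1):
    """One k-means fit (k-means++ seeding, Lloyd iterations, squared
    Euclidean distance). Returns (centroids, labels, within-cluster cost)."""
    z = np.asarray(zdata, dtype=float)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, max_iter=300,
                tol=1e-8, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(z)
    return km.cluster_centers_, labels, float(km.inertia_)


def evaluate_k_scan(zdata: np.ndarray, k_range: Sequence[int] = range(2, 51),
                    n_replicates: int = 20, seed: int = 0,
                    stability_threshold: float = 0.9, quality_slack: float = 0.05,
                    silhouette_subsample: int = 2000, n_init: int = 2) -> KScanResult:
    """Scan cluster counts and select one.

    Per k: ``n_replicates`` k-means fits with seeds derived from the
    master seed by fixed offsets (each fit keeps the better of ``n_init``
    k-means++ starts); stability is the mean adjusted Rand
    index over all replicate pairs, quality the mean silhouette of the
    replicate partitions on one seeded subsample (at most 20 000 points).
    The selected k is the largest k with stability >= threshold and
    quality within ``quality_slack`` (fractional) of the running maximum.
    """
    ks = list(k_range)
    if len(ks) == 0:
        raise ValueError("empty k_range")
    z = np.asarray(zdata, dtype=float)
    rng = np.random.default_rng(seed)
    nsub = min(len(z), min(silhouette_subsample, 20_000))
    sub_idx = rng.choice(len(z), nsub, replace=False)

    stability = np.empty(len(ks))
    quality = np.empty(len(ks))
    centroids: dict[int, list] = {}
    for a, k in enumerate(ks):
        fits = [
            kmeans_fit(z, k, seed=seed + 1000 * k + r, n_init=n_init)
            for r in range(n_replicates)
        ]
        centroids[k] = [f[0] for f in fits]
        labels = [f[1] for f in fits]
        pairs = [
            adjusted_rand_score(labels[i], labels[j])
            for i in range(n_replicates)
            for j in range(i + 1, n_replicates)
        ]
        stability[a] = float(np.mean(pairs)) if pairs else 1.0
        sils = []
        for lab in labels:
            lsub = lab[sub_idx]
            if len(np.unique(lsub)) < 2:
                sils.append(-1.0)
            else:
                sils.append(silhouette_score(z[sub_idx], lsub))
        quality[a] = float(np.mean(sils))

    eligible = np.zeros(len(ks), dtype=bool)
    run_max = -np.inf
    for a in range(len(ks)):
        run_max = max(run_max, quality[a])
        eligible[a] = (
            stability[a] >= stability_threshold
            and quality[a] >= run_max - quality_slack * abs(run_max)
        )
    if eligible.any():
        selected = int(np.asarray(ks)[eligible].max())
    else:
        # degenerate data: fall back to the best-quality k
        selected = int(ks[int(np.argmax(quality))])
        logger.warning("no k passed the stability/quality rule; falling back to k=%d", selected)
    return KScanResult(
        ks=np.asarray(ks), stability=stability, quality=quality,
        selected_k=selected, eligible=eligible, replicate_centroids=centroids,
        params={
            "n_replicates": n_replicates, "seed": seed,
            "stability_threshold": stability_threshold,
            "quality_slack": quality_slack,
            "silhouette_subsample": nsub,
        },
    )


def _canonical_order(raw: np.ndarray) -> np.ndarray:
    """Order centroids into the conventional PM numbering: the
    backward/lowest-thrust prototype first, then by increasing rotation
    amplitude, the positive-yaw member of each pair before its partner."""
    idx = np.arange(len(raw))
    first = int(np.argmin(raw[:, 0]))
    rest = np.array([i for i in idx if i != first])
    order = rest[np.lexsort((-raw[rest, 2], np.abs(raw[rest, 2])))]
    return np.concatenate([[first], order])


def find_mirror_pairs(centroids: np.ndarray, tol: float = 0.5,
                      scale: tuple[float, float] = (1.0, 1.0)) -> list[tuple[int, int]]:
    """Greedy mirror-pair matching over PM centroids.

    The score of an unordered pair is |dthrust| + |slip_i + slip_j| +
    |yaw_i + yaw_j| with the translational terms divided by ``scale[0]``
    and the yaw term by ``scale[1]`` — i.e. in z units, but mean-free
    (a z-scored sum would retain twice the scaler mean). Pairs are
    accepted best-first while the score is below ``tol``. Unpaired PMs
    (the backward and the low-rotation forward prototype on faithful
    data) remain singletons. Returned ids are 1-based.
    """
    c = np.asarray(centroids, dtype=float)
    ts, rs = scale
    k = len(c)
    scored = []
    for i in range(k):
        for j in range(i + 1, k):
            s = (
                abs(c[i, 0] - c[j, 0]) / ts
                + abs(c[i, 1] + c[j, 1]) / ts
                + abs(c[i, 2] + c[j, 2]) / rs
            )
            scored.append((s, i, j))
    scored.sort()
    used: set[int] = set()
    pairs = []
    for s, i, j in scored:
        if s >= tol:
            break
        if i in used or j in used:
            continue
        pairs.append((i + 1, j + 1))
        used.update((i, j))
    return pairs


def fit_pm_model(zdata: np.ndarray, scaler: ScalerParams, k: Optional[int] = None,
                 seed: int = 0, kscan_kwargs: Optional[dict] = None,
                 mirror_tol: float = 0.5, final_n_init: int = 10) -> PMModel:
    """Fit the PM catalog: optionally run the k-scan to choose k, then a
    final k-means fit, canonical PM ordering, and mirror-pair detection."""
    z = np.asarray(zdata, dtype=float)
    kscan = None
    if k is None:
        kscan = evaluate_k_scan(z, seed=seed, **(kscan_kwargs or {}))
        k = kscan.selected_k
    cent_z, labels, _ = kmeans_fit(z, k, seed=seed, n_init=final_n_init)
    raw = apply_scaler(scaler, cent_z, inverse=True)
    order = _canonical_order(raw)
    cent_z = cent_z[order]
    raw = raw[order]
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[labels]
    frac = np.bincount(labels, minlength=k) / len(labels)
    pairs = find_mirror_pairs(raw, tol=mirror_tol,
                              scale=(scaler.trans_sd, scaler.rot_sd))
    return PMModel(
        selected_k=k, centroids_z=cent_z, centroids_raw=raw, scaler=scaler,
        mirror_pairs=pairs, data_fraction=frac, kscan=kscan,
    )


def assign(model: PMModel, zdata: np.ndarray) -> np.ndarray:
    """Nearest-centroid PM labels (1-based) for z-scored triples.

    Deterministic; equidistant points go to the lowest PM id.
    """
    z = np.asarray(zdata, dtype=float)
    if z.ndim != 2 or z.shape[1] != model.centroids_z.shape[1]:
        raise ValueError("zdata dimensionality does not match the model centroids")
    d2 = ((z[:, None, :] - model.centroids_z[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1) + 1
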