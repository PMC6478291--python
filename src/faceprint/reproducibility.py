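"""Within-subject, across-session stability of localizer activation.

Three complementary views of test-retest reliability:

* index-run matching — peaks defined in the first session must recur at the
  same or directly surrounding voxel coordinates (Chebyshev distance <= 1
  voxel) in at least 3 of the 4 subsequent sessions;
* Ward clustering — peaks pooled over sessions are grouped by minimum-
  variance agglomerative clustering of their mm coordinates, and a cluster is
  stable when its inner variance (mean squared distance to the centroid) is
  at most 20 mm^2 and at least 4 of 5 sessions contribute;
* voxel overlap — the Dice-type coefficient R_ij = 2*V_ij/(V_i+V_j) between
  the suprathreshold masks of session pairs, averaged first over the 10
  session pairs within a subject and then across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .glm import StatMap, t_critical
from .peaks import Peak, PeakSet

__all__ = [
    "MatchParams",
    "ClusterParams",
    "OverlapResult",
    "StablePeakCluster",
    "match_to_index_run",
    "ward_cluster_peaks",
    "overlap_coefficient",
    "overlap_summary",
]


@dataclass(frozen=True)
class MatchParams:
    match_tolerance_voxels: int = 1  # Chebyshev distance
    min_subsequent_hits: int = 3  # "3 of the 4 subsequent runs"

    def __post_init__(self):
        if self.match_tolerance_voxels < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass(frozen=True)
class ClusterParams:
    max_inner_variance_mm2: float = 20.0
    min_runs_in_cluster: int = 4  # "4 out of 5 runs"

    def __post_init__(self):
        if self.max_inner_variance_mm2 <= 0 or self.min_runs_in_cluster <= 0:
            raise ValueError("cluster parameters must be positive")


@dataclass(frozen=True)
class OverlapResult:
    v_i: int
    v_j: int
    v_ij: int
    r_ij: float


@dataclass
class StablePeakCluster:
    members: list[Peak]  # at most one per run
    centroid_mm: np.ndarray
    inner_variance_mm2: float
    n_runs: int
    stable: bool


def _chebyshev(a: tuple[int, int, int], b: tuple[int, int, int]) -> int:
    return max(abs(x - y) for x, y in zip(a, b))


def match_to_index_run(
    peaksets_by_run: list[PeakSet], params: MatchParams = MatchParams()
) -> pd.DataFrame:
    """Reproducibility of first-session peaks in subsequent sessions.

    For each index-run peak, counts subsequent runs containing at least one
    peak within the voxel tolerance; a peak is reproducible when that count
    reaches ``min_subsequent_hits``.  The returned frame flags the index
    run's maximum peak per ROI so callers can report whether the strongest
    activation recurred.
    """
    if not peaksets_by_run:
        raise ValueError("empty run list")
    if len(peaksets_by_run) < 2:
        raise ValueError("need >= 2 runs")
    index_run = peaksets_by_run[0]
    later = peaksets_by_run[1:]
    rows = []
    max_by_roi = {
        roi: index_run.max_peak(roi) for roi in {p.roi for p in index_run}
    }
    for p in index_run:
        hits = sum(
            any(_chebyshev(p.ijk, q.ijk) <= params.match_tolerance_voxels for q in run)
            for run in later
        )
        rows.append(
            {
                "roi": p.roi,
                "i": p.ijk[0],
                "j": p.ijk[1],
                "k": p.ijk[2],
                "t": p.t,
                "polarity": p.polarity,
                "n_subsequent_hits": hits,
                "n_subsequent_runs": len(later),
                "reproducible": hits >= params.min_subsequent_hits,
                "is_roi_max": max_by_roi[p.roi] is p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "roi", "i", "j", "k", "t", "polarity",
            "n_subsequent_hits", "n_subsequent_runs", "reproducible", "is_roi_max",
        ],
    )


def _inner_variance(coords: np.ndarray) -> float:
    centroid = coords.mean(axis=0)
    return float(np.mean(np.sum((coords - centroid) ** 2, axis=1)))


def cut_by_inner_variance(coords: np.ndarray, max_var: float) -> np.ndarray:
    """Coarsest cut of the Ward tree in which every cluster's inner variance
    (mean squared distance to centroid, mm^2) is within the bound.

    Returns integer cluster labels.  Falls back to singletons, which always
    satisfy the bound.
    """
    n = len(coords)
    if n == 1:
        return np.array([1])
    Z = linkage(coords, method="ward")
    for k in range(1, n + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        ok = all(
            _inner_variance(coords[labels == lab]) <= max_var + 1e-12
            for lab in np.unique(labels)
        )
        if ok:
            return labels
    return np.arange(1, n + 1)


def ward_cluster_peaks(
    peaksets_by_run: list[PeakSet], params: ClusterParams = ClusterParams()
) -> list[StablePeakCluster]:
    """Group peaks pooled over runs by Ward clustering of mm coordinates.

    The dendrogram is cut at the coarsest partition whose clusters all have
    inner variance <= ``max_inner_variance_mm2``.  Within a cluster, a run
    contributing several peaks counts once, through the member nearest the
    raw cluster centroid; the reported centroid and variance are recomputed
    on those per-run representatives.
    """
    pooled: list[tuple[Peak, int]] = [
        (p, r) for r, ps in enumerate(peaksets_by_run) for p in ps
    ]
    if not pooled:
        return []
    coords = np.array([p.xyz_mm for p, _ in pooled])
    labels = cut_by_inner_variance(coords, params.max_inner_variance_mm2)
    clusters = []
    for lab in np.unique(labels):
        members_all = [pooled[i] for i in np.flatnonzero(labels == lab)]
        raw_coords = np.array([p.xyz_mm for p, _ in members_all])
        raw_centroid = raw_coords.mean(axis=0)
        best_by_run: dict[int, tuple[Peak, float]] = {}
        for (p, r), c in zip(members_all, raw_coords):
            d = float(np.sum((c - raw_centroid) ** 2))
            if r not in best_by_run or d < best_by_run[r][1]:
                best_by_run[r] = (p, d)
        members = [p for p, _ in best_by_run.values()]
        coords_kept = np.array([p.xyz_mm for p in members])
        var = _inner_variance(coords_kept)
        n_runs = len(best_by_run)
        clusters.append(
            StablePeakCluster(
                members=members,
                centroid_mm=coords_kept.mean(axis=0),
                inner_variance_mm2=var,
                n_runs=n_runs,
                stable=(
                    var <= params.max_inner_variance_mm2 + 1e-12
                    and n_runs >= params.min_runs_in_cluster
                ),
            )
        )
    clusters.sort(key=lambda c: -c.n_runs)
    return clusters


def overlap_coefficient(mask_i: np.ndarray, mask_j: np.ndarray) -> OverlapResult:
    """R_ij = 2*V_ij/(V_i+V_j); 0 when both masks are empty."""
    if mask_i.shape != mask_j.shape:
        raise ValueError("masks are on different grids")
    v_i = int(np.count_nonzero(mask_i))
    v_j = int(np.count_nonzero(mask_j))
    v_ij = int(np.count_nonzero(mask_i & mask_j))
    r = 2.0 * v_ij / (v_i + v_j) if (v_i + v_j) > 0 else 0.0
    return OverlapResult(v_i, v_j, v_ij, r)


def overlap_summary(
    conjunction_maps_by_subject: dict[str, list[StatMap]],
    roi_mask: np.ndarray,
    thresholds_p: tuple[float, ...] = (0.001, 0.01, 0.05),
) -> pd.DataFrame:
    """Across-session voxel overlap within one ROI, per voxelwise threshold.

    For each subject and uncorrected one-sided threshold p, the suprathreshold
    conjunction masks of all session pairs (10 pairs for 5 sessions) are
    compared with ``overlap_coefficient`` and averaged; subject means are then
    averaged across subjects.  Subjects without a single activated in-ROI
    voxel in any session are excluded, and the included n is reported.
    """
    rows = []
    for p_thr in thresholds_p:
        subject_means = []
        for sub, maps in conjunction_maps_by_subject.items():
            if len(maps) < 2:
                raise ValueError(f"subject {sub} has fewer than 2 sessions")
            masks = [
                (m.values > t_critical(m.df, p_thr)) & roi_mask for m in maps
            ]
            if not any(m.any() for m in masks):
                continue  # excluded: no activated voxel in any session
            pair_rs = [
                overlap_coefficient(masks[i], masks[j]).r_ij
                for i, j in combinations(range(len(masks)), 2)
            ]
            subject_means.append(np.mean(pair_rs))
        subject_means = np.asarray(subject_means)
        n_inc = len(subject_means)
        n_pairs = len(list(combinations(range(len(next(iter(conjunction_maps_by_subject.values())))), 2)))
        rows.append(
            {
                "p_threshold": p_thr,
                "overlap_pct": 100.0 * subject_means.mean() if n_inc else np.nan,
                "sem_pct": (
                    100.0 * subject_means.std(ddof=1) / np.sqrt(n_inc)
                    if n_inc > 1
                    else np.nan
                ),
                "n_included": n_inc,
                "n_pairs_per_subject": n_pairs,
            }
        )
    return pd.DataFrame(rows)
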