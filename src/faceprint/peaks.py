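"""ROI-restricted local-maximum detection on statistic maps.

A peak is a voxel inside a named ROI whose statistic reaches the threshold
(default T >= 1.65, one-sided p < 0.05 uncorrected for large df) and strictly
exceeds each of its 26 neighbors in the surrounding 3x3x3 cube.  Neighbors
outside the ROI but inside the volume still take part in the comparison, so
ROI borders cannot manufacture spurious peaks; neighbors outside the volume
are ignored.  Exact ties disqualify a peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .glm import StatMap, t_critical
from .synth import ROIAtlas, nib_affines_apply

__all__ = [
    "PeakDetectionParams",
    "Peak",
    "PeakSet",
    "detect_peaks",
    "classify_polarity",
    "peak_count_table",
    "activated_fraction_test",
]


@dataclass(frozen=True)
class PeakDetectionParams:
    t_min: float = 1.65

    def __post_init__(self):
        if not np.isfinite(self.t_min):
            raise ValueError("t_min must be finite")


@dataclass(frozen=True)
class Peak:
    ijk: tuple[int, int, int]
    xyz_mm: tuple[float, float, float]
    t: float
    roi: str
    polarity: str = ""  # activation | deactivation | ""
    run_id: str = ""


@dataclass
class PeakSet:
    """Peaks of one (run, map) pair, sorted by descending statistic."""

    peaks: list[Peak]
    run_id: str = ""

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def in_roi(self, roi: str) -> list[Peak]:
        return [p for p in self.peaks if p.roi == roi]

    def max_peak(self, roi: str | None = None) -> Peak | None:
        cand = self.peaks if roi is None else self.in_roi(roi)
        return cand[0] if cand else None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "run": p.run_id,
                "roi": p.roi,
                "i": p.ijk[0],
                "j": p.ijk[1],
                "k": p.ijk[2],
                "x_mm": p.xyz_mm[0],
                "y_mm": p.xyz_mm[1],
                "z_mm": p.xyz_mm[2],
                "t": p.t,
                "polarity": p.polarity,
            }
            for p in self.peaks
        ]
        cols = ["run", "roi", "i", "j", "k", "x_mm", "y_mm", "z_mm", "t", "polarity"]
        return pd.DataFrame(rows, columns=cols)


_CUBE26 = np.ones((3, 3, 3), dtype=bool)
_CUBE26[1, 1, 1] = False


def detect_peaks(
    tmap: StatMap,
    atlas: ROIAtlas,
    params: PeakDetectionParams = PeakDetectionParams(),
    run_id: str = "",
    polarity_map: StatMap | None = None,
) -> PeakSet:
    """All suprathreshold 26-neighborhood local maxima inside named ROIs."""
    vals = tmap.values
    if vals.shape != atlas.shape:
        raise ValueError("statistic map and atlas grids differ")
    # neighbor max with out-of-volume treated as -inf (ignored)
    neigh_max = ndimage.maximum_filter(
        vals, footprint=_CUBE26, mode="constant", cval=-np.inf
    )
    is_peak = (vals >= params.t_min) & (vals > neigh_max) & (atlas.labels > 0)
    idx = np.argwhere(is_peak)
    peaks = []
    for ijk in idx:
        lab = int(atlas.labels[tuple(ijk)])
        xyz = nib_affines_apply(atlas.affine, ijk[None, :])[0]
        pol = ""
        if polarity_map is not None:
            pol = classify_polarity_value(float(polarity_map.values[tuple(ijk)]))
        peaks.append(
            Peak(
                ijk=tuple(int(v) for v in ijk),
                xyz_mm=tuple(float(v) for v in xyz),
                t=float(vals[tuple(ijk)]),
                roi=atlas.rois[lab].name,
                polarity=pol,
                run_id=run_id,
            )
        )
    peaks.sort(key=lambda p: -p.t)
    return PeakSet(peaks, run_id=run_id)


def classify_polarity_value(value: float) -> str:
    """Positive faces-vs-baseline -> activation; zero or negative ->
    deactivation (the zero case is an arbitrary documented convention)."""
    return "activation" if value > 0 else "deactivation"


def classify_polarity(peak: Peak, polarity_map: StatMap) -> str:
    return classify_polarity_value(float(polarity_map.values[peak.ijk]))


def peak_count_table(cohort_peaksets: dict[str, PeakSet], rois: list[str]) -> pd.DataFrame:
    """Percentage of subjects with 0, 1, 2, 3, >=4 peaks per ROI.

    ``cohort_peaksets`` maps subject id -> that subject's PeakSet (one run
    per subject, as in a single-session group).  Rows sum to 100%.
    """
    if not cohort_peaksets:
        raise ValueError("need >= 1 subject")
    n = len(cohort_peaksets)
    bins = ["0", "1", "2", "3", ">=4"]
    rows = {}
    for roi in rois:
        counts = np.zeros(5)
        for ps in cohort_peaksets.values():
            k = min(len(ps.in_roi(roi)), 4)
            counts[k] += 1
        rows[roi] = 100.0 * counts / n
    return pd.DataFrame(rows, index=bins).T


def activated_fraction_test(
    individual_maps: list[StatMap],
    mask: np.ndarray,
    voxel_volume_mm3: float,
    alpha_voxel: float = 0.05,
) -> tuple[float, float, float]:
    """Does the suprathreshold volume exceed what chance alone would give?

    Per subject, counts in-mask voxels exceeding the one-sided uncorrected
    critical t for ``alpha_voxel``; the per-subject suprathreshold fractions
    are then tested against ``alpha_voxel`` with a one-sided one-sample
    t-test.  Returns (mean volume mm^3, SEM mm^3, p).
    """
    if len(individual_maps) < 2:
        raise ValueError("need >= 2 subjects")
    if not mask.any():
        raise ValueError("empty mask")
    n_mask = int(mask.sum())
    fractions = []
    volumes = []
    for m in individual_maps:
        thr = t_critical(m.df, alpha_voxel)
        k = int((m.values[mask] > thr).sum())
        fractions.append(k / n_mask)
        volumes.append(k * voxel_volume_mm3)
    volumes = np.asarray(volumes, dtype=float)
    fr = np.asarray(fractions)
    if fr.std(ddof=1) == 0:  # degenerate: no spread, decide by the mean alone
        p = 0.0 if fr.mean() > alpha_voxel else 1.0
    else:
        p = float(stats.ttest_1samp(fr, alpha_voxel, alternative="greater").pvalue)
    sem = float(volumes.std(ddof=1) / np.sqrt(len(volumes)))
    return float(volumes.mean()), sem, p
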