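"""First- and second-level GLM for block-design localizer runs.

Design matrices carry one HRF-convolved boxcar regressor per stimulus
category, a discrete-cosine drift basis realizing a 1/128 Hz high-pass
filter, and a constant.  Fitting whitens data and design with a fixed
first-order autoregressive coefficient (default 0.2) and then solves
ordinary least squares per voxel, so serial correlations are handled the
way standard localizer analyses handle them: one global AR(1) model, not
voxelwise estimation.

Contrast t maps, the minimum-statistic conjunction (significant only if
every constituent contrast is), a faces-versus-baseline polarity map,
Gaussian spatial smoothing, and second-level one-sample t tests complete
the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .synth import StimulusSchedule

__all__ = [
    "GLMOptions",
    "DesignMatrix",
    "GLMFit",
    "StatMap",
    "SmoothingParams",
    "build_design_matrix",
    "fit_glm",
    "contrast_tmap",
    "contrast_weights",
    "conjunction_min_t",
    "polarity_reference",
    "smooth_volume",
    "smooth_series",
    "group_ttest",
    "bonferroni_threshold",
    "roi_condition_means",
    "t_critical",
]

_CONTRAST_SHORTHAND = {"f": "faces", "h": "houses", "o": "objects", "l": "landscapes"}


@dataclass(frozen=True)
class GLMOptions:
    """Error model and HRF parameters.

    The HRF is the canonical double-gamma (peak delay 6 s, undershoot delay
    16 s, unit dispersions, peak:undershoot ratio 6, 32 s support), evaluated
    by nilearn's ``spm_hrf`` and rescaled to unit time-integral so a sustained
    block response plateaus at 1 and betas are in the units of the simulated
    signal amplitude.
    """

    ar_coefficient: float = 0.2
    hp_cutoff_hz: float = 1.0 / 128.0
    hrf_time_length_s: float = 32.0
    conv_dt_s: float = 0.05

    def __post_init__(self):
        if not abs(self.ar_coefficient) < 1:
            raise ValueError("|ar_coefficient| must be < 1")


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_volumes, n_regressors)
    names: list[str]
    tr_s: float
    hp_cutoff_hz: float
    frame_times: np.ndarray

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def condition_names(self) -> list[str]:
        return [n for n in self.names if not n.startswith("drift_") and n != "constant"]


@dataclass
class GLMFit:
    betas: dict[str, np.ndarray]  # regressor name -> 3D volume
    residual_variance: np.ndarray  # 3D
    df: int
    design: DesignMatrix
    affine: np.ndarray
    xtx_inv: np.ndarray  # (X_w' X_w)^{-1} on the whitened design


@dataclass
class StatMap:
    """Scalar 3D statistic volume on a voxel grid with a world affine."""

    values: np.ndarray
    kind: str  # beta | contrast | t | min_t
    df: int | None
    affine: np.ndarray
    name: str = ""

    def __post_init__(self):
        if self.kind in ("t", "min_t") and (self.df is None or self.df <= 0):
            raise ValueError("t maps require df > 0")


@dataclass(frozen=True)
class SmoothingParams:
    fwhm_mm: float = 8.0

    def __post_init__(self):
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")


def _spm_hrf(dt: float, time_length: float) -> np.ndarray:
    from nilearn.glm.first_level import spm_hrf

    h = spm_hrf(dt, oversampling=1, time_length=time_length)
    # unit time-integral: a sustained block response plateaus at 1, so betas
    # carry the units of the simulated signal amplitude
    return h / (h.sum() * dt)


def _dct_drift(n: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Cosine drift columns with frequency k/(2*T) below the cutoff, k >= 1."""
    T = n * tr
    k_max = int(np.floor(2.0 * T * cutoff_hz))
    if 2.0 * T * cutoff_hz == k_max:  # strict inequality: f < cutoff
        k_max -= 1
    i = np.arange(n)
    cols = [np.cos(np.pi * k * (2 * i + 1) / (2.0 * n)) for k in range(1, k_max + 1)]
    return np.column_stack(cols) if cols else np.empty((n, 0))


def build_design_matrix(
    schedule: StimulusSchedule,
    tr_s: float,
    n_volumes: int,
    options: GLMOptions = GLMOptions(),
    drift: bool = True,
    start_time_s: float = 0.0,
) -> DesignMatrix:
    """Boxcar-convolve the schedule with the canonical HRF on a fine grid
    (``options.conv_dt_s``), sample at the volume acquisition times, and
    append the drift basis and a constant.

    ``start_time_s`` shifts the acquisition grid, e.g. when initial volumes
    were discarded before fitting.
    """
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    frame_times = start_time_s + np.arange(n_volumes) * tr_s
    scan_end = frame_times[-1] + tr_s
    if schedule.blocks and schedule.total_duration_s > scan_end + 1e-9:
        raise ValueError(
            f"schedule ends at {schedule.total_duration_s:.1f}s but the scan "
            f"covers only {scan_end:.1f}s"
        )
    dt = options.conv_dt_s
    hrf = _spm_hrf(dt, options.hrf_time_length_s)
    t_fine = np.arange(0.0, schedule.total_duration_s + options.hrf_time_length_s + dt, dt)
    cols = []
    for cond in schedule.conditions:
        box = np.zeros_like(t_fine)
        for b in schedule.blocks:
            if b.condition == cond:
                box[(t_fine >= b.onset_s) & (t_fine < b.onset_s + b.duration_s)] = 1.0
        reg = np.convolve(box, hrf)[: len(t_fine)] * dt
        cols.append(np.interp(frame_times, t_fine, reg, left=0.0, right=0.0))
    names = list(schedule.conditions)
    X = np.column_stack(cols) if cols else np.empty((n_volumes, 0))
    if drift:
        D = _dct_drift(n_volumes, tr_s, options.hp_cutoff_hz)
        X = np.column_stack([X, D]) if D.size else X
        names += [f"drift_{k}" for k in range(1, D.shape[1] + 1)]
        X = np.column_stack([X, np.ones(n_volumes)])
        names.append("constant")
    return DesignMatrix(X, names, tr_s, options.hp_cutoff_hz, frame_times)


def _whiten(arr: np.ndarray, rho: float) -> np.ndarray:
    """Exact AR(1) whitening transform along axis 0 (Prais-Winsten)."""
    out = np.empty_like(arr, dtype=float)
    out[0] = np.sqrt(1.0 - rho**2) * arr[0]
    out[1:] = arr[1:] - rho * arr[:-1]
    return out


def fit_glm(
    series: np.ndarray,
    design: DesignMatrix,
    options: GLMOptions = GLMOptions(),
    affine: np.ndarray | None = None,
) -> GLMFit:
    """AR(1)-whitened ordinary least squares per voxel.

    ``series`` is a 4D (x, y, z, t) volume or a (t, n_voxels) matrix.  Both
    data and design are transformed with the fixed-coefficient whitening
    matrix, after which OLS is exact generalized least squares under the
    assumed error covariance.
    """
    if series.ndim == 4:
        grid_shape = series.shape[:3]
        Y = series.reshape(-1, series.shape[3]).T.astype(float)
    elif series.ndim == 2:
        grid_shape = (series.shape[1], 1, 1)
        Y = series.astype(float)
    else:
        raise ValueError("series must be 4D (x,y,z,t) or 2D (t,voxels)")
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("series time length must equal design rows")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # report which columns are linearly dependent on earlier ones
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(design.names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    rho = options.ar_coefficient
    Xw = _whiten(X, rho)
    Yw = _whiten(Y, rho)
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    B = xtx_inv @ (Xw.T @ Yw)  # (p, V)
    resid = Yw - Xw @ B
    df = int(X.shape[0] - rank)
    sigma2 = np.einsum("tv,tv->v", resid, resid) / df

    betas = {
        name: B[i].reshape(grid_shape) for i, name in enumerate(design.names)
    }
    if affine is None:
        affine = np.eye(4)
    return GLMFit(betas, sigma2.reshape(grid_shape), df, design, affine, xtx_inv)


def contrast_weights(contrast: str | np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Expand shorthand like ``"f>h"`` or ``"f"`` into a full weight vector."""
    if not isinstance(contrast, str):
        c = np.asarray(contrast, dtype=float)
        if c.shape != (len(design.names),):
            raise ValueError("weight vector length must equal n_regressors")
        return c
    c = np.zeros(len(design.names))
    if ">" in contrast:
        pos, neg = contrast.split(">")
        c[design.names.index(_CONTRAST_SHORTHAND.get(pos.strip(), pos.strip()))] = 1.0
        c[design.names.index(_CONTRAST_SHORTHAND.get(neg.strip(), neg.strip()))] = -1.0
    else:
        c[design.names.index(_CONTRAST_SHORTHAND.get(contrast.strip(), contrast.strip()))] = 1.0
    return c


def contrast_tmap(fit: GLMFit, weights: str | np.ndarray, name: str = "") -> StatMap:
    """t = c'b / sqrt(s2 * c'(Xw'Xw)^-1 c), df = error df of the fit."""
    c = contrast_weights(weights, fit.design)
    if not np.any(c):
        raise ValueError("all-zero contrast weights")
    effect = sum(c[i] * fit.betas[n] for i, n in enumerate(fit.design.names) if c[i] != 0.0)
    var_scale = float(c @ fit.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(fit.residual_variance * var_scale)
    t = np.nan_to_num(t, nan=0.0)
    label = name or (weights if isinstance(weights, str) else "contrast")
    return StatMap(t, "t", fit.df, fit.affine.copy(), name=label)


def conjunction_min_t(maps: list[StatMap]) -> StatMap:
    """Voxelwise minimum statistic; under the conjunction null the result is
    significant at level alpha only where every input exceeds the
    single-contrast critical value."""
    if not maps:
        raise ValueError("need at least one map")
    shape = maps[0].values.shape
    df = maps[0].df
    for m in maps[1:]:
        if m.values.shape != shape:
            raise ValueError("grid mismatch between conjunction inputs")
        if m.df != df:
            raise ValueError("df mismatch between conjunction inputs")
    vals = np.minimum.reduce([m.values for m in maps])
    return StatMap(vals, "min_t", df, maps[0].affine.copy(), name="conjunction")


def polarity_reference(fit: GLMFit) -> StatMap:
    """Faces-versus-implicit-baseline t map, used to tell whether a
    face-selective response is an activation or a weaker deactivation."""
    if "faces" not in fit.design.names:
        raise ValueError("design has no 'faces' regressor")
    return contrast_tmap(fit, "f", name="faces_vs_baseline")


def _check_affine_no_shear(affine: np.ndarray):
    lin = affine[:3, :3]
    if np.any(np.abs(lin - np.diag(np.diag(lin))) > 1e-9):
        raise ValueError("smoothing supports only shear-free, axis-aligned affines")


def smooth_volume(
    volume: np.ndarray | StatMap,
    params: SmoothingParams = SmoothingParams(),
    affine: np.ndarray | None = None,
) -> np.ndarray | StatMap:
    """Separable Gaussian smoothing, sigma = FWHM/(2*sqrt(2 ln 2)) per axis
    in mm converted to voxels via the affine; the kernel is renormalized at
    volume edges so constant volumes stay constant."""
    if isinstance(volume, StatMap):
        out = smooth_volume(volume.values, params, volume.affine)
        return StatMap(out, volume.kind, volume.df, volume.affine.copy(), volume.name)
    if affine is None:
        affine = np.eye(4)
    _check_affine_no_shear(affine)
    if params.fwhm_mm == 0:
        return volume.astype(float).copy()
    vox_mm = np.abs(np.diag(affine)[:3])
    sigma_vox = (params.fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / vox_mm
    sm = ndimage.gaussian_filter(volume.astype(float), sigma_vox, mode="constant", cval=0.0)
    norm = ndimage.gaussian_filter(np.ones(volume.shape), sigma_vox, mode="constant", cval=0.0)
    return sm / norm


def smooth_series(series: np.ndarray, params: SmoothingParams, affine: np.ndarray) -> np.ndarray:
    """Smooth each volume of a 4D (x, y, z, t) series spatially."""
    _check_affine_no_shear(affine)
    if params.fwhm_mm == 0:
        return series.copy()
    vox_mm = np.abs(np.diag(affine)[:3])
    sigma_vox = (params.fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / vox_mm
    norm = ndimage.gaussian_filter(np.ones(series.shape[:3]), sigma_vox, mode="constant", cval=0.0)
    out = np.empty_like(series, dtype=np.float32)
    for t in range(series.shape[3]):
        out[..., t] = (
            ndimage.gaussian_filter(series[..., t].astype(float), sigma_vox, mode="constant")
            / norm
        )
    return out


def group_ttest(contrast_maps: list[StatMap]) -> StatMap:
    """Second-level random-effects one-sample t across subjects (df = n-1).

    Voxels with zero between-subject variance and a nonzero mean yield
    +/-inf with a warning rather than an error."""
    if len(contrast_maps) < 2:
        raise ValueError("group test needs >= 2 subjects")
    shape = contrast_maps[0].values.shape
    for m in contrast_maps[1:]:
        if m.values.shape != shape:
            raise ValueError("grid mismatch between subject maps")
    data = np.stack([m.values for m in contrast_maps])
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    if np.any(np.isinf(t)):
        warnings.warn("zero-variance voxels produced infinite group t values")
    t = np.where(np.isnan(t), 0.0, t)
    return StatMap(t, "t", n - 1, contrast_maps[0].affine.copy(), name="group")


def t_critical(df: int, p: float, two_sided: bool = False) -> float:
    """Critical t value for an uncorrected voxelwise threshold."""
    q = 1.0 - p / 2.0 if two_sided else 1.0 - p
    return float(stats.t.ppf(q, df))


def bonferroni_threshold(df: int, n_voxels: int, alpha: float = 0.05) -> float:
    """Family-wise-error height threshold via Bonferroni over in-mask voxels."""
    return t_critical(df, alpha / n_voxels)


def roi_condition_means(fit: GLMFit, mask: np.ndarray) -> dict[str, float]:
    """Mean beta per condition over the mask voxels."""
    if not mask.any():
        raise ValueError("empty ROI mask")
    return {
        cond: float(fit.betas[cond][mask].mean())
        for cond in fit.design.condition_names()
    }


def cohort_roi_means(fits: list[GLMFit], mask: np.ndarray):
    """Across-subject mean +/- SEM of the per-subject ROI condition means."""
    import pandas as pd

    per_sub = pd.DataFrame([roi_condition_means(f, mask) for f in fits])
    return pd.DataFrame(
        {
            "mean": per_sub.mean(),
            "sem": per_sub.sem(ddof=1) if len(per_sub) > 1 else np.nan,
        }
    )
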