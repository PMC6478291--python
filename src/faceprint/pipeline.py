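"""End-to-end orchestration: simulate -> GLM -> peaks -> reproducibility ->
fingerprinting, with CSV/JSON report emission.

Each stage is a plain function over in-memory objects so the pipeline can be
driven from Python (see ``examples/``) or from the thin CLI.  A single master
seed deterministically derives all stage seeds, so reruns are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .fingerprint import (
    FeatureSpec,
    binomial_cutoff,
    extract_features,
    hyperplane_protocol,
    svm_identify_loo,
)
from .glm import (
    GLMFit,
    GLMOptions,
    SmoothingParams,
    StatMap,
    build_design_matrix,
    conjunction_min_t,
    contrast_tmap,
    fit_glm,
    polarity_reference,
    smooth_series,
)
from .peaks import PeakDetectionParams, PeakSet, detect_peaks, peak_count_table
from .reproducibility import (
    ClusterParams,
    MatchParams,
    match_to_index_run,
    overlap_summary,
    ward_cluster_peaks,
)
from .synth import (
    Acquisition,
    CohortDataset,
    NoiseParams,
    SessionRealization,
    simulate_cohort,
)

CONTRAST_NAMES = ("f>h", "f>o", "f>l")

__all__ = [
    "PipelineConfig",
    "cmd_simulate",
    "run_glm_for_session",
    "cmd_glm",
    "cmd_report",
    "glm_maps_for_cohort",
]


@dataclass
class PipelineConfig:
    data_root: str = "data"
    output_root: str = "out"
    layout: str = "5x5"
    n_subjects: int | None = None
    sessions_per_subject: int | None = None
    tr_s: float = 1.7
    n_volumes: int = 336
    discard_initial: int = 5
    schedule: dict = field(default_factory=dict)
    ar_coefficient: float = 0.2
    white_sd: float = 1.0
    amplitude_jitter_sd: float = 0.1
    hp_cutoff_hz: float = 1.0 / 128.0
    smoothing_fwhm_mm: float = 8.0
    t_min: float = 1.65
    match_tolerance_voxels: int = 1
    min_subsequent_hits: int = 3
    max_inner_variance_mm2: float = 20.0
    min_runs_in_cluster: int = 4
    alpha: float = 0.05
    feature_rois: tuple[str, ...] = ("FFA_L", "FFA_R")
    feature_mode: str = "voxelwise"
    seed: int = 0

    def __post_init__(self):
        Acquisition(self.tr_s, self.n_volumes, self.discard_initial)
        NoiseParams(self.ar_coefficient, self.white_sd, self.amplitude_jitter_sd)
        SmoothingParams(self.smoothing_fwhm_mm)
        PeakDetectionParams(self.t_min)
        MatchParams(self.match_tolerance_voxels, self.min_subsequent_hits)
        ClusterParams(self.max_inner_variance_mm2, self.min_runs_in_cluster)
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @property
    def acquisition(self) -> Acquisition:
        return Acquisition(self.tr_s, self.n_volumes, self.discard_initial)

    @property
    def noise(self) -> NoiseParams:
        return NoiseParams(self.ar_coefficient, self.white_sd, self.amplitude_jitter_sd)

    @property
    def glm_options(self) -> GLMOptions:
        return GLMOptions(ar_coefficient=self.ar_coefficient, hp_cutoff_hz=self.hp_cutoff_hz)

    def schedule_kwargs(self) -> dict:
        kw = dict(self.schedule)
        # stimuli start after the discarded equilibration volumes by default
        kw.setdefault("start_s", self.discard_initial * self.tr_s)
        return kw

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "feature_rois" in data:
            data["feature_rois"] = tuple(data["feature_rois"])
        return cls(**data)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def cmd_simulate(config: PipelineConfig, write: bool = True) -> CohortDataset:
    """Simulate the configured cohort and (optionally) write it to disk."""
    out = Path(config.data_root) if write else None
    return simulate_cohort(
        layout=config.layout,
        n_subjects=config.n_subjects,
        sessions_per_subject=config.sessions_per_subject,
        schedule_kwargs=config.schedule_kwargs(),
        acquisition=config.acquisition,
        noise_params=config.noise,
        master_seed=config.seed,
        out_dir=out,
    )


def run_glm_for_session(
    sess: SessionRealization,
    options: GLMOptions,
    smoothing: SmoothingParams | None = None,
    discard_initial: int | None = None,
) -> tuple[GLMFit, dict[str, StatMap]]:
    """Fit one run and compute the three face contrasts, their conjunction,
    and the faces-vs-baseline polarity map.

    The first ``discard_initial`` volumes are dropped before fitting and the
    acquisition-time grid shifted accordingly (T1-equilibration convention).
    """
    discard = sess.acquisition.discard_initial if discard_initial is None else discard_initial
    series = sess.series
    if smoothing is not None and smoothing.fwhm_mm > 0:
        series = smooth_series(series, smoothing, sess.affine)
    series = series[..., discard:]
    n_vol = series.shape[3]
    design = build_design_matrix(
        sess.schedule,
        sess.acquisition.tr_s,
        n_vol,
        options,
        start_time_s=discard * sess.acquisition.tr_s,
    )
    fit = fit_glm(series, design, options, affine=sess.affine)
    maps = {c: contrast_tmap(fit, c) for c in CONTRAST_NAMES}
    maps["conjunction"] = conjunction_min_t([maps[c] for c in CONTRAST_NAMES])
    maps["faces_vs_baseline"] = polarity_reference(fit)
    return fit, maps


def glm_maps_for_cohort(
    cohort: CohortDataset,
    config: PipelineConfig,
    smoothed: bool = False,
) -> dict[tuple[str, int], dict[str, StatMap]]:
    """Contrast/conjunction maps for every run, keyed by (subject, session)."""
    smoothing = SmoothingParams(config.smoothing_fwhm_mm) if smoothed else None
    out = {}
    for sess in cohort.sessions:
        _, maps = run_glm_for_session(sess, config.glm_options, smoothing)
        out[(sess.subject_id, sess.session_index)] = maps
    return out


def cmd_glm(config: PipelineConfig, smoothed: bool = False) -> Path:
    """Load the simulated cohort from disk, fit every run, write StatMaps."""
    data_dir = Path(config.data_root)
    manifest = fio.read_manifest(data_dir)
    out_dir = Path(config.output_root) / ("glm_smoothed" if smoothed else "glm")
    out_dir.mkdir(parents=True, exist_ok=True)
    smoothing = SmoothingParams(config.smoothing_fwhm_mm) if smoothed else None
    for _, row in manifest.iterrows():
        sess = fio.read_session(data_dir, row)
        _, maps = run_glm_for_session(sess, config.glm_options, smoothing)
        stem = f"{row['subject']}_ses-{row['session']}"
        for cname, smap in maps.items():
            safe = cname.replace(">", "_gt_")
            fio.write_statmap(smap, out_dir / f"{stem}_{safe}.nii")
    return out_dir


def _load_cohort_maps(config: PipelineConfig, smoothed: bool = False):
    data_dir = Path(config.data_root)
    out_dir = Path(config.output_root) / ("glm_smoothed" if smoothed else "glm")
    if not out_dir.exists():
        raise FileNotFoundError(
            f"GLM outputs not found under {out_dir}; run the glm stage first"
        )
    manifest = fio.read_manifest(data_dir)
    maps = {}
    for _, row in manifest.iterrows():
        stem = f"{row['subject']}_ses-{row['session']}"
        maps[(row["subject"], int(row["session"]))] = {
            c: fio.read_statmap(out_dir / f"{stem}_{c.replace('>', '_gt_')}.nii")
            for c in (*CONTRAST_NAMES, "conjunction", "faces_vs_baseline")
        }
    atlas = fio.read_atlas(data_dir / "atlas.nii")
    return manifest, maps, atlas


def peaksets_by_subject(
    maps, atlas, params: PeakDetectionParams
) -> dict[str, dict[int, PeakSet]]:
    out: dict[str, dict[int, PeakSet]] = {}
    for (sub, ses), m in maps.items():
        ps = detect_peaks(
            m["conjunction"], atlas, params,
            run_id=f"{sub}_ses-{ses}", polarity_map=m["faces_vs_baseline"],
        )
        out.setdefault(sub, {})[ses] = ps
    return out


def cmd_report(config: PipelineConfig, stage: str) -> dict:
    """Emit the stage's tables (CSV) and a JSON summary; returns the summary."""
    out_root = Path(config.output_root)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest, maps, atlas = _load_cohort_maps(config, smoothed=False)
    pparams = PeakDetectionParams(config.t_min)
    by_subject = peaksets_by_subject(maps, atlas, pparams)
    rois = atlas.names()
    summary: dict = {"stage": stage, "seed": config.seed}

    if stage == "peaks":
        first = {sub: runs[min(runs)] for sub, runs in by_subject.items()}
        table = peak_count_table(first, rois)
        table.to_csv(out_root / "peak_counts.csv")
        pd.concat([ps.to_frame() for runs in by_subject.values() for ps in runs.values()]).to_csv(
            out_root / "peaks.csv", index=False
        )
        summary["n_subjects"] = len(first)
    elif stage == "reproducibility":
        mparams = MatchParams(config.match_tolerance_voxels, config.min_subsequent_hits)
        cparams = ClusterParams(config.max_inner_variance_mm2, config.min_runs_in_cluster)
        match_rows = []
        cluster_rows = []
        overlap_frames = []
        for sub, runs in by_subject.items():
            ordered = [runs[k] for k in sorted(runs)]
            if len(ordered) < 2:
                continue
            rep = match_to_index_run(ordered, mparams)
            rep.insert(0, "subject", sub)
            match_rows.append(rep)
            for roi in rois:
                roi_sets = [PeakSet(ps.in_roi(roi), ps.run_id) for ps in ordered]
                for cl in ward_cluster_peaks(roi_sets, cparams):
                    cluster_rows.append(
                        {
                            "subject": sub,
                            "roi": roi,
                            "n_runs": cl.n_runs,
                            "inner_variance_mm2": cl.inner_variance_mm2,
                            "stable": cl.stable,
                            "x_mm": cl.centroid_mm[0],
                            "y_mm": cl.centroid_mm[1],
                            "z_mm": cl.centroid_mm[2],
                        }
                    )
        conj_by_sub = {
            sub: [maps[(sub, ses)]["conjunction"] for ses in sorted(runs)]
            for sub, runs in by_subject.items()
            if len(runs) >= 2
        }
        for roi in rois:
            tab = overlap_summary(conj_by_sub, atlas.mask(roi))
            tab.insert(0, "roi", roi)
            overlap_frames.append(tab)
        match_df = (
            pd.concat(match_rows, ignore_index=True) if match_rows else pd.DataFrame()
        )
        match_df.to_csv(out_root / "peak_match.csv", index=False)
        pd.DataFrame(cluster_rows).to_csv(out_root / "ward_clusters.csv", index=False)
        pd.concat(overlap_frames, ignore_index=True).to_csv(
            out_root / "overlap.csv", index=False
        )
        summary["n_stable_clusters"] = int(
            sum(r["stable"] for r in cluster_rows)
        )
        if len(match_df):
            summary["pct_index_peaks_reproducible"] = float(
                100.0 * match_df["reproducible"].mean()
            )
    elif stage == "fingerprint":
        spec = FeatureSpec(
            mode=config.feature_mode, rois=config.feature_rois, contrast="conjunction",
            t_min=config.t_min,
        )
        subs = sorted(by_subject)
        runs_per = [sorted(by_subject[s]) for s in subs]
        n_runs = min(len(r) for r in runs_per)
        feats = np.stack(
            [
                np.stack(
                    [extract_features(maps[(s, ses)], atlas, spec) for ses in rl[:n_runs]]
                )
                for s, rl in zip(subs, runs_per)
            ]
        )
        if n_runs >= 2 and len(subs) >= 2:
            report = svm_identify_loo(feats, subs, alpha=config.alpha)
            report.trials.to_csv(out_root / "svm_trials.csv", index=False)
            report.confusion.to_csv(out_root / "svm_confusion.csv")
            summary["svm_accuracy_pct"] = report.accuracy_pct
            summary["svm_cutoff_pct"] = report.cutoff_pct
            summary["svm_significant"] = report.significant
        summary["binomial_cutoff_5class_25trials_pct"] = binomial_cutoff(25, 0.2, 0.05)
        summary["binomial_cutoff_2class_25trials_pct"] = binomial_cutoff(25, 0.5, 0.05)
    else:
        raise ValueError(f"unknown report stage {stage!r}")

    (out_root / f"summary_{stage}.json").write_text(json.dumps(summary, indent=1))
    return summary


def fingerprint_with_library(
    target_cohort: CohortDataset,
    library_cohort: CohortDataset,
    config: PipelineConfig,
    spec: FeatureSpec | None = None,
):
    """Run the single-exemplar hyperplane protocol of a multi-session cohort
    against a single-session library cohort (in-memory convenience)."""
    spec = spec or FeatureSpec(
        mode=config.feature_mode, rois=config.feature_rois, contrast="conjunction",
        t_min=config.t_min,
    )
    tmaps = glm_maps_for_cohort(target_cohort, config)
    lmaps = glm_maps_for_cohort(library_cohort, config)
    atlas = target_cohort.atlas
    subs = sorted({s for s, _ in tmaps})
    sessions = sorted({r for _, r in tmaps})
    target = np.stack(
        [
            np.stack([extract_features(tmaps[(s, r)], atlas, spec) for r in sessions])
            for s in subs
        ]
    )
    lib_keys = sorted(lmaps)
    library = np.stack([extract_features(lmaps[k], atlas, spec) for k in lib_keys])
    return hyperplane_protocol(target, library, alpha=config.alpha)
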