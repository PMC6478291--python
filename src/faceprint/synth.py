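"""Synthetic block-design face-localizer cohorts with known ground truth.

Every generator is a pure function of its seed and parameters.  Subject
identity is carried by Gaussian activation blobs whose centers and amplitudes
are drawn once per subject and reused, bit-identical, in every session; only
temporal noise and a multiplicative amplitude jitter differ between sessions.
This operationalizes the premise that individual activation topographies are
stable over time while measurement noise is not.

The default paradigm mirrors a standard face localizer: four stimulus
categories (faces, houses, objects, landscapes) presented in 16 s blocks of
20 stimuli at 800 ms each, eight blocks per category in pseudorandomized
order (no category twice in a row), plus one 27 s rest period, acquired at
TR = 1.7 s over 336 volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

DEFAULT_CONDITIONS = ("faces", "houses", "objects", "landscapes")

__all__ = [
    "Block",
    "StimulusSchedule",
    "ROISpec",
    "ROIAtlas",
    "EffectSpec",
    "SubjectTemplate",
    "Acquisition",
    "NoiseParams",
    "SessionRealization",
    "CohortDataset",
    "build_schedule",
    "make_atlas",
    "default_roi_specs",
    "make_subject_template",
    "simulate_session",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# stimulus schedule


@dataclass(frozen=True)
class Block:
    condition: str
    onset_s: float
    duration_s: float


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered condition blocks plus rest periods for one imaging run."""

    blocks: tuple[Block, ...]
    rest_periods: tuple[tuple[float, float], ...]  # (onset_s, duration_s)
    total_duration_s: float
    conditions: tuple[str, ...]

    def onsets(self, condition: str) -> np.ndarray:
        return np.array([b.onset_s for b in self.blocks if b.condition == condition])

    def to_events_frame(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type)."""
        rows = [(b.onset_s, b.duration_s, b.condition) for b in self.blocks]
        rows += [(o, d, "rest") for o, d in self.rest_periods]
        frame = pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])
        return frame.sort_values("onset", kind="stable").reset_index(drop=True)

    @staticmethod
    def from_events_frame(frame: pd.DataFrame) -> "StimulusSchedule":
        blocks = []
        rests = []
        for _, row in frame.iterrows():
            if row["trial_type"] == "rest":
                rests.append((float(row["onset"]), float(row["duration"])))
            else:
                blocks.append(
                    Block(str(row["trial_type"]), float(row["onset"]), float(row["duration"]))
                )
        blocks.sort(key=lambda b: b.onset_s)
        ends = [b.onset_s + b.duration_s for b in blocks] + [o + d for o, d in rests]
        conds = tuple(dict.fromkeys(b.condition for b in blocks))
        return StimulusSchedule(tuple(blocks), tuple(rests), max(ends, default=0.0), conds)


def _pseudorandom_order(
    n_conditions: int, blocks_per_condition: int, rng: np.random.Generator
) -> list[int]:
    """Condition sequence with equal counts and no immediate repeats."""
    if n_conditions == 1:
        return [0] * blocks_per_condition
    # sequential draw that stays feasible: a condition holding more than half
    # of the remaining slots must be placed next (majority rule), otherwise
    # pick uniformly among the conditions different from the previous one
    rem = np.full(n_conditions, blocks_per_condition)
    order: list[int] = []
    prev = -1
    while rem.sum() > 0:
        total = int(rem.sum())
        forced = np.flatnonzero(2 * rem > total)
        if forced.size and forced[0] != prev:
            pick = int(forced[0])
        else:
            candidates = np.flatnonzero((rem > 0) & (np.arange(n_conditions) != prev))
            if candidates.size == 0:
                raise RuntimeError("no-repeat order infeasible")
            pick = int(rng.choice(candidates))
        order.append(pick)
        rem[pick] -= 1
        prev = pick
    return order


def build_schedule(
    n_conditions: int = 4,
    blocks_per_condition: int = 8,
    stimuli_per_block: int = 20,
    stimulus_period_s: float = 0.8,
    rest_duration_s: float = 27.0,
    order_seed: int = 0,
    conditions: tuple[str, ...] | None = None,
    inter_block_gap_s: float = 0.0,
    start_s: float = 0.0,
) -> StimulusSchedule:
    """Build a pseudorandomized block schedule.

    Block duration is ``stimuli_per_block * stimulus_period_s`` (the default
    20 x 0.8 s = 16 s).  No condition occurs twice in a row.  The single rest
    period is appended after the last block; ``inter_block_gap_s`` inserts an
    optional fixation gap between consecutive blocks.
    """
    if n_conditions < 1 or blocks_per_condition < 1 or stimuli_per_block < 1:
        raise ValueError("all counts must be >= 1")
    if stimulus_period_s <= 0:
        raise ValueError("stimulus_period_s must be > 0")
    if rest_duration_s < 0 or inter_block_gap_s < 0:
        raise ValueError("durations must be >= 0")
    if conditions is None:
        if n_conditions <= len(DEFAULT_CONDITIONS):
            conditions = DEFAULT_CONDITIONS[:n_conditions]
        else:
            conditions = tuple(f"cond_{i}" for i in range(n_conditions))
    if len(conditions) != n_conditions:
        raise ValueError("len(conditions) must equal n_conditions")

    rng = np.random.default_rng(order_seed)
    order = _pseudorandom_order(n_conditions, blocks_per_condition, rng)
    duration = stimuli_per_block * stimulus_period_s
    blocks = []
    t = start_s
    for idx in order:
        blocks.append(Block(conditions[idx], t, duration))
        t += duration + inter_block_gap_s
    if inter_block_gap_s:
        t -= inter_block_gap_s  # no gap after the final block
    rests: tuple[tuple[float, float], ...] = ()
    if rest_duration_s > 0:
        rests = ((t, rest_duration_s),)
        t += rest_duration_s
    return StimulusSchedule(tuple(blocks), rests, t, conditions)


# ---------------------------------------------------------------------------
# ROI atlas


@dataclass(frozen=True)
class ROISpec:
    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    response_class: str  # task_positive | task_negative | hybrid
    hemisphere: str = "M"  # L | R | M(idline)


@dataclass(frozen=True)
class ROIInfo:
    name: str
    hemisphere: str
    response_class: str


@dataclass
class ROIAtlas:
    """Integer label volume with a voxel->mm affine.

    Label 0 is background; ``rois`` maps each positive label to its name,
    hemisphere and response class.
    """

    labels: np.ndarray  # int array, grid shape
    affine: np.ndarray  # 4x4
    rois: dict[int, ROIInfo]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def label_of(self, name: str) -> int:
        for lab, info in self.rois.items():
            if info.name == name:
                return lab
        raise KeyError(f"no ROI named {name!r}")

    def names(self) -> list[str]:
        return [info.name for info in self.rois.values()]

    def mask(self, names: str | list[str] | tuple[str, ...]) -> np.ndarray:
        """Boolean mask for one ROI name or the union of several."""
        if isinstance(names, str):
            names = [names]
        out = np.zeros(self.shape, dtype=bool)
        for name in names:
            out |= self.labels == self.label_of(name)
        return out

    def voxel_centers_mm(self, mask: np.ndarray) -> np.ndarray:
        """World-mm coordinates of the centers of the masked voxels, (n, 3)."""
        ijk = np.argwhere(mask)
        return nib_affines_apply(self.affine, ijk)


def nib_affines_apply(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    from nibabel.affines import apply_affine

    return apply_affine(affine, ijk)


def _centered_affine(grid_shape, voxel_size_mm) -> np.ndarray:
    vs = np.broadcast_to(np.asarray(voxel_size_mm, float), (3,))
    affine = np.diag([vs[0], vs[1], vs[2], 1.0])
    affine[:3, 3] = -vs * (np.asarray(grid_shape) - 1) / 2.0
    return affine


def default_roi_specs() -> list[ROISpec]:
    """Bilateral FFA/OFA/pSTS-TPJ/amygdala analogs plus a midline
    task-negative (precuneus-like) region, sized for a 32x32x24 grid at 3 mm."""
    specs = []
    for hemi, sx in (("L", -1), ("R", 1)):
        specs += [
            ROISpec(f"FFA_{hemi}", (sx * 30.0, -18.0, -15.0), 7.5, "task_positive", hemi),
            ROISpec(f"OFA_{hemi}", (sx * 33.0, -33.0, -3.0), 7.0, "task_positive", hemi),
            ROISpec(f"pSTS_TPJ_{hemi}", (sx * 36.0, -9.0, 9.0), 9.0, "hybrid", hemi),
            ROISpec(f"Amygdala_{hemi}", (sx * 15.0, 6.0, -15.0), 6.0, "task_positive", hemi),
        ]
    specs.append(ROISpec("Precuneus_M", (0.0, -24.0, 21.0), 9.0, "task_negative", "M"))
    return specs


def make_atlas(
    grid_shape: tuple[int, int, int] = (32, 32, 24),
    voxel_size_mm: float = 3.0,
    roi_specs: list[ROISpec] | None = None,
) -> ROIAtlas:
    """Rasterize spherical ROIs onto a regular grid (first-listed wins).

    A voxel belongs to a sphere when its center lies within ``radius_mm`` of
    the sphere center (inclusive, so radius 0 at a voxel center keeps that
    one voxel).
    """
    if any(s < 1 for s in grid_shape):
        raise ValueError("grid_shape must be positive")
    if roi_specs is None:
        roi_specs = default_roi_specs()
    affine = _centered_affine(grid_shape, voxel_size_mm)
    labels = np.zeros(grid_shape, dtype=np.int16)
    ijk = np.indices(grid_shape).reshape(3, -1).T
    xyz = nib_affines_apply(affine, ijk)
    rois: dict[int, ROIInfo] = {}
    for lab, spec in enumerate(roi_specs, start=1):
        d2 = np.sum((xyz - np.asarray(spec.center_mm)) ** 2, axis=1)
        inside = (d2 <= spec.radius_mm**2 + 1e-9).reshape(grid_shape)
        if not inside.any():
            raise ValueError(f"ROI {spec.name!r} lies entirely outside the grid")
        labels[inside & (labels == 0)] = lab
        rois[lab] = ROIInfo(spec.name, spec.hemisphere, spec.response_class)
    return ROIAtlas(labels, affine, rois)


# ---------------------------------------------------------------------------
# subject templates


@dataclass(frozen=True)
class EffectSpec:
    """Mean condition betas per ROI response class, plus blob geometry.

    ``condition_betas`` maps response class -> 4-vector aligned with the
    schedule's condition order.  Defaults encode face-selective activation in
    task-positive regions and task deactivation that is weakest for faces in
    task-negative regions; hybrid regions get a positive (task-positive-like)
    blob in their inferior half and a negative (task-negative-like) blob in
    their superior half.
    """

    condition_betas: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "task_positive": (1.0, 0.3, 0.3, 0.3),
            "task_negative": (-0.2, -0.8, -0.8, -0.8),
        }
    )
    blob_fwhm_mm: float = 6.0
    blob_amplitude: float = 3.0
    amplitude_jitter_range: tuple[float, float] = (0.8, 1.2)  # per-blob draw
    max_blobs_per_roi: int = 2


@dataclass(frozen=True)
class PlantedBlob:
    """Ground-truth record of one activation source."""

    center_mm: np.ndarray
    polarity: str  # activation | deactivation
    amplitude: float


@dataclass
class SubjectTemplate:
    """Per-subject ground-truth spatial beta pattern, session-invariant."""

    subject_id: str
    beta_maps: dict[str, np.ndarray]  # condition -> 3D volume
    blobs: dict[str, list[PlantedBlob]]  # roi -> planted sources
    affine: np.ndarray
    conditions: tuple[str, ...]
    seed: int

    @property
    def peak_centers(self) -> dict[str, list[tuple[np.ndarray, str]]]:
        """(mm center, polarity) pairs per ROI."""
        return {
            roi: [(b.center_mm, b.polarity) for b in blobs]
            for roi, blobs in self.blobs.items()
        }


def _gaussian_blob(xyz_flat, center_mm, fwhm_mm, grid_shape):
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    d2 = np.sum((xyz_flat - center_mm) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * sigma**2)).reshape(grid_shape)


def make_subject_template(
    atlas: ROIAtlas,
    effect_spec: EffectSpec | None = None,
    subject_seed: int = 0,
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
    subject_id: str | None = None,
) -> SubjectTemplate:
    """Draw subject-specific blob centers and build per-condition beta maps.

    Per ROI, 1-2 Gaussian blob centers are placed uniformly inside the ROI
    (uniform over voxel centers plus sub-voxel jitter) with per-blob amplitude
    draws; the beta map of each condition is the sum of blobs scaled by that
    condition's mean beta for the ROI's response class.  Hybrid ROIs receive
    one positive blob in their inferior half and one negative blob in their
    superior half (split at the ROI's median z in world mm).
    """
    spec = effect_spec or EffectSpec()
    for cls in {info.response_class for info in atlas.rois.values()}:
        needed = ("task_positive", "task_negative") if cls == "hybrid" else (cls,)
        for cl in needed:
            if cl not in spec.condition_betas:
                raise ValueError(f"effect_spec missing condition betas for {cl!r}")
    rng = np.random.default_rng(subject_seed)
    grid_shape = atlas.shape
    ijk = np.indices(grid_shape).reshape(3, -1).T
    xyz = nib_affines_apply(atlas.affine, ijk)
    vox_edge = np.abs(np.diag(atlas.affine)[:3])

    beta_maps = {c: np.zeros(grid_shape) for c in conditions}
    blobs: dict[str, list[PlantedBlob]] = {}

    def _draw_center(mask: np.ndarray) -> np.ndarray:
        centers = atlas.voxel_centers_mm(mask)
        pick = centers[rng.integers(len(centers))]
        return pick + rng.uniform(-0.5, 0.5, size=3) * vox_edge

    def _add_blob(center, betas, amp):
        blob = _gaussian_blob(xyz, center, spec.blob_fwhm_mm, grid_shape)
        for cond, b in zip(conditions, betas):
            beta_maps[cond] += amp * b * blob

    for lab, info in atlas.rois.items():
        mask = atlas.labels == lab
        blobs[info.name] = []
        if info.response_class == "hybrid":
            z = atlas.voxel_centers_mm(mask)[:, 2]
            z_split = np.median(z)
            zvol = xyz[:, 2].reshape(grid_shape)
            halves = [
                (mask & (zvol <= z_split), "task_positive", "activation"),
                (mask & (zvol > z_split), "task_negative", "deactivation"),
            ]
            for half_mask, cls, pol in halves:
                if not half_mask.any():
                    continue
                center = _draw_center(half_mask)
                amp = spec.blob_amplitude * rng.uniform(*spec.amplitude_jitter_range)
                _add_blob(center, spec.condition_betas[cls], amp)
                blobs[info.name].append(PlantedBlob(center, pol, amp))
        else:
            n_blobs = int(rng.integers(1, spec.max_blobs_per_roi + 1))
            pol = "activation" if info.response_class == "task_positive" else "deactivation"
            for _ in range(n_blobs):
                center = _draw_center(mask)
                amp = spec.blob_amplitude * rng.uniform(*spec.amplitude_jitter_range)
                _add_blob(center, spec.condition_betas[info.response_class], amp)
                blobs[info.name].append(PlantedBlob(center, pol, amp))

    return SubjectTemplate(
        subject_id=subject_id or f"sub-{subject_seed:04d}",
        beta_maps=beta_maps,
        blobs=blobs,
        affine=atlas.affine.copy(),
        conditions=tuple(conditions),
        seed=subject_seed,
    )


# ---------------------------------------------------------------------------
# session simulation


@dataclass(frozen=True)
class Acquisition:
    tr_s: float = 1.7
    n_volumes: int = 336
    discard_initial: int = 5


@dataclass(frozen=True)
class NoiseParams:
    """Temporal noise: stationary AR(1) with marginal SD ``white_sd`` and
    lag-1 autocorrelation ``ar_coefficient`` (white noise when 0), plus a
    per-session multiplicative amplitude jitter on the condition betas."""

    ar_coefficient: float = 0.2
    white_sd: float = 1.0
    amplitude_jitter_sd: float = 0.1

    def __post_init__(self):
        if self.white_sd < 0 or self.amplitude_jitter_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not abs(self.ar_coefficient) < 1:
            raise ValueError("|ar_coefficient| must be < 1")


@dataclass
class SessionRealization:
    subject_id: str
    session_index: int
    series: np.ndarray  # 4D (x, y, z, t)
    schedule: StimulusSchedule
    acquisition: Acquisition
    noise_params: NoiseParams
    affine: np.ndarray
    seed: int


def _ar1_noise(rho: float, sd: float, shape_tv: tuple[int, int], rng) -> np.ndarray:
    """Stationary AR(1) series, marginal SD ``sd``, shape (T, V)."""
    T, V = shape_tv
    if sd == 0:
        return np.zeros((T, V))
    innov = rng.standard_normal((T, V)) * sd * np.sqrt(1.0 - rho**2)
    innov[0] = rng.standard_normal(V) * sd  # stationary start
    return _signal.lfilter([1.0], [1.0, -rho], innov, axis=0)


def simulate_session(
    template: SubjectTemplate,
    schedule: StimulusSchedule,
    acquisition: Acquisition = Acquisition(),
    noise_params: NoiseParams = NoiseParams(),
    session_seed: int = 0,
    session_index: int = 0,
) -> SessionRealization:
    """Forward-simulate one run: HRF-convolved regressors times the subject's
    beta maps (with session amplitude jitter), plus AR(1) temporal noise."""
    from .glm import GLMOptions, build_design_matrix

    if acquisition.n_volumes * acquisition.tr_s < schedule.total_duration_s:
        raise ValueError("scan shorter than the stimulus schedule")
    design = build_design_matrix(
        schedule, acquisition.tr_s, acquisition.n_volumes, GLMOptions(), drift=False
    )
    cols = []
    for c in template.conditions:  # conditions absent from the schedule: flat
        if c in design.names:
            cols.append(design.matrix[:, design.names.index(c)])
        else:
            cols.append(np.zeros(acquisition.n_volumes))
    R = np.column_stack(cols)  # (T, C)

    rng = np.random.default_rng(session_seed)
    jitter = 1.0 + rng.standard_normal(len(template.conditions)) * noise_params.amplitude_jitter_sd
    grid_shape = template.beta_maps[template.conditions[0]].shape
    B = np.stack(
        [template.beta_maps[c].ravel() * j for c, j in zip(template.conditions, jitter)]
    )  # (C, V)
    Y = R @ B  # (T, V)
    Y += _ar1_noise(
        noise_params.ar_coefficient, noise_params.white_sd, Y.shape, rng
    )
    series = np.ascontiguousarray(
        Y.T.reshape(grid_shape + (acquisition.n_volumes,)).astype(np.float32)
    )
    return SessionRealization(
        subject_id=template.subject_id,
        session_index=session_index,
        series=series,
        schedule=schedule,
        acquisition=acquisition,
        noise_params=noise_params,
        affine=template.affine.copy(),
        seed=session_seed,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortDataset:
    atlas: ROIAtlas
    templates: list[SubjectTemplate]
    sessions: list[SessionRealization]
    manifest: pd.DataFrame  # subject, session, series_path, events_path
    seed: int


def simulate_cohort(
    layout: str = "5x5",
    n_subjects: int | None = None,
    sessions_per_subject: int | None = None,
    atlas: ROIAtlas | None = None,
    effect_spec: EffectSpec | None = None,
    schedule_kwargs: dict | None = None,
    acquisition: Acquisition = Acquisition(),
    noise_params: NoiseParams = NoiseParams(),
    master_seed: int = 0,
    out_dir=None,
    common_template: bool | int = False,
) -> CohortDataset:
    """Simulate a cohort of runs with a deterministic seed tree.

    ``layout`` "5x5" is 5 subjects x 5 sessions (test-retest group), "80x1"
    is ``n_subjects`` (default 80) single-session subjects, "custom" uses the
    explicit counts.  The master seed deterministically spawns per-subject and
    per-session seeds.  One pseudorandomized block order, drawn from the
    master seed, is shared by every run of the cohort, as in a localizer
    study that presents the same stimulus protocol to all participants
    (per-run orders would make the design correlation structure, and hence
    the joint distribution of the contrast maps, subject-specific).
    ``common_template`` gives every subject the same spatial template
    (identity information removed; useful for null calibration): ``True``
    derives the shared template seed from the master seed, an integer fixes
    it explicitly so separate cohorts can share one template.

    With ``out_dir`` set, runs are written as 4D NIfTI plus BIDS-style
    events.tsv, the atlas as 3D NIfTI, and a manifest.csv.
    """
    if layout == "5x5":
        n_subjects, sessions_per_subject = 5, 5
    elif layout == "80x1":
        n_subjects = 80 if n_subjects is None else n_subjects
        sessions_per_subject = 1
    elif layout == "custom":
        if n_subjects is None or sessions_per_subject is None:
            raise ValueError("custom layout needs n_subjects and sessions_per_subject")
    else:
        raise ValueError(f"unknown layout {layout!r}")
    if n_subjects < 1 or sessions_per_subject < 1:
        raise ValueError("counts must be >= 1")

    atlas = atlas or make_atlas()
    ss = np.random.SeedSequence(master_seed)
    subject_streams = ss.spawn(n_subjects)
    schedule_kwargs = dict(schedule_kwargs or {})
    # one pseudorandomized order for the whole study, independent of the
    # master seed so that separately simulated cohorts share the paradigm
    order_seed = schedule_kwargs.pop("order_seed", 0)
    sched = build_schedule(order_seed=order_seed, **schedule_kwargs)

    templates: list[SubjectTemplate] = []
    sessions: list[SessionRealization] = []
    rows = []
    for si, sub_ss in enumerate(subject_streams):
        seeds = sub_ss.generate_state(2 + sessions_per_subject) % (2**31)
        if common_template is False:
            template_seed = int(seeds[0])
        elif common_template is True:
            template_seed = int(
                np.random.SeedSequence(master_seed).generate_state(1)[0] % (2**31)
            )
        else:
            template_seed = int(common_template)
        template = make_subject_template(
            atlas, effect_spec, subject_seed=template_seed, subject_id=f"sub-{si + 1:02d}"
        )
        template.subject_id = f"sub-{si + 1:02d}"
        templates.append(template)
        for ri in range(sessions_per_subject):
            sess = simulate_session(
                template,
                sched,
                acquisition,
                noise_params,
                session_seed=int(seeds[2 + ri]),
                session_index=ri + 1,
            )
            sessions.append(sess)
            rows.append(
                {
                    "subject": template.subject_id,
                    "session": ri + 1,
                    "series_path": f"{template.subject_id}_ses-{ri + 1}_bold.nii",
                    "events_path": f"{template.subject_id}_ses-{ri + 1}_events.tsv",
                }
            )
    manifest = pd.DataFrame(rows)
    cohort = CohortDataset(atlas, templates, sessions, manifest, master_seed)
    if out_dir is not None:
        from . import io as fio

        fio.write_cohort(cohort, out_dir)
    return cohort
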