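"""Identifying individual subjects from their activation patterns.

Two protocols:

* multiclass leave-one-out SVM — one run is held out, features are
  standardized with the remaining runs' statistics, linear one-vs-one
  support vector machines are trained on the remaining runs, and the held-out
  run is classified by majority vote (chance 1/n_subjects);

* single-exemplar hyperplane fingerprinting — for every (target subject,
  training run, library subject) triple, the separating hyperplane is the
  plane through the midpoint of the two training feature vectors with the
  normal along their difference; each of the target's remaining runs is
  classified by the side it falls on (chance 1/2).

Accuracy is declared significant at the smallest k/n whose binomial CDF
reaches 1 - alpha (the inverse-CDF convention; 32% for 25 five-class trials,
68% for 25 two-class trials).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .glm import StatMap
from .synth import ROIAtlas, nib_affines_apply

__all__ = [
    "FeatureSpec",
    "FeatureVector",
    "ClassificationReport",
    "extract_features",
    "standardize",
    "svm_identify_loo",
    "hyperplane_classify",
    "hyperplane_protocol",
    "binomial_cutoff",
]

CONTRASTS = ("f>h", "f>o", "f>l")


@dataclass(frozen=True)
class FeatureSpec:
    """What to extract from a run's statistic maps.

    ``mode``: voxelwise (all in-mask values of one combined ROI mask),
    peak_t (per-ROI maximum t), peak_coords (mm coordinates of each ROI's
    maximum), or peak_t_and_coords.  ``contrast`` is one of the three
    face contrasts, "conjunction", or "combination" (the three contrasts'
    feature blocks concatenated).  ``t_min`` marks a ROI peak as missing
    when its maximum stays below it; missing peaks map to sentinel features
    (t = 0, coordinates = ROI centroid).
    """

    mode: str = "voxelwise"
    rois: tuple[str, ...] = ("FFA_L", "FFA_R")
    contrast: str = "conjunction"
    smoothed: bool = False
    t_min: float = 1.65

    def __post_init__(self):
        if self.mode not in ("voxelwise", "peak_t", "peak_coords", "peak_t_and_coords"):
            raise ValueError(f"unknown feature mode {self.mode!r}")


@dataclass
class FeatureVector:
    values: np.ndarray
    subject_id: str
    session_id: int
    spec: FeatureSpec


@dataclass
class ClassificationReport:
    accuracy_pct: float
    confusion: pd.DataFrame
    trials: pd.DataFrame
    cutoff_pct: float
    significant: bool
    n_trials: int
    chance: float
    extra: dict = field(default_factory=dict)


def _maps_for_contrast(stat_maps: dict[str, StatMap], contrast: str) -> list[StatMap]:
    if contrast == "combination":
        return [stat_maps[c] for c in CONTRASTS]
    return [stat_maps[contrast]]


def extract_features(
    stat_maps: dict[str, StatMap],
    atlas: ROIAtlas,
    spec: FeatureSpec,
) -> np.ndarray:
    """Feature vector of one run from its contrast/conjunction t maps.

    ``stat_maps`` maps contrast names ("f>h", "f>o", "f>l", "conjunction")
    to StatMaps on the atlas grid.  Feature order is fixed by the spec and
    the atlas scan order, so vectors from different runs are comparable.
    """
    for roi in spec.rois:
        if not atlas.mask(roi).any():
            raise ValueError(f"empty ROI {roi!r}")
    blocks = []
    for smap in _maps_for_contrast(stat_maps, spec.contrast):
        if smap.values.shape != atlas.shape:
            raise ValueError("map and atlas grids differ")
        if spec.mode == "voxelwise":
            mask = atlas.mask(list(spec.rois))
            blocks.append(smap.values[mask])
            continue
        t_feats = []
        c_feats = []
        for roi in spec.rois:
            mask = atlas.mask(roi)
            vals = np.where(mask, smap.values, -np.inf)
            ijk = np.unravel_index(np.argmax(vals), vals.shape)
            t_max = float(smap.values[ijk])
            if t_max >= spec.t_min:
                xyz = nib_affines_apply(atlas.affine, np.array([ijk]))[0]
            else:  # missing peak -> sentinel
                t_max = 0.0
                xyz = atlas.voxel_centers_mm(mask).mean(axis=0)
            t_feats.append(t_max)
            c_feats.extend(xyz)
        if spec.mode == "peak_t":
            blocks.append(np.asarray(t_feats))
        elif spec.mode == "peak_coords":
            blocks.append(np.asarray(c_feats))
        else:
            blocks.append(np.concatenate([t_feats, c_feats]))
    return np.concatenate(blocks)


def standardize(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Z-score features with training-set statistics only.

    Columns with zero training SD become all zeros in both sets (they carry
    no information under this scaling).
    """
    train = np.asarray(train, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need >= 2 training rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    live = sd > 1e-12 * np.maximum(1.0, np.abs(mean))  # constant up to rounding
    safe = np.where(live, sd, 1.0)
    tr = np.where(live, (train - mean) / safe, 0.0)
    te = None
    if test is not None:
        test = np.atleast_2d(np.asarray(test, dtype=float))
        te = np.where(live, (test - mean) / safe, 0.0)
    return tr, te


def _ovo_predict(X_train, y_train, x_test, classes, C=1.0):
    """One-vs-one linear SVMs with majority vote; ties -> lowest class."""
    votes = np.zeros(len(classes), dtype=int)
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            sel = (y_train == classes[a]) | (y_train == classes[b])
            clf = SVC(kernel="linear", C=C)
            clf.fit(X_train[sel], y_train[sel])
            pred = clf.predict(x_test.reshape(1, -1))[0]
            votes[a if pred == classes[a] else b] += 1
    return classes[int(np.argmax(votes))]  # argmax takes the first (lowest) max


def svm_identify_loo(
    features: np.ndarray,
    subject_ids: list[str] | None = None,
    alpha: float = 0.05,
    C: float = 1.0,
) -> ClassificationReport:
    """Leave-one-run-out multiclass identification.

    ``features`` has shape (n_subjects, n_runs, n_features).  For each held-
    out run, standardization statistics and the one-vs-one linear SVMs come
    exclusively from the remaining runs.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 3:
        raise ValueError("features must be (n_subjects, n_runs, n_features)")
    S, R, F = features.shape
    if S < 2:
        raise ValueError("need >= 2 subjects (classes)")
    if R < 2:
        raise ValueError("need >= 2 runs per subject")
    subject_ids = subject_ids or [f"sub-{i + 1:02d}" for i in range(S)]
    X = features.reshape(S * R, F)
    y = np.repeat(np.arange(S), R)
    runs = np.tile(np.arange(R), S)
    classes = np.arange(S)

    records = []
    confusion = np.zeros((S, S), dtype=int)
    for i in range(S * R):
        mask = np.ones(S * R, dtype=bool)
        mask[i] = False
        Xtr, Xte = standardize(X[mask], X[i])
        pred = _ovo_predict(Xtr, y[mask], Xte[0], classes, C=C)
        confusion[y[i], pred] += 1
        records.append(
            {
                "true": subject_ids[y[i]],
                "predicted": subject_ids[pred],
                "run": int(runs[i]) + 1,
                "correct": bool(pred == y[i]),
            }
        )
    trials = pd.DataFrame(records)
    n_trials = len(trials)
    acc = 100.0 * trials["correct"].mean()
    cutoff = binomial_cutoff(n_trials, 1.0 / S, alpha)
    return ClassificationReport(
        accuracy_pct=float(acc),
        confusion=pd.DataFrame(confusion, index=subject_ids, columns=subject_ids),
        trials=trials,
        cutoff_pct=cutoff,
        significant=bool(acc >= cutoff),
        n_trials=n_trials,
        chance=1.0 / S,
    )


def hyperplane_classify(
    train_a: np.ndarray, train_b: np.ndarray, test: np.ndarray
) -> int:
    """Side of the point-normal bisector hyperplane a test vector falls on.

    The hyperplane passes through m = (a+b)/2 with normal w = a - b.
    Returns +1 (side of a), -1 (side of b) or 0 for a point exactly on the
    boundary, which callers count as incorrect for either class.
    """
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    x = np.asarray(test, dtype=float)
    if a.shape != b.shape or a.shape != x.shape:
        raise ValueError("vectors must have equal length")
    if np.array_equal(a, b):
        raise ValueError("degenerate hyperplane: identical training vectors")
    s = float((a - b) @ (x - (a + b) / 2.0))
    return 0 if s == 0 else (1 if s > 0 else -1)


def hyperplane_protocol(
    target_features: np.ndarray,
    library_features: np.ndarray,
    alpha: float = 0.05,
    standardize_with: str | None = "pooled",
) -> ClassificationReport:
    """Single-exemplar identification against a one-session library.

    ``target_features`` is (S, R, F) for the multi-session group,
    ``library_features`` (L, F) for the single-session group.  Every
    (subject, training run, library subject) triple defines one hyperplane
    (S*R*L pairs; 2000 for 5x5x80) and classifies the subject's R-1 held-out
    runs (S*R*L*(R-1) classifications; 8000).  A held-out run is correct when
    it falls on its own subject's side.

    A two-point training set has a degenerate SD, so features are z-scored
    with cohort-level statistics: ``standardize_with`` "pooled" (default)
    uses all target and library runs together, which treats both cohorts
    symmetrically (with "library", each library vector contributes to its
    own centering, which systematically shrinks library norms and biases the
    bisector rule toward the library side when the library is small);
    ``None`` skips scaling.  The significance cutoff uses n = S*R trials at
    chance 0.5, the convention under which 25 trials give 68%.
    """
    target = np.asarray(target_features, dtype=float)
    library = np.asarray(library_features, dtype=float)
    if target.ndim != 3 or library.ndim != 2:
        raise ValueError("target must be (S,R,F), library (L,F)")
    S, R, F = target.shape
    L = library.shape[0]
    if L == 0:
        raise ValueError("empty library cohort")
    if R < 2:
        raise ValueError("need >= 2 runs per target subject")
    if library.shape[1] != F:
        raise ValueError("feature length mismatch between cohorts")

    if standardize_with == "pooled":
        pooled = np.vstack([target.reshape(S * R, F), library])
        _, both = standardize(pooled, pooled)
        target = both[: S * R].reshape(S, R, F)
        library = both[S * R :]
    elif standardize_with == "library":
        lib_std, tgt_std = standardize(library, target.reshape(S * R, F))
        target = tgt_std.reshape(S, R, F)
        library = lib_std
    elif standardize_with is not None:
        raise ValueError("standardize_with must be 'pooled', 'library' or None")

    n_pairs = 0
    n_correct = 0
    n_total = 0
    per_subject = np.zeros(S, dtype=int)
    per_subject_n = np.zeros(S, dtype=int)
    for s in range(S):
        held = [r for r in range(R)]
        for r in range(R):
            a = target[s, r]
            tests = [target[s, rr] for rr in held if rr != r]
            for ell in range(L):
                b = library[ell]
                n_pairs += 1
                for x in tests:
                    side = hyperplane_classify(a, b, x)
                    ok = side == 1
                    n_correct += int(ok)
                    n_total += 1
                    per_subject[s] += int(ok)
                    per_subject_n[s] += 1
    acc = 100.0 * n_correct / n_total
    cutoff = binomial_cutoff(S * R, 0.5, alpha)
    per_sub = pd.DataFrame(
        {
            "subject": [f"sub-{i + 1:02d}" for i in range(S)],
            "accuracy_pct": 100.0 * per_subject / np.maximum(per_subject_n, 1),
            "n": per_subject_n,
        }
    )
    trials = pd.DataFrame(
        {"n_training_pairs": [n_pairs], "n_classifications": [n_total]}
    )
    return ClassificationReport(
        accuracy_pct=float(acc),
        confusion=per_sub,
        trials=trials,
        cutoff_pct=cutoff,
        significant=bool(acc >= cutoff),
        n_trials=n_total,
        chance=0.5,
        extra={"n_training_pairs": n_pairs, "n_classifications": n_total},
    )


def binomial_cutoff(n_trials: int, chance: float, alpha: float = 0.05) -> float:
    """Smallest accuracy (in %) declared above chance at level alpha.

    k* is the smallest integer k with BinomialCDF(k; n, chance) >= 1 - alpha
    (the binomial inverse-CDF convention); the cutoff is 100*k*/n.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not (0 < chance < 1) or not (0 < alpha < 1):
        raise ValueError("chance and alpha must lie in (0, 1)")
    k = int(stats.binom.ppf(1.0 - alpha, n_trials, chance))
    return 100.0 * k / n_trials
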