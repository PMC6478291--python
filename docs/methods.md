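# Methods

`faceprint` simulates and analyzes block-design face-localizer fMRI with a
focus on two questions: how stable are an individual's face-selective
activation peaks across repeated sessions, and how well do activation
patterns identify the individual ("fMRI fingerprinting")?  Every analysis
stage is exercised against a synthetic-data generator whose ground truth is
known exactly, so the pipeline's claims are testable without any scan data.

## Signal model

Each subject is a **template**: per ROI, 1–2 Gaussian blobs (FWHM 6 mm)
whose centers are drawn uniformly inside the ROI and whose amplitudes are
drawn once per blob (base amplitude 3.0 in signal units, per-blob factor
U[0.8, 1.2]).  Condition beta maps are the blob field scaled by per-class
condition weights:

* task-positive ROIs (FFA/OFA/amygdala analogs): faces 1.0, other
  categories 0.3 — face-selective activation;
* task-negative ROI (precuneus analog): faces −0.2, others −0.8 — task
  deactivation that is weakest for faces, so the face contrasts are positive
  there while faces-vs-baseline is negative;
* hybrid ROI (pSTS/TPJ analog): a task-positive blob in the inferior half
  and a task-negative blob in the superior half (split at the ROI's median
  z), so both polarities coexist.

Templates are bit-identical across a subject's sessions.  A session applies
one multiplicative amplitude jitter per condition (SD 0.1, the only
session-level signal variability) and adds stationary AR(1) temporal noise
with lag-1 autocorrelation 0.2 and marginal SD 1.0 per voxel.  The blob
amplitude is therefore 3× the noise SD by default; single-run conjunction
peaks land around t ≈ 8–12 on the default paradigm, a realistic range for a
strong localizer.  At AR coefficient 0 the noise reduces to white.

The paradigm is 4 categories × 8 blocks × 20 stimuli × 800 ms (16 s
blocks) in a pseudorandomized order with no immediate category repeat, plus
one 27 s rest appended after the last block, sampled at TR = 1.7 s over 336
volumes (9.5 min).  One block order, drawn from a fixed order seed, is
shared by every run and cohort: presenting the same stimulus protocol to
everyone is how localizer studies run, and per-run orders would make the
design correlation structure — and hence the joint distribution of the
contrast maps — carry subject identity, contaminating the fingerprinting
null.  An optional inter-block gap reconciles the 32 × 16 s + 27 s block
arithmetic with the 336-volume scan length if a user wants the two to match
exactly; by default the residual scan time simply trails the rest period.

The default grid is 32 × 32 × 24 voxels at 3 mm isotropic with the origin
at the grid center — large enough to hold 9 face-network ROI analogs,
small enough for desk-scale runtimes.

What the generator does **not** emulate: scanner drift beyond what the DCT
basis absorbs, motion, physiological noise, spatial noise correlations,
field distortions, and anatomical variability between subjects' ROI
boundaries.  Passing tests therefore demonstrate the correctness and
calibration of the analysis machinery under the stated noise model, not
performance on real scans.

## GLM

The design matrix holds one regressor per category — a boxcar over the
block convolved with the canonical double-gamma HRF (peak 6 s, undershoot
16 s, unit dispersions, ratio 6, 32 s support) on a 0.05 s grid, sampled at
volume times — plus a discrete-cosine drift basis with all frequencies
below 1/128 Hz and a constant.  The HRF is normalized to unit time-integral
so a sustained block response plateaus near 1 and betas stay in
signal-amplitude units.  A response to a single 16 s block peaks ~12 s
after block onset (the familiar 5–6 s HRF lag applies to brief events; for
a 16 s block the response keeps integrating until the HRF's positive lobe
ends).

Fitting whitens data and design with the fixed AR(1) coefficient 0.2
(Prais–Winsten transform: first row scaled by √(1−ρ²), then lagged
differences) and solves OLS per voxel; this equals closed-form GLS under
the assumed covariance, which a test verifies to 1e−8.  The error df is
volumes − rank(design).  The first five volumes of a default acquisition
are discarded before fitting (T1 equilibration), with the time axis shifted
accordingly; stimuli start after the discarded volumes by default.

Contrasts: t = c'β̂ / √(σ̂² c'(Xw'Xw)⁻¹c).  The conjunction is the voxelwise
minimum of the f>h, f>o, f>l t maps (conjunction-null convention: reject at
level α only where every constituent exceeds the single-contrast critical
value).  Faces-vs-baseline (c = +1 on faces) is the polarity reference that
separates "stronger activation" from "weaker deactivation" peaks.  Spatial
smoothing is a separable Gaussian (default FWHM 8 mm, σ in voxels via the
affine) with edge-renormalized kernels so constants are preserved; the
smoothed pipeline branch smooths the 4D series before fitting.  Group
inference is a voxelwise one-sample t (df = n−1); family-wise correction,
when requested, is Bonferroni over in-mask voxels.

## Peaks and reproducibility

A peak is a voxel inside a named ROI with t ≥ 1.65 (the default threshold
is configurable; exact critical values for any df are available) that
strictly exceeds all 26 neighbors in the 3×3×3 cube.  Neighbors outside the
ROI but inside the volume participate in the comparison — otherwise ROI
borders would manufacture peaks — while out-of-volume neighbors are
ignored; ties disqualify.  Polarity at exactly 0 is "deactivation" by
convention.

Reproducibility metrics:

* **Index-run matching** — a first-session peak is reproducible when a peak
  occurs within Chebyshev distance ≤ 1 voxel ("same or directly
  surrounding coordinates") in at least 3 of the 4 subsequent sessions.
* **Ward clustering** — peaks pooled over sessions are clustered by Ward's
  minimum-variance linkage on their mm coordinates; the tree is cut at the
  coarsest partition in which every cluster's *inner variance* — mean
  squared Euclidean distance to the centroid, mm² — is ≤ 20 (RMS radius
  √20 ≈ 4.5 mm).  Within a cluster each run counts once, via its member
  nearest the raw centroid; a cluster is stable with ≥ 4 contributing runs
  out of 5.  For ≤ 6 peaks the cut provably matches exhaustive partition
  search in the test suite.
* **Voxel overlap** — R_ij = 2·V_ij/(V_i+V_j) between suprathreshold
  conjunction masks of session pairs (0 when both masks are empty),
  averaged over the 10 pairs per subject and then across subjects, at
  voxelwise p < 0.001/0.01/0.05 uncorrected; subjects with no activated
  in-ROI voxel in any session are excluded and the included n reported.

## Identification

Features per run come from the contrast or conjunction t maps: voxelwise
values over a combined ROI mask (e.g. bilateral FFA), per-ROI maximum t,
the mm coordinates of those maxima, or both; "combination" concatenates the
three contrasts' blocks.  A ROI whose maximum stays below the peak
threshold contributes sentinel features (t = 0, coordinates = ROI
centroid).  All features are z-scored with training-set statistics only;
zero-variance features map to 0.

**Leave-one-out SVM.**  Each run is held out in turn; standardization
statistics and linear one-vs-one SVMs (C = 1) come exclusively from the
remaining runs; the held-out run is classified by majority vote with ties
broken toward the lowest class index.  The one-vs-one loop is explicit
(binary `sklearn` SVCs) to keep the tie-break deterministic.  A linear
kernel with unit cost is the default because the hypothesis being tested is
a stable *spatial pattern*, linearly separable by construction, and it
keeps results deterministic; the kernel is configurable in the sense that
the surrounding code accepts any accuracy source.

**Hyperplane fingerprinting.**  For every (target subject, training run,
library subject) triple, the classifier is the plane through the midpoint
of the two training vectors with normal along their difference —
equivalently, nearest-of-two-exemplars — and the target's remaining runs
are classified by side; a point exactly on the plane counts as an error,
and identical training vectors raise an error.  A 5×5 target group against
an 80-subject single-run library yields 2000 hyperplanes and 8000
classifications.  Because a two-point training SD is degenerate,
standardization uses cohort-level statistics; the default pools target and
library runs, which treats the two cohorts symmetrically.  Standardizing
with the library alone is available but biased: each library vector enters
its own centering, so library norms shrink by ≈ (1−1/L) while target norms
grow by ≈ (1+1/L), and the bisector rule then favors the library side —
at L = 8 the null accuracy drops to ~29%.

**Significance.**  An accuracy is above chance at level α from the smallest
k with BinomialCDF(k; n, chance) ≥ 1−α, reported as 100·k/n.  With n = 25
trials this gives 32% at chance 0.2 and 68% at chance 0.5; the hyperplane
report uses n = S·R for its cutoff (the convention under which the 68%
figure arises; the 8000 classifications are heavily correlated, sharing
runs, so their pooled count would overstate the evidence).

Null behavior, verified by simulation with all subject templates identical
(target and library sharing one template): the hyperplane protocol is
exactly exchangeable and sits at 50%; leave-one-out SVM sits slightly
*below* 20% — the familiar pessimistic bias of LOO on null data, where the
held-out run's own class always has one fewer training exemplar — well
inside the 25-trial binomial interval.

## Numerical and degenerate-input conventions

Zero residual variance maps t to 0 after a 0/0 (noiseless data are exactly
interpolated, so contrast effects, not t values, are the meaningful output
there).  Zero between-subject variance in the group test yields ±inf with a
warning.  Smoothing rejects sheared affines.  Peak detection on a constant
plateau returns nothing (strict inequality).  Empty peak lists produce
empty cluster lists; empty masks raise.  Schedules are validated against
the scan length; rank-deficient designs raise with the collinear columns
named.

## Problem sizes in the test suite

Unit and property tests run on 16×16×12 grids with an abbreviated paradigm
(4 s blocks, 30 volumes).  The signal-recovery tests use the full default
conditions (32×32×24, 336 volumes, 5×5 cohort).  Null calibration runs 100
simulated cohorts on the small grid with an 8-subject library — library
size does not enter the null — while the 2000/8000 protocol combinatorics
are checked at the full 5×5×80 scale.  The recovery test restricts itself
to hemisphere-FFAs whose template has an unambiguous strongest source
(judged from ground truth only): twin blobs of near-equal amplitude make
the session maximum genuinely ill-defined, and border blobs whose true
maximum rasterizes just outside the ROI are deleted by the boundary rule
above, so neither configuration tests what "recovery" means.

## Known limitations

Voxelwise AR estimation, random-field-theory correction, spatial
normalization, motion/distortion handling, and nonlinear kernels are out of
scope.  The binomial cutoffs treat trials as independent, which the
protocols' trial structures only approximate.  Accuracies on synthetic
cohorts characterize the pipeline under the generator's assumptions; they
are not forecasts for real populations.
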