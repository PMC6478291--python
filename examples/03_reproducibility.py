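"""Within-subject reproducibility across 5 sessions of one subject.

Shows the three stability views: index-run peak matching (same or directly
surrounding voxel in >= 3 of 4 subsequent runs), Ward clustering of peaks
pooled over runs (stable: inner variance <= 20 mm^2 in >= 4 of 5 runs), and
the Dice-type overlap R_ij = 2*V_ij/(V_i+V_j) of suprathreshold masks.
"""

from faceprint import GLMOptions, build_schedule, make_atlas, make_subject_template, simulate_session
from faceprint.peaks import PeakDetectionParams, PeakSet, detect_peaks
from faceprint.pipeline import run_glm_for_session
from faceprint.reproducibility import (
    match_to_index_run,
    overlap_summary,
    ward_cluster_peaks,
)

atlas = make_atlas()
schedule = build_schedule(order_seed=1)
template = make_subject_template(atlas, subject_seed=5)

runs, conj_maps = [], []
for ses in range(5):
    session = simulate_session(template, schedule, session_seed=200 + ses)
    _, maps = run_glm_for_session(session, GLMOptions(), discard_initial=0)
    conj_maps.append(maps["conjunction"])
    runs.append(detect_peaks(maps["conjunction"], atlas,
                             PeakDetectionParams(1.65), run_id=f"ses-{ses + 1}",
                             polarity_map=maps["faces_vs_baseline"]))

report = match_to_index_run(runs)
n_rep = int(report["reproducible"].sum())
print(f"index-run peaks: {len(report)}, reproducible in >=3/4 later runs: {n_rep}")
print(report[report["is_roi_max"]][["roi", "t", "n_subsequent_hits", "reproducible"]]
      .to_string(index=False))

ffa_runs = [PeakSet(ps.in_roi("FFA_L"), ps.run_id) for ps in runs]
for cl in ward_cluster_peaks(ffa_runs):
    print(f"FFA_L Ward cluster: runs={cl.n_runs} "
          f"variance={cl.inner_variance_mm2:.1f} mm^2 stable={cl.stable}")

overlap = overlap_summary({"sub-05": conj_maps}, atlas.mask("FFA_L"))
overlap["overlap_pct"] = overlap["overlap_pct"].round(1)
print(overlap[["p_threshold", "overlap_pct", "n_pairs_per_subject"]]
      .to_string(index=False))
# Planted sources are session-stable, so the strongest peaks recur at the
# same coordinates and form tight Ward clusters.  Overlap is high at every
# threshold; with a strong planted signal the strict p<.001 mask keeps only
# the stable activation core, while lenient thresholds admit unstable noise
# voxels at the mask fringe (with weak signal the ordering reverses).
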