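"""Reading and writing the pipeline's on-disk formats.

Runs are 4D NIfTI-1, the atlas a 3D integer NIfTI with a JSON sidecar
carrying the label table, stimulus schedules BIDS-style ``events.tsv``
tables, statistic maps 3D NIfTI with a ``kind``/``df`` JSON sidecar, and the
cohort manifest a CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .glm import StatMap
from .synth import (
    Acquisition,
    CohortDataset,
    NoiseParams,
    ROIAtlas,
    ROIInfo,
    SessionRealization,
    StimulusSchedule,
)

__all__ = [
    "write_cohort",
    "write_statmap",
    "read_statmap",
    "write_atlas",
    "read_atlas",
    "read_events",
    "write_events",
    "read_manifest",
    "read_session",
]


def write_statmap(smap: StatMap, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(smap.values.astype(np.float32), smap.affine), path)
    sidecar = path.with_suffix("").with_suffix(".json")
    sidecar.write_text(
        json.dumps({"kind": smap.kind, "df": smap.df, "name": smap.name}, indent=1)
    )
    return path


def read_statmap(path) -> StatMap:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return StatMap(
        np.asarray(img.dataobj, dtype=float),
        meta["kind"],
        meta["df"],
        img.affine,
        meta.get("name", ""),
    )


def write_atlas(atlas: ROIAtlas, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine), path)
    table = {
        str(lab): {"name": i.name, "hemisphere": i.hemisphere, "response_class": i.response_class}
        for lab, i in atlas.rois.items()
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(table, indent=1))
    return path


def read_atlas(path) -> ROIAtlas:
    path = Path(path)
    img = nib.load(path)
    table = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    rois = {
        int(lab): ROIInfo(e["name"], e["hemisphere"], e["response_class"])
        for lab, e in table.items()
    }
    return ROIAtlas(np.asarray(img.dataobj, dtype=np.int16), img.affine, rois)


def write_events(schedule: StimulusSchedule, path) -> Path:
    path = Path(path)
    schedule.to_events_frame().to_csv(path, sep="\t", index=False)
    return path


def read_events(path) -> StimulusSchedule:
    frame = pd.read_csv(path, sep="\t")
    return StimulusSchedule.from_events_frame(frame)


def write_cohort(cohort: CohortDataset, out_dir) -> Path:
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    write_atlas(cohort.atlas, out_dir / "atlas.nii")
    for sess in cohort.sessions:
        stem = f"{sess.subject_id}_ses-{sess.session_index}"
        nib.save(
            nib.Nifti1Image(sess.series, sess.affine), out_dir / f"{stem}_bold.nii"
        )
        write_events(sess.schedule, out_dir / f"{stem}_events.tsv")
        (out_dir / f"{stem}_acq.json").write_text(
            json.dumps(
                {
                    "tr_s": sess.acquisition.tr_s,
                    "n_volumes": sess.acquisition.n_volumes,
                    "discard_initial": sess.acquisition.discard_initial,
                    "ar_coefficient": sess.noise_params.ar_coefficient,
                    "white_sd": sess.noise_params.white_sd,
                    "amplitude_jitter_sd": sess.noise_params.amplitude_jitter_sd,
                    "seed": sess.seed,
                }
            )
        )
    cohort.manifest.to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "config_used.json").write_text(
        json.dumps({"seed": cohort.seed, "n_runs": len(cohort.sessions)}, indent=1)
    )
    return out_dir


def read_manifest(data_dir) -> pd.DataFrame:
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    for _, row in manifest.iterrows():
        for col in ("series_path", "events_path"):
            if not (data_dir / row[col]).exists():
                raise FileNotFoundError(
                    f"manifest entry {row['subject']} ses-{row['session']}: "
                    f"missing {data_dir / row[col]}"
                )
    if manifest.duplicated(["subject", "session"]).any():
        raise ValueError("duplicate (subject, session) rows in manifest")
    return manifest


def read_session(data_dir, row) -> SessionRealization:
    """Load one manifest row back into a SessionRealization."""
    data_dir = Path(data_dir)
    img = nib.load(data_dir / row["series_path"])
    schedule = read_events(data_dir / row["events_path"])
    stem = f"{row['subject']}_ses-{row['session']}"
    meta = json.loads((data_dir / f"{stem}_acq.json").read_text())
    return SessionRealization(
        subject_id=row["subject"],
        session_index=int(row["session"]),
        series=np.asarray(img.dataobj, dtype=np.float32),
        schedule=schedule,
        acquisition=Acquisition(meta["tr_s"], meta["n_volumes"], meta["discard_initial"]),
        noise_params=NoiseParams(
            meta["ar_coefficient"], meta["white_sd"], meta["amplitude_jitter_sd"]
        ),
        affine=img.affine,
        seed=meta["seed"],
    )
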