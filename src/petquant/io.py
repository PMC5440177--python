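"""File formats: NIfTI images, blood/TAC/ppIF CSV tables, manifest JSON.

CSV dialect: UTF-8, '.' decimal, header row.  Images are NIfTI-1 with the
voxel size carried in the affine; parametric maps are float32 with NaN as
the missing-value code.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .frames import FrameSchedule, build_frame_schedule
from .input_function import BloodSamples, PlasmaInputFunction


def save_nifti(path, data: np.ndarray, voxel_size_mm=(4.0, 4.0, 4.0)) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple]:
    img = nib.load(str(path))
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), vs


def schedule_to_json(schedule: FrameSchedule, path) -> None:
    spec = []
    durations = schedule.frame_duration
    for d in durations:
        if spec and spec[-1]["duration_s"] == d:
            spec[-1]["count"] += 1
        else:
            spec.append({"count": 1, "duration_s": float(d)})
    payload = {"frames": spec,
               "injection_time_s": schedule.injection_time,
               "decay_constant_per_s": schedule.decay_constant}
    Path(path).write_text(json.dumps(payload, indent=2))


def schedule_from_json(path) -> FrameSchedule:
    payload = json.loads(Path(path).read_text())
    spec = [(f["count"], f["duration_s"]) for f in payload["frames"]]
    return build_frame_schedule(spec, payload["injection_time_s"],
                                payload["decay_constant_per_s"])


def blood_to_csv(blood: BloodSamples, path) -> None:
    """One row per sample; the 'source' column separates the continuous
    detector stream from the discrete syringe samples."""
    cont = pd.DataFrame({
        "time_s": blood.continuous_time,
        "whole_blood_kBq_per_ml": blood.continuous_whole_blood,
        "plasma_kBq_per_ml": np.nan, "parent_fraction": np.nan,
        "source": "continuous"})
    disc = pd.DataFrame({
        "time_s": blood.discrete_time,
        "whole_blood_kBq_per_ml": blood.discrete_whole_blood,
        "plasma_kBq_per_ml": blood.discrete_plasma,
        "parent_fraction": blood.parent_fraction,
        "source": "discrete"})
    pd.concat([cont, disc]).to_csv(path, index=False)


def blood_from_csv(path) -> BloodSamples:
    df = pd.read_csv(path)
    cont = df[df["source"] == "continuous"].sort_values("time_s")
    disc = df[df["source"] == "discrete"].sort_values("time_s")
    return BloodSamples(
        continuous_time=cont["time_s"].to_numpy(),
        continuous_whole_blood=cont["whole_blood_kBq_per_ml"].to_numpy(),
        discrete_time=disc["time_s"].to_numpy(),
        discrete_whole_blood=disc["whole_blood_kBq_per_ml"].to_numpy(),
        discrete_plasma=disc["plasma_kBq_per_ml"].to_numpy(),
        parent_fraction_time=disc["time_s"].to_numpy(),
        parent_fraction=disc["parent_fraction"].to_numpy(),
    )


def ppif_to_csv(ppif: PlasmaInputFunction, path) -> None:
    pd.DataFrame({
        "time_s": ppif.time,
        "parent_plasma_kBq_per_ml": ppif.parent_plasma,
        "whole_blood_kBq_per_ml": ppif.whole_blood,
    }).to_csv(path, index=False)


def tac_to_csv(schedule: FrameSchedule, activity: np.ndarray, path,
               decay_corrected: bool = True) -> None:
    df = pd.DataFrame({
        "frame_index": np.arange(1, schedule.n_frames + 1),
        "t_start_s": schedule.frame_start,
        "t_end_s": schedule.frame_end,
        "activity_kBq_per_ml": activity,
    })
    with open(path, "w") as fh:
        fh.write(f"# decay_corrected={str(decay_corrected).lower()}\n")
        df.to_csv(fh, index=False)
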