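"""File I/O for the formats the pipeline touches.

Volumes travel as NIfTI-1 (via nibabel) with a diagonal affine carrying the
voxel size; frame timing as a JSON sidecar; TACs, subject tables and reports
as TSV; configuration as JSON or YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .kinetics import FrameSchedule, InputError, TimeActivityCurve

__all__ = [
    "write_dynamic",
    "read_dynamic",
    "write_map",
    "read_map",
    "write_tac_tsv",
    "read_tac_tsv",
    "write_subject_table",
    "read_subject_table",
    "load_config",
]


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def write_dynamic(
    path,
    image: np.ndarray,
    schedule: FrameSchedule,
    timing_path,
    voxel_size=(2.0, 2.0, 2.0),
) -> None:
    """Write a 4D dynamic volume plus its frame-timing JSON sidecar."""
    image = np.asarray(image)
    if image.ndim != 4:
        raise InputError("expected a 4D dynamic image (x, y, z, frames)")
    if image.shape[3] != schedule.n_frames:
        raise InputError("image frame count must match the schedule")
    nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float32), _affine(voxel_size)), str(path))
    schedule.to_json(timing_path)


def read_dynamic(path, timing_path) -> tuple[np.ndarray, FrameSchedule, np.ndarray]:
    """Read a 4D dynamic volume and validate it against its timing sidecar.

    Returns ``(data, schedule, affine)``.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise InputError(f"expected a 4D dynamic image, got {data.ndim}D")
    schedule = FrameSchedule.from_json(timing_path)  # contiguity validated on load
    if data.shape[3] != schedule.n_frames:
        raise InputError(
            f"timing lists {schedule.n_frames} frames but image has {data.shape[3]}"
        )
    return data, schedule, img.affine


def write_map(path, map3d: np.ndarray, voxel_size=(2.0, 2.0, 2.0)) -> None:
    """Write a 3D parametric map (float32, missing = NaN)."""
    m = np.asarray(map3d)
    if m.ndim != 3:
        raise InputError("expected a 3D map")
    nib.save(nib.Nifti1Image(m.astype(np.float32), _affine(voxel_size)), str(path))


def read_map(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise InputError(f"expected a 3D map, got {data.ndim}D")
    return data


def write_tac_tsv(path, tac: TimeActivityCurve, schedule: FrameSchedule) -> None:
    df = pd.DataFrame(
        {
            "frame_start_s": schedule.frame_start,
            "frame_duration_s": schedule.frame_duration,
            "value_kBq_per_mL": tac.values,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_tac_tsv(path) -> tuple[TimeActivityCurve, FrameSchedule]:
    df = pd.read_csv(path, sep="\t")
    schedule = FrameSchedule(
        df["frame_start_s"].to_numpy(), df["frame_duration_s"].to_numpy()
    )
    return TimeActivityCurve(schedule.mid_times, df["value_kBq_per_mL"].to_numpy()), schedule


def write_subject_table(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep="")


def read_subject_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path) -> dict:
    """Load a JSON or YAML configuration file by extension."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
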