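"""NIfTI-1 and tabular I/O plus frame-schedule sidecars.

Images travel as NIfTI-1; dynamic (4-D) images additionally require a
two-column TSV sidecar of (start_s, duration_s) per frame, because frame
timing does not belong in the NIfTI header.  Round trips preserve voxel
data bit-exactly and the affine to float precision.  Tables are TSV with a
header row; configs and model files are YAML/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import DynamicImage, FrameSchedule, LabelMap, StatImage

__all__ = [
    "read_image",
    "write_image",
    "read_schedule",
    "write_schedule",
    "write_table",
    "read_table",
    "load_config",
    "save_config",
    "voxel_volume_mm3",
    "default_schedule_path",
]


def default_schedule_path(image_path) -> Path:
    p = Path(image_path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + "_frames.tsv")
    return p.with_suffix(".tsv")


def write_schedule(schedule: FrameSchedule, path) -> Path:
    df = pd.DataFrame({"start_s": schedule.starts, "duration_s": schedule.durations})
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_schedule(path) -> FrameSchedule:
    df = pd.read_csv(path, sep="\t")
    for col in ("start_s", "duration_s"):
        if col not in df.columns:
            raise ValueError(f"schedule sidecar {path} lacks column {col!r}")
    return FrameSchedule(df["start_s"].to_numpy(float), df["duration_s"].to_numpy(float))


def write_image(image, path, schedule_path=None) -> Path:
    """Write a StatImage / LabelMap / DynamicImage as NIfTI-1.

    Dynamic images also write their frame-schedule sidecar (default:
    ``<stem>_frames.tsv`` next to the image).
    """
    path = Path(path)
    if isinstance(image, DynamicImage):
        nib.save(nib.Nifti1Image(image.data, image.affine), path)
        write_schedule(image.schedule, schedule_path or default_schedule_path(path))
    elif isinstance(image, LabelMap):
        nib.save(nib.Nifti1Image(image.data.astype(np.int32), image.affine), path)
    elif isinstance(image, StatImage):
        nib.save(nib.Nifti1Image(image.data, image.affine), path)
    else:
        data = np.asarray(image)
        raise TypeError(f"unsupported image type {type(image).__name__} ({data.ndim}-D)")
    return path


def read_image(path, schedule_path=None, tag: str = "activity"):
    """Read a NIfTI-1 file back into the matching container.

    3-D integer volumes become LabelMap, 3-D floats StatImage, 4-D volumes
    DynamicImage (the frame-schedule sidecar is required and must match the
    frame count).
    """
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    affine = img.affine
    if data.ndim == 4:
        sp = Path(schedule_path) if schedule_path else default_schedule_path(path)
        if not sp.exists():
            raise FileNotFoundError(
                f"dynamic image {path} requires frame-schedule sidecar {sp}"
            )
        schedule = read_schedule(sp)
        if schedule.n_frames != data.shape[3]:
            raise ValueError(
                f"sidecar has {schedule.n_frames} frames, image has {data.shape[3]}"
            )
        return DynamicImage(data.astype(float), affine, schedule)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D or 4-D image, got {data.ndim}-D")
    if np.issubdtype(data.dtype, np.integer):
        return LabelMap(data, affine)
    return StatImage(data.astype(float), affine, tag=tag)


def voxel_volume_mm3(affine) -> float:
    return float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))


def write_table(df: pd.DataFrame, path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(cfg: dict, path) -> Path:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return path
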