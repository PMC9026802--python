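"""Format adapters: NIfTI volumes, curve/feature CSVs, JSON and YAML."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import FEATURE_COLUMNS, LABEL_COLUMNS
from .phantom import Phantom
from .relaxometry import ConcentrationCurve, SignalCurve


def _affine_from_spacing(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def write_4d_nifti(path, data: np.ndarray, spacing_mm, frame_spacing_s: float) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine_from_spacing(spacing_mm))
    zooms = tuple(spacing_mm) + (frame_spacing_s,)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def write_3d_nifti(path, data: np.ndarray, spacing_mm, integer: bool = False) -> None:
    dtype = np.int16 if integer else np.float64
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), _affine_from_spacing(spacing_mm))
    img.header.set_zooms(tuple(spacing_mm))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_nifti(path) -> Tuple[np.ndarray, Tuple[float, ...]]:
    """Returns (data array, voxel zooms from the header)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms())
    return data, zooms


def roi_mean_signal(img4d: np.ndarray, mask: np.ndarray, label: int) -> np.ndarray:
    """Arithmetic mean over mask voxels, per frame."""
    if img4d.ndim != 4 or mask.ndim != 3:
        raise ValueError("need a 4-D image and a 3-D mask")
    if img4d.shape[:3] != mask.shape:
        raise ValueError("image and mask grids disagree")
    sel = mask == label
    if not np.any(sel):
        raise ValueError(f"no voxels with label {label}")
    return img4d[sel].mean(axis=0)


def write_phantom(phantom: Phantom, outdir) -> Dict[str, Path]:
    """Write the phantom as NIfTI volumes plus a JSON ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp = phantom.spec.spacing_mm
    paths = {
        "dynamic": outdir / "dynamic.nii.gz",
        "calib_low": outdir / "calib_low.nii.gz",
        "calib_high": outdir / "calib_high.nii.gz",
        "mask": outdir / "mask.nii.gz",
        "truth": outdir / "truth.json",
    }
    write_4d_nifti(paths["dynamic"], phantom.dynamic, sp, phantom.spec.frame_spacing_s)
    write_3d_nifti(paths["calib_low"], phantom.calib_low, sp)
    write_3d_nifti(paths["calib_high"], phantom.calib_high, sp)
    write_3d_nifti(paths["mask"], phantom.mask, sp, integer=True)
    truth = {str(k): v for k, v in phantom.truth.items()}
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths


# ---------------------------------------------------------------------------
# curves and tables


def write_curve_csv(path, curve) -> None:
    pd.DataFrame({"time_s": curve.times_s, "value": curve.values}).to_csv(path, index=False)


def read_curve_csv(path, kind: str = "concentration", flip_deg: Optional[float] = None):
    df = pd.read_csv(path)
    missing = {"time_s", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"curve CSV missing columns: {sorted(missing)}")
    if kind == "concentration":
        return ConcentrationCurve(times_s=df["time_s"].to_numpy(),
                                  values=df["value"].to_numpy())
    if kind == "signal":
        if flip_deg is None:
            raise ValueError("signal curves need flip_deg")
        return SignalCurve(times_s=df["time_s"].to_numpy(),
                           values=df["value"].to_numpy(), flip_deg=flip_deg)
    raise ValueError(f"unknown curve kind '{kind}'")


def write_feature_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path, require_labels: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = set(FEATURE_COLUMNS) | (set(LABEL_COLUMNS) if require_labels else set())
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return df


def load_yaml(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError("config must be a YAML mapping")
    return out


def dump_yaml(path, obj: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
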