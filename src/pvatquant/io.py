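"""Readers and writers: NIfTI/TIFF images, masks, cohort CSV, YAML/JSON.

The long-format cohort CSV is the single interchange between the imaging
and statistics stages.  Columns (data dictionary):

    patient_id    str    patient identifier
    vessel_class  str    aorta | carotid | left/right common/internal/external carotid
    slice_index   int    slice position within the patient's stack (shared labels)
    angle_deg     float  cord angle, degrees clockwise from the zero direction
    wall_mm       float  wall thickness along the cord (mm)
    pvat_mm       float  PVAT thickness within the extent window (mm)
    normal_flag   bool   True if the slice is classified normal
    flags         int    optional per-cord warning bitmask

All lengths are mm; all angles are degrees on the 5-deg grid.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

COHORT_COLUMNS = ["patient_id", "vessel_class", "slice_index", "angle_deg",
                  "wall_mm", "pvat_mm", "normal_flag"]


# ---------------------------------------------------------------- images

def write_nifti(path, image: np.ndarray, pixel_spacing_mm: float) -> None:
    """Write a 2-D image as NIfTI with isotropic in-plane spacing (mm)."""
    import nibabel as nib

    affine = np.diag([pixel_spacing_mm, pixel_spacing_mm, 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(image, dtype=np.float32), affine)
    img.header.set_zooms((pixel_spacing_mm, pixel_spacing_mm))
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, float]:
    """Read a 2-D NIfTI image; returns (array, pixel_spacing_mm)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D slice, got shape {data.shape}")
    zooms = img.header.get_zooms()[:2]
    if not np.isclose(zooms[0], zooms[1]):
        raise ValueError(f"{path}: anisotropic in-plane spacing {zooms} unsupported")
    sp = float(zooms[0])
    if sp <= 0:
        raise ValueError(f"{path}: missing or nonpositive pixel spacing")
    return data, sp


def write_tiff(path, image: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_tiff(path, pixel_spacing_mm: Optional[float] = None) -> tuple[np.ndarray, float]:
    """Read a TIFF slice.  TIFF carries no reliable mm spacing, so the
    spacing must come from the sidecar manifest; absent -> error."""
    import tifffile

    if pixel_spacing_mm is None or not pixel_spacing_mm > 0:
        raise ValueError(
            f"{path}: TIFF has no pixel-spacing metadata; provide "
            "pixel_spacing_mm via the sidecar manifest"
        )
    data = np.asarray(tifffile.imread(str(path)), dtype=float)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D slice, got shape {data.shape}")
    return data, float(pixel_spacing_mm)


def read_image(path, pixel_spacing_mm: Optional[float] = None) -> tuple[np.ndarray, float]:
    """Dispatch on suffix: .nii/.nii.gz via NIfTI, .tif/.tiff via TIFF."""
    p = Path(path)
    name = p.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return read_nifti(p)
    if name.endswith((".tif", ".tiff")):
        return read_tiff(p, pixel_spacing_mm)
    raise ValueError(f"{path}: unsupported image format")


def write_mask(path, mask: np.ndarray, pixel_spacing_mm: float) -> None:
    """Write a binary mask as an 8-bit image with the same geometry."""
    arr = np.asarray(mask).astype(np.uint8)
    name = str(path).lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([pixel_spacing_mm, pixel_spacing_mm, 1.0, 1.0])
        img = nib.Nifti1Image(arr, affine)
        img.header.set_zooms((pixel_spacing_mm, pixel_spacing_mm))
        nib.save(img, str(path))
    else:
        import tifffile

        tifffile.imwrite(str(path), arr)


def read_mask(path, pixel_spacing_mm: Optional[float] = None) -> np.ndarray:
    data, _ = read_image(path, pixel_spacing_mm=pixel_spacing_mm or 1.0)
    return data > 0


# ---------------------------------------------------------------- tables

def write_cohort(path, cohort: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    # %.17g guarantees float64 round-trip to full precision
    cohort.to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort CSV missing columns {missing}")
    df["normal_flag"] = df["normal_flag"].astype(bool)
    return df


# ---------------------------------------------------------------- config / results

def write_yaml(path, obj: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return out


def write_json(path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
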