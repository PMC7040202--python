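"""Readers and writers for every on-disk artifact.

Volumes are NIfTI-1 (``.nii``/``.nii.gz``) or NRRD (``.nrrd``); clinical and
feature tables are comma-separated UTF-8 CSV with a header row and dot
decimals; models and reports are JSON.  Volumes are re-oriented to the LPS
anatomical convention on load (when the header carries an orientation) so
texture direction labels mean the same thing for every input file.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .errors import EmptyVOIError, FormatError, ValidationError
from .grids import ImageVolume, MaskVolume, validate_pair

VOLUME_SUFFIXES = (".nii", ".nii.gz", ".nrrd")

CLINICAL_COLUMNS = [
    "patient_id",
    "sex",
    "age_years",
    "smoking",
    "pfs_days",
    "event",
    "cohort_label",
]

_SEX_LEVELS = {"male", "female"}
_SMOKING_LEVELS = {"smoker", "nonsmoker"}


def _check_suffix(path: str | Path) -> None:
    name = str(path).lower()
    if not any(name.endswith(s) for s in VOLUME_SUFFIXES):
        raise FormatError(
            f"{path}: unsupported volume format (expected one of {VOLUME_SUFFIXES})"
        )


def _read_sitk(path: str | Path) -> sitk.Image:
    if not os.path.exists(path):
        raise FormatError(f"{path}: file does not exist")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # SimpleITK raises RuntimeError on bad files
        raise FormatError(f"{path}: unreadable volume ({exc})") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {img.GetDimension()}D")
    try:
        img = sitk.DICOMOrient(img, "LPS")
    except Exception:
        # identity/missing direction cosines: keep the stored axis order
        pass
    spacing = img.GetSpacing()
    if any((not np.isfinite(s)) or s <= 0 for s in spacing):
        raise FormatError(f"{path}: missing or non-positive voxel spacing {spacing}")
    return img


def read_image(path: str | Path) -> ImageVolume:
    """Read a CT volume from NIfTI or NRRD."""
    img = _read_sitk(path)
    arr = sitk.GetArrayFromImage(img).astype(np.float64)  # (z, y, x)
    if not np.all(np.isfinite(arr)):
        raise FormatError(f"{path}: volume contains non-finite intensities")
    return ImageVolume(
        voxels=arr,
        spacing=tuple(reversed(img.GetSpacing())),
        origin=tuple(reversed(img.GetOrigin())),
    )


def read_mask(path: str | Path, reference: ImageVolume) -> MaskVolume:
    """Read a VOI mask, binarize at > 0 and check it against ``reference``."""
    img = _read_sitk(path)
    arr = sitk.GetArrayFromImage(img)
    binar = (arr > 0).astype(np.uint8)
    if binar.sum() == 0:
        raise EmptyVOIError(f"{path}: mask has no foreground voxels")
    mask = MaskVolume(
        voxels=binar,
        spacing=tuple(reversed(img.GetSpacing())),
        origin=tuple(reversed(img.GetOrigin())),
    )
    validate_pair(reference, mask)
    return mask


def _to_sitk(voxels: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(voxels)
    img.SetSpacing(tuple(reversed([float(s) for s in spacing])))
    img.SetOrigin(tuple(reversed([float(o) for o in origin])))
    return img


def write_image(vol: ImageVolume, path: str | Path) -> None:
    _check_suffix(path)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_to_sitk(vol.voxels, vol.spacing, vol.origin), str(path))


def write_mask(mask: MaskVolume, path: str | Path) -> None:
    _check_suffix(path)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_to_sitk(mask.voxels, mask.spacing, mask.origin), str(path))


# ---------------------------------------------------------------------------
# clinical table


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Type, normalize and validate a clinical table in place."""
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"clinical table missing columns {missing}")
    df = df[CLINICAL_COLUMNS].copy()
    df["patient_id"] = df["patient_id"].astype(str)
    dup = df["patient_id"][df["patient_id"].duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate patient_id values: {list(dup)}")
    for col, levels in (("sex", _SEX_LEVELS), ("smoking", _SMOKING_LEVELS)):
        df[col] = df[col].astype(str).str.strip().str.lower()
        bad = sorted(set(df[col]) - levels)
        if bad:
            raise ValidationError(f"column {col!r}: unknown levels {bad}")
    df["age_years"] = pd.to_numeric(df["age_years"])
    df["pfs_days"] = pd.to_numeric(df["pfs_days"])
    df["event"] = pd.to_numeric(df["event"])
    if (df["age_years"] <= 0).any():
        raise ValidationError("age_years must be positive")
    if (df["pfs_days"] <= 0).any():
        bad_ids = df.loc[df["pfs_days"] <= 0, "patient_id"].tolist()
        raise ValidationError(f"pfs_days must be positive (patients {bad_ids})")
    if not df["event"].isin([0, 1]).all():
        raise ValidationError("event must be 0 or 1")
    df["event"] = df["event"].astype(int)
    df["cohort_label"] = df["cohort_label"].astype(str)
    return df.reset_index(drop=True)


def read_clinical(path: str | Path) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FormatError(f"{path}: file does not exist")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    return validate_clinical(df)


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df = validate_clinical(df)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# feature table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-patient feature table (index = patient_id) to CSV.

    Floating values keep >= 17 significant digits so write-then-read is
    stable to 1e-9 relative and better.
    """
    if table.index.name != "patient_id":
        raise ValidationError("feature table index must be named 'patient_id'")
    if table.isna().any().any():
        raise ValidationError("feature table contains missing values")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, float_format="%.17g")


def read_feature_table(path: str | Path, expected_columns: Iterable[str] | None = None) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FormatError(f"{path}: file does not exist")
    df = pd.read_csv(path, index_col="patient_id")
    df.index = df.index.astype(str)
    if expected_columns is not None:
        expected = list(expected_columns)
        if list(df.columns) != expected:
            raise ValidationError(
                f"{path}: feature columns do not match the registry "
                f"({len(df.columns)} found, {len(expected)} expected)"
            )
    return df


# ---------------------------------------------------------------------------
# JSON artifacts (models, reports, selection results)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    if not os.path.exists(path):
        raise FormatError(f"{path}: file does not exist")
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
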