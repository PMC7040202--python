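"""Preprocessing before texture computation: resampling, gray-level
discretization and the undecimated wavelet channel bank."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
import warnings

import numpy as np
import pywt
import SimpleITK as sitk
from scipy.ndimage import correlate1d

from .errors import EmptyVOIError, ValidationError
from .grids import ImageVolume, MaskVolume, validate_pair

WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


@dataclass(frozen=True)
class DiscretizationSpec:
    """Equal-width binning of VOI intensities into ``n_levels`` gray levels."""

    n_levels: int = 32

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValidationError("need at least 2 gray levels")


def resample_isotropic(
    img: ImageVolume, mask: MaskVolume, target_mm: float = 1.0
) -> tuple[ImageVolume, MaskVolume]:
    """Resample an image/mask pair onto an isotropic grid.

    Intensities are trilinear-interpolated, the mask nearest-neighbour and
    re-binarized.  Inputs already on the target grid are returned unchanged
    (no interpolation error is introduced).
    """
    validate_pair(img, mask)
    if target_mm <= 0:
        raise ValidationError("target spacing must be positive")
    if all(abs(s - target_mm) < 1e-9 for s in img.spacing):
        return img, mask

    def _resample(vol_arr, spacing, origin, interpolator):
        im = sitk.GetImageFromArray(vol_arr)
        im.SetSpacing(tuple(reversed([float(s) for s in spacing])))
        im.SetOrigin(tuple(reversed([float(o) for o in origin])))
        old_size = np.array(vol_arr.shape[::-1], dtype=float)  # (x, y, z)
        old_sp = np.array(spacing[::-1], dtype=float)
        new_size = np.maximum(1, np.ceil(old_size * old_sp / target_mm)).astype(int)
        out = sitk.Resample(
            im,
            [int(v) for v in new_size],
            sitk.Transform(),
            interpolator,
            im.GetOrigin(),
            (target_mm,) * 3,
            im.GetDirection(),
            0.0,
            im.GetPixelID(),
        )
        return sitk.GetArrayFromImage(out), tuple(reversed(out.GetOrigin()))

    img_arr, origin = _resample(
        img.voxels, img.spacing, img.origin, sitk.sitkLinear
    )
    mask_arr, _ = _resample(
        mask.voxels.astype(np.float64), mask.spacing, mask.origin, sitk.sitkNearestNeighbor
    )
    mask_arr = (mask_arr > 0.5).astype(np.uint8)
    if mask_arr.sum() == 0:
        raise EmptyVOIError(
            f"VOI vanished after resampling to {target_mm} mm isotropic"
        )
    new_img = ImageVolume(voxels=img_arr, spacing=(target_mm,) * 3, origin=origin)
    new_mask = MaskVolume(voxels=mask_arr, spacing=(target_mm,) * 3, origin=origin)
    return new_img, new_mask


def crop_to_voi(
    img: ImageVolume, mask: MaskVolume, margin: int = 6
) -> tuple[ImageVolume, MaskVolume]:
    """Crop both volumes to the VOI bounding box plus ``margin`` voxels.

    The margin keeps enough context for the wavelet filter support so
    filtered values inside the VOI are unaffected by the crop.
    """
    idx = mask.indices()
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    origin = tuple(
        o + a * s for o, a, s in zip(img.origin, lo, img.spacing)
    )
    return (
        ImageVolume(voxels=img.voxels[sl], spacing=img.spacing, origin=origin),
        MaskVolume(voxels=mask.voxels[sl], spacing=mask.spacing, origin=origin),
    )


def discretize(
    img: ImageVolume, mask: MaskVolume, spec: DiscretizationSpec = DiscretizationSpec()
) -> tuple[np.ndarray, bool]:
    """Map VOI intensities to gray levels 1..Ng, equal-width over [min, max].

    Returns ``(levels, constant_flag)``: ``levels`` holds 0 outside the VOI;
    a constant VOI maps every voxel to level 1 and sets the flag.
    """
    inside = mask.voxels > 0
    if not inside.any():
        raise EmptyVOIError("cannot discretize an empty VOI")
    vals = img.voxels[inside]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(img.shape, dtype=np.int32)
    if hi == lo:
        levels[inside] = 1
        return levels, True
    ng = spec.n_levels
    binned = np.floor((img.voxels[inside] - lo) / (hi - lo) * ng).astype(np.int32) + 1
    levels[inside] = np.clip(binned, 1, ng)
    return levels, False


def _band_filters(wavelet: str = "coif1") -> dict[str, np.ndarray]:
    w = pywt.Wavelet(wavelet)
    return {"L": np.asarray(w.dec_lo), "H": np.asarray(w.dec_hi)}


def wavelet_channels(
    img: ImageVolume, mask: MaskVolume | None = None, wavelet: str = "coif1"
) -> dict[str, ImageVolume]:
    """Single-level undecimated 3D wavelet decomposition into 8 sub-bands.

    Each band label has one letter per array axis (z, y, x); the band is the
    separable application of the low- (L) or high-pass (H) decomposition
    filter along that axis, with reflection boundary handling.  Outputs keep
    the input shape, so the original mask applies unchanged.
    """
    filters = _band_filters(wavelet)
    support = len(filters["L"])
    if mask is not None:
        idx = mask.indices()
        extent = idx.max(axis=0) - idx.min(axis=0) + 1
        if int(extent.min()) < support:
            warnings.warn(
                f"VOI extent {tuple(int(e) for e in extent)} is smaller than the "
                f"{wavelet} filter support ({support}); reflection padding dominates",
                stacklevel=2,
            )
    out: dict[str, ImageVolume] = {}
    for letters in product("LH", repeat=3):
        band = "".join(letters)
        arr = img.voxels
        for axis, letter in enumerate(letters):
            arr = correlate1d(arr, filters[letter], axis=axis, mode="reflect")
        out[band] = ImageVolume(voxels=arr, spacing=img.spacing, origin=img.origin)
    return out
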