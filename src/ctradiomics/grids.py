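"""In-memory containers for CT volumes and tumor masks.

Canonical axis convention
-------------------------
Voxel arrays are indexed ``(z, y, x)`` — slice, row, column — matching
``SimpleITK.GetArrayFromImage``.  ``spacing`` and ``origin`` are stored in
the same ``(z, y, x)`` order, in millimetres.  Files are re-oriented to LPS
on load so that direction labels are reproducible across inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyVOIError, GridMismatchError, ValidationError

#: tolerance (mm) for spacing/origin agreement between an image and its mask
GRID_TOL_MM = 1e-4


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical voxel geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Intensities in HU-like units.
    spacing : tuple of float
        Per-axis physical step in mm, ``(z, y, x)`` order.
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0) in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"expected a 3D voxel grid, got ndim={self.voxels.ndim}"
            )
        if min(self.voxels.shape) < 1:
            raise ValidationError("grid must have at least one voxel per axis")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacings must be three positive numbers, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class MaskVolume:
    """A binary VOI on the same grid as its paired :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    require_nonempty: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError(f"mask values must be 0/1, found levels {uniq[:10]}")
        self.voxels = vox.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.voxels.ndim != 3:
            raise ValidationError(f"expected a 3D mask, got ndim={self.voxels.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacings must be positive, got {self.spacing}")
        if self.require_nonempty and self.voxels.sum() == 0:
            raise EmptyVOIError("mask has no foreground voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def indices(self) -> np.ndarray:
        """Foreground voxel indices, shape (n, 3), (z, y, x) order."""
        return np.argwhere(self.voxels > 0)


def validate_pair(img: ImageVolume, mask: MaskVolume, tol_mm: float = GRID_TOL_MM) -> None:
    """Check that image and mask share shape, spacing and origin.

    The check is symmetric in the two grids' metadata.  Raises
    :class:`GridMismatchError` on disagreement beyond ``tol_mm``.
    """
    if img.shape != mask.shape:
        raise GridMismatchError(
            f"image shape {img.shape} != mask shape {mask.shape}"
        )
    d_sp = max(abs(a - b) for a, b in zip(img.spacing, mask.spacing))
    d_or = max(abs(a - b) for a, b in zip(img.origin, mask.origin))
    if d_sp > tol_mm or d_or > tol_mm:
        raise GridMismatchError(
            "image grid (spacing={}, origin={}) does not match mask grid "
            "(spacing={}, origin={}) within {} mm".format(
                img.spacing, img.origin, mask.spacing, mask.origin, tol_mm
            )
        )
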