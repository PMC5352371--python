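"""Binary segmentation masks with physical voxel spacing.

The mask is the geometric substrate for all volumetry: a 3D boolean array
whose axes are ordered (in-plane-x, in-plane-y, slice), together with the
per-axis voxel size in millimetres.  Masks are read from and written to
NIfTI (.nii/.nii.gz) and NRRD files; any nonzero voxel value counts as
foreground.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import EmptyMaskError, ParameterError

__all__ = ["SegmentationMask", "read_mask", "write_mask"]


@dataclass(frozen=True)
class SegmentationMask:
    """3D binary voxel grid with physical spacing.

    Parameters
    ----------
    voxels
        3D array; nonzero = tumor.  Stored as bool.
    spacing
        Per-axis voxel size in mm, ordered (in-plane-x, in-plane-y, slice).
    origin
        Physical offset in mm (informational; carried through I/O).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ParameterError(f"mask must be 3-dimensional, got ndim={vox.ndim}")
        object.__setattr__(self, "voxels", vox.astype(bool))
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ParameterError(f"spacing must be 3 positive lengths in mm, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def require_nonempty(self, op: str = "feature computation") -> None:
        if self.is_empty:
            raise EmptyMaskError(f"{op} requires at least one foreground voxel")

    def foreground_coordinates_mm(self) -> np.ndarray:
        """(n, 3) physical coordinates of foreground voxel centers, in mm."""
        idx = np.argwhere(self.voxels)
        return idx * np.asarray(self.spacing)


def read_mask(path: str | Path) -> SegmentationMask:
    """Read a NIfTI or NRRD file as a binary mask; spacing comes from the header."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise ParameterError(f"{path}: expected a 3D image, got ndim={arr.ndim}")
    voxels = np.transpose(arr, (2, 1, 0)) != 0  # -> (x, y, z)
    return SegmentationMask(voxels, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    """Write a mask as uint8 NIfTI/NRRD (format chosen by file extension)."""
    arr = np.transpose(mask.voxels.astype(np.uint8), (2, 1, 0))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(mask.spacing)
    img.SetOrigin(mask.origin)
    sitk.WriteImage(img, str(path))
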