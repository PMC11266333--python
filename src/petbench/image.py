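"""Volumetric image container with NIfTI round-trip."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class ImageVolume:
    """3D image with voxel size and origin metadata (mm).

    ``origin_mm`` is the physical position of the centre of voxel
    (0, 0, 0); axes are (x, y, z) with z the scanner axis.
    """

    values: np.ndarray
    voxel_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        return self.origin_mm[axis] + np.arange(self.shape[axis]) * self.voxel_mm[axis]

    @classmethod
    def centred(cls, values: np.ndarray, voxel_mm) -> "ImageVolume":
        """Image whose grid is centred on the physical origin."""
        origin = tuple(-(n - 1) / 2.0 * v for n, v in zip(values.shape, voxel_mm))
        return cls(values, tuple(float(v) for v in voxel_mm), origin)

    def save(self, path: str | Path) -> None:
        affine = np.diag(list(self.voxel_mm) + [1.0])
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(np.asarray(self.values, dtype=np.float64), affine),
                 str(path))

    @classmethod
    def load(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        affine = img.affine
        return cls(
            values=np.asarray(img.get_fdata()),
            voxel_mm=tuple(float(affine[i, i]) for i in range(3)),
            origin_mm=tuple(float(affine[i, 3]) for i in range(3)),
        )
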