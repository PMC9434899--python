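"""Minimal 3-D volume container with voxel spacing and NIfTI-1 round-trip.

Array axes follow the (x, y, z) = (left-right, posterior-anterior,
inferior-superior) convention used throughout the package: increasing index
along axis 1 moves anteriorly, along axis 2 superiorly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid"]


@dataclass
class VolumeGrid:
    """A 3-D scalar or label array plus voxel spacing in mm.

    Parameters
    ----------
    data
        3-D array; float for intensities/probabilities, integer for labels.
    spacing
        Voxel edge lengths in mm, one per axis.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"invalid spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """A new grid with the same spacing and new data."""
        return VolumeGrid(data, self.spacing)

    # -- NIfTI-1 I/O ---------------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.spacing) + [1.0])
        data = self.data
        if data.dtype == bool:
            data = data.astype(np.uint8)
        return nib.Nifti1Image(data, affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "VolumeGrid":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj), spacing)
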