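"""3D scalar volumes and binary masks on a common voxel grid.

These are deliberately thin wrappers around numpy arrays: a scalar image
with voxel spacing in millimetres, and a boolean mask living on the same
grid.  NIfTI round-tripping goes through nibabel; the affine is diagonal
(spacing only) because the pipeline assumes pre-resampled, co-registered
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeImage", "BinaryMask"]

_MIN_AXIS = 8


@dataclass(frozen=True)
class VolumeImage:
    """A 3D scalar image (arbitrary MR intensity units) with voxel spacing.

    Invariants: finite voxel values, strictly positive spacing, every axis
    at least 8 voxels long.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.float64)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={vox.ndim}")
        if any(s < _MIN_AXIS for s in vox.shape):
            raise ValueError(f"each axis must be >= {_MIN_AXIS}, got {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("voxel values must all be finite")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def with_voxels(self, voxels: np.ndarray) -> "VolumeImage":
        return VolumeImage(voxels=voxels, spacing=self.spacing)

    def save(self, path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        nib.save(nib.Nifti1Image(self.voxels.astype(np.float32), affine), str(path))

    @classmethod
    def load(cls, path) -> "VolumeImage":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(voxels=np.asarray(img.get_fdata(), dtype=np.float64), spacing=spacing)


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} mask on the same grid as its VolumeImage."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={vox.ndim}")
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask voxels must be 0 or 1")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", vox.astype(bool))
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def require_nonempty(self, what: str = "mask") -> None:
        if self.n_voxels == 0:
            raise ValueError(f"{what} is empty")

    def is_subset_of(self, other: "BinaryMask") -> bool:
        return bool(np.all(~self.voxels | other.voxels))

    def values_in(self, img: VolumeImage) -> np.ndarray:
        """Image intensities of in-mask voxels, as a flat float array."""
        if img.shape != self.shape:
            raise ValueError(f"shape mismatch: image {img.shape} vs mask {self.shape}")
        return img.voxels[self.voxels]

    def save(self, path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        nib.save(nib.Nifti1Image(self.voxels.astype(np.uint8), affine), str(path))

    @classmethod
    def load(cls, path) -> "BinaryMask":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(voxels=np.asarray(img.get_fdata()) > 0.5, spacing=spacing)
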