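"""Lightweight containers for CT volumes and binary segmentation masks.

Everything downstream assumes a fixed right-anterior-superior (RAS) frame:
array axis 0 increases towards the patient's right (R), axis 1 towards
anterior (A), axis 2 towards superior (S).  NIfTI inputs in
any orientation are reoriented with :func:`nibabel.as_closest_canonical`
before analysis, so "lowest axial plane" always means the smallest index
along axis 2 and "ventral" the larger anterior world coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["CtVolume", "SegmentationMask", "load_volume", "load_mask"]


def _spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


@dataclass
class CtVolume:
    """A 3D grid of Hounsfield units in the canonical RAS frame."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return _spacing_from_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_to_world(self, vox: np.ndarray) -> np.ndarray:
        """Map (N,3) voxel coordinates to world millimetres."""
        vox = np.atleast_2d(np.asarray(vox, dtype=float))
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, world: np.ndarray) -> np.ndarray:
        world = np.atleast_2d(np.asarray(world, dtype=float))
        inv = np.linalg.inv(self.affine)
        return world @ inv[:3, :3].T + inv[:3, 3]

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


@dataclass
class SegmentationMask:
    """Binary mask aligned to a :class:`CtVolume` (same shape and affine)."""

    data: np.ndarray
    affine: np.ndarray
    axis_convention: str = field(default="RAS")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.data.shape}")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return _spacing_from_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, vox: np.ndarray) -> np.ndarray:
        vox = np.atleast_2d(np.asarray(vox, dtype=float))
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


def _canonical(img: nib.Nifti1Image) -> nib.Nifti1Image:
    return nib.as_closest_canonical(img)


def load_volume(path) -> CtVolume:
    """Read a NIfTI volume and reorient it to the canonical RAS frame."""
    img = _canonical(nib.load(str(path)))
    return CtVolume(np.asarray(img.dataobj, dtype=np.float32), img.affine)


def load_mask(path) -> SegmentationMask:
    """Read a binary NIfTI mask and reorient it to the canonical RAS frame."""
    img = _canonical(nib.load(str(path)))
    return SegmentationMask(np.asarray(img.dataobj) > 0, img.affine)
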