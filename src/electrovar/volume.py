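"""NIfTI-backed 3-D/4-D scalar lattices with a voxel-to-world affine."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ValidationError
from .transforms import AffineTransform


@dataclass
class VolumeGrid:
    """A scalar lattice plus the affine mapping voxel indices to world mm.

    ``data`` is 3-D (masks, rendered maps) or 4-D (probabilistic atlases,
    last axis = region). The affine follows the NIfTI convention: index
    (i, j, k) maps to world coordinates ``affine @ (i, j, k, 1)``.
    """

    data: np.ndarray
    affine: np.ndarray  # 4x4 voxel -> world (mm)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4) or min(self.data.shape) < 1:
            raise ValidationError(f"data must be 3-D or 4-D with positive shape, got {self.data.shape}")
        a = np.asarray(self.affine, dtype=float)
        if a.shape != (4, 4) or abs(np.linalg.det(a[:3, :3])) <= 1e-12:
            raise ValidationError("voxel-to-world affine must be an invertible 4x4 matrix")
        self.affine = a

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Physical voxel edge lengths (mm) along each index axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_to_world(self) -> AffineTransform:
        return AffineTransform(self.affine, "voxel", "world")

    def voxel_to_world_coords(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        out = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates for world points (no rounding)."""
        inv = np.linalg.inv(self.affine)
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return p @ inv[:3, :3].T + inv[:3, 3]

    def nearest_voxel(self, point: np.ndarray) -> tuple[np.ndarray, bool]:
        """Nearest voxel index for one world point, plus an in-bounds flag."""
        v = np.rint(self.world_to_voxel(point)[0]).astype(int)
        inside = bool(np.all(v >= 0) and np.all(v < np.array(self.data.shape[:3])))
        return v, inside

    def to_nifti(self) -> nib.Nifti1Image:
        data = self.data
        if data.dtype == bool:
            data = data.astype(np.uint8)
        return nib.Nifti1Image(data, self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VolumeGrid":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj), np.asarray(img.affine))
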