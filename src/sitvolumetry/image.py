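"""Volumetric image container and NIfTI-1 I/O.

A :class:`VolumetricImage` is the common currency of every operation in this
package: a 3D scalar grid, its voxel spacing in millimetres, and a world
origin.  World coordinates follow the voxel-centre convention with 0-based
indices: the centre of voxel ``(i, j, k)`` sits at ``origin + (i, j, k) *
spacing``.  Spacing may be anisotropic (CT-like slices thicker than the
in-plane pixel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumetricImage"]


@dataclass
class VolumetricImage:
    """3D scalar image with voxel spacing (mm) and world origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (product of the spacings)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (diagonal spacing, translation = origin)."""
        aff = np.diag([*self.spacing, 1.0])
        aff[:3, 3] = self.origin
        return aff

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical extent (lo, hi) in mm, including the half-voxel borders."""
        sp = np.asarray(self.spacing)
        org = np.asarray(self.origin)
        lo = org - sp / 2.0
        hi = org + (np.asarray(self.shape) - 1) * sp + sp / 2.0
        return lo, hi

    def voxel_centers_world(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of the given ``(n, 3)`` voxel indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    # ----------------------------------------------------------------- I/O

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_zooms(self.spacing)
        return img

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        nib.save(self.to_nifti(), str(path))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "VolumetricImage":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
        aff = img.affine
        spacing = tuple(np.abs(np.diag(aff)[:3]))
        origin = tuple(aff[:3, 3])
        return cls(data=data, spacing=spacing, origin=origin)
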