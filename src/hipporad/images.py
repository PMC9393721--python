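"""In-memory image containers and NIfTI-1 I/O.

Three thin containers wrap numpy arrays together with their voxel geometry
(a 4x4 NIfTI-style affine): :class:`VolumeImage` for 3D scalar volumes,
:class:`ROIMask` for 3D binary masks, and :class:`TimeSeriesImage` for 4D
BOLD-like series (time on the last axis, repetition time in seconds).

All disk I/O goes through nibabel; arrays are stored as float32 (images)
or uint8 (masks) on disk and promoted to float64/bool in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeImage", "ROIMask", "TimeSeriesImage", "GeometryError"]


class GeometryError(ValueError):
    """Raised when image/mask geometries are inconsistent."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise GeometryError(f"affine must be 4x4, got {affine.shape}")
    return affine


@dataclass
class VolumeImage:
    """A 3D scalar image with voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise GeometryError(f"VolumeImage needs 3D data, got {self.data.ndim}D")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def same_grid(self, other: "VolumeImage | ROIMask") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VolumeImage":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj, dtype=float), img.affine)


@dataclass
class ROIMask:
    """A 3D binary mask sharing geometry with the images it indexes."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise GeometryError(f"ROIMask needs 3D data, got {self.data.ndim}D")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def same_grid(self, other: "VolumeImage | ROIMask") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "ROIMask":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj) > 0, img.affine)


@dataclass
class TimeSeriesImage:
    """A 4D scalar time series (x, y, z, t) with repetition time in seconds."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise GeometryError(f"TimeSeriesImage needs 4D data, got {self.data.ndim}D")
        self.affine = _check_affine(self.affine)
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def same_grid(self, other: "VolumeImage | ROIMask | TimeSeriesImage") -> bool:
        return self.shape[:3] == other.shape[:3] and np.allclose(self.affine, other.affine)

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(img.header.get_zooms()[:3] + (self.tr,))
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path, tr: float | None = None) -> "TimeSeriesImage":
        img = nib.load(str(path))
        if tr is None:
            zooms = img.header.get_zooms()
            tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
        return cls(np.asanyarray(img.dataobj, dtype=float), img.affine, tr)
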