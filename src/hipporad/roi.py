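"""ROI mask utilities: Dice overlap, resampling, bilateral combination.

Masks are resampled with nearest-neighbor interpolation so labels stay
binary. Affine transforms are 4x4 world-coordinate matrices (NIfTI sform
convention) mapping target-space world coordinates to source-space world
coordinates ("pull" resampling).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .images import ROIMask

__all__ = ["dice", "resample_mask", "combine_bilateral", "load_affine", "save_affine"]


def dice(a: ROIMask, b: ROIMask) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); symmetric, in [0, 1]."""
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise ValueError("Dice undefined: both masks empty")
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def resample_mask(
    mask: ROIMask,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
    transform: np.ndarray | None = None,
) -> ROIMask:
    """Nearest-neighbor resampling of a binary mask onto a target grid.

    ``transform`` (optional 4x4) maps target world coordinates into source
    world coordinates; identity when omitted. With an identity transform and
    an identical grid the input is returned unchanged.
    """
    target_affine = np.asarray(target_affine, dtype=float)
    if transform is None:
        transform = np.eye(4)
    transform = np.asarray(transform, dtype=float)
    if abs(np.linalg.det(transform)) < 1e-12:
        raise ValueError("transform is not invertible")
    if (
        tuple(target_shape) == mask.shape
        and np.allclose(target_affine, mask.affine)
        and np.allclose(transform, np.eye(4))
    ):
        return ROIMask(mask.data.copy(), mask.affine.copy())
    # target voxel -> target world -> source world -> source voxel
    m = np.linalg.inv(mask.affine) @ transform @ target_affine
    idx = np.indices(target_shape).reshape(3, -1)
    src = m[:3, :3] @ idx + m[:3, 3:4]
    vals = map_coordinates(mask.data.astype(np.float32), src, order=0, mode="constant", cval=0.0)
    return ROIMask(vals.reshape(target_shape) > 0.5, target_affine)


def combine_bilateral(left: ROIMask, right: ROIMask) -> ROIMask:
    """Voxelwise union of two hemisphere masks (expected disjoint)."""
    if left.shape != right.shape or not np.allclose(left.affine, right.affine):
        raise ValueError("hemisphere masks must share geometry")
    if (left.data & right.data).any():
        warnings.warn("left and right masks overlap; union returned", stacklevel=2)
    return ROIMask(left.data | right.data, left.affine)


def load_affine(path: str | Path) -> np.ndarray:
    """Read a 4x4 affine from whitespace-delimited text."""
    m = np.loadtxt(str(path))
    if m.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix in {path}, got {m.shape}")
    return m


def save_affine(m: np.ndarray, path: str | Path) -> None:
    np.savetxt(str(path), np.asarray(m, dtype=float), fmt="%.12g")
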