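"""Gray-level texture matrices and their features, computed in 3D.

Five matrix families are implemented over a discretized ROI:

* GLCM  — gray-level co-occurrence: joint probability of level pairs at
  distance 1, aggregated (summed) over the 13 unique 3D directions and
  symmetrized, so every voxel is compared with its 26 neighbors.
* GLRLM — gray-level run-length: runs of consecutive equal levels along the
  13 directions, matrices summed over directions.
* GLSZM — gray-level size-zone: 26-connected components of equal level,
  counted by level and zone size.
* GLDZM — gray-level distance-zone: the same zones counted by level and by
  the zone's minimum city-block distance to the ROI border.
* NGLDM — neighboring gray-level dependence: for each voxel, the number of
  26-neighbors sharing its level (coarseness parameter alpha = 0).

Discretization uses the fixed-bin-number scheme (default 32 levels within
the ROI's own intensity range), which makes all texture features invariant
under monotone affine intensity transforms — required because structural
and ALFF intensities live on incomparable scales.

Degenerate-input conventions (documented, fixed): a constant ROI has GLCM
correlation 1 (zero marginal variance); entropy-like features treat
0 * log(0) as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DiscretizedROI",
    "discretize",
    "DIRECTIONS_13",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "gldzm_matrix",
    "gldzm_features",
    "ngldm_matrix",
    "ngldm_features",
]

#: The 13 unique distance-1 offsets in 3D (one per axis/diagonal family);
#: counting each pair in both orders covers the full 26-neighborhood.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DiscretizedROI:
    """Integer levels 1..n_levels on ROI voxels; 0 marks non-ROI voxels."""

    levels: np.ndarray  # 3D int array, 0 outside ROI
    n_levels: int
    intensity_range: tuple[float, float]

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretize(image_data: np.ndarray, mask_data: np.ndarray, n_bins: int = 32) -> DiscretizedROI:
    """Fixed-bin-number discretization within the ROI.

    level = 1 + floor(n_bins * (x - min) / (max - min)), with the maximum
    mapped to n_bins; a constant ROI maps every voxel to level 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mask = np.asarray(mask_data).astype(bool)
    if not mask.any():
        raise ValueError("ROI is empty")
    x = np.asarray(image_data, dtype=float)[mask]
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite intensities inside ROI")
    lo, hi = float(x.min()), float(x.max())
    levels = np.zeros(mask.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
    else:
        lv = 1 + np.floor(n_bins * (x - lo) / (hi - lo)).astype(np.int32)
        np.clip(lv, 1, n_bins, out=lv)
        levels[mask] = lv
    return DiscretizedROI(levels, n_bins, (lo, hi))


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0*log(0)=0 convention."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(
    d: DiscretizedROI,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> np.ndarray:
    """Symmetric co-occurrence probabilities over the directions, sum 1."""
    ng = d.n_levels
    lv = np.pad(d.levels, 1)
    core = lv[1:-1, 1:-1, 1:-1]
    counts = np.zeros((ng + 1) * (ng + 1), dtype=np.int64)
    for (a, b, c) in directions:
        nb = lv[1 + a:lv.shape[0] - 1 + a,
                1 + b:lv.shape[1] - 1 + b,
                1 + c:lv.shape[2] - 1 + c]
        valid = (core > 0) & (nb > 0)
        if valid.any():
            counts += np.bincount(
                core[valid].astype(np.int64) * (ng + 1) + nb[valid],
                minlength=(ng + 1) * (ng + 1),
            )
    m = counts.reshape(ng + 1, ng + 1)[1:, 1:].astype(float)
    m = m + m.T  # count both orders -> 26-neighborhood, symmetric
    total = m.sum()
    if total == 0:
        raise ValueError("no valid co-occurrence pairs in ROI")
    return m / total


def glcm_features(
    d: DiscretizedROI,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> dict[str, float]:
    p = glcm_matrix(d, directions)
    ng = d.n_levels
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # marginal (symmetric)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())

    diff = np.abs(ii - jj)
    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.array([p[diff == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    da = float((k_diff * p_diff).sum())
    sa = float((k_sum * p_sum).sum())

    hxy = float(-_xlogx(p).sum())
    hx = float(-_xlogx(px).sum())
    pxpy = np.outer(px, px)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    hxy2 = float(-_xlogx(pxpy).sum())

    if sigma2 > 0:
        correlation = float((((ii - mu) * (jj - mu) * p).sum()) / sigma2)
    else:
        correlation = 1.0  # constant image convention
    imc1 = (hxy - hxy1) / max(hx, 1e-30) if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * max(0.0, hxy2 - hxy)))))

    off = diff > 0
    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "ClusterProminence": float((((ii + jj - 2 * mu) ** 4) * p).sum()),
        "ClusterShade": float((((ii + jj - 2 * mu) ** 3) * p).sum()),
        "ClusterTendency": float((((ii + jj - 2 * mu) ** 2) * p).sum()),
        "Contrast": float((((ii - jj) ** 2) * p).sum()),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-_xlogx(p_diff).sum()),
        "DifferenceVariance": float((((k_diff - da) ** 2) * p_diff).sum()),
        "Dissimilarity": float((diff * p).sum()),
        "Energy": float((p**2).sum()),
        "Entropy": hxy,
        "IMC1": float(imc1),
        "IMC2": imc2,
        "InverseDifference": float((p / (1.0 + diff)).sum()),
        "InverseDifferenceMoment": float((p / (1.0 + diff**2)).sum()),
        "InverseDifferenceMomentNormalized": float((p / (1.0 + diff**2 / ng**2)).sum()),
        "InverseDifferenceNormalized": float((p / (1.0 + diff / ng)).sum()),
        "InverseVariance": float((p[off] / diff[off] ** 2).sum()),
        "JointAverage": mu,
        "JointMaximum": float(p.max()),
        "JointVariance": sigma2,
        "SumAverage": sa,
        "SumEntropy": float(-_xlogx(p_sum).sum()),
        "SumVariance": float((((k_sum - sa) ** 2) * p_sum).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(
    d: DiscretizedROI,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> np.ndarray:
    """Run counts R[level-1, length-1], summed over the directions."""
    lv = np.pad(d.levels, 1)
    shape = d.levels.shape
    max_len = max(shape)
    counts = np.zeros((d.n_levels, max_len), dtype=np.int64)
    coords_all = np.argwhere(d.levels > 0) + 1  # padded coords
    for dvec in directions:
        dv = np.array(dvec)
        prev = coords_all - dv
        prev_lv = lv[prev[:, 0], prev[:, 1], prev[:, 2]]
        cur_lv = lv[coords_all[:, 0], coords_all[:, 1], coords_all[:, 2]]
        starts = coords_all[(prev_lv != cur_lv)]
        start_lv = lv[starts[:, 0], starts[:, 1], starts[:, 2]]
        # walk every run in lock-step; at most max(shape) iterations
        lengths = np.ones(len(starts), dtype=np.int64)
        pos = starts.copy()
        alive = np.ones(len(starts), dtype=bool)
        while alive.any():
            pos[alive] += dv
            nxt = lv[pos[alive][:, 0], pos[alive][:, 1], pos[alive][:, 2]]
            cont = nxt == start_lv[alive]
            idx = np.flatnonzero(alive)
            lengths[idx[cont]] += 1
            alive[idx[~cont]] = False
        np.add.at(counts, (start_lv - 1, lengths - 1), 1)
    return counts


def _rl_features(counts: np.ndarray, n_voxels: int, n_directions: int) -> dict[str, float]:
    """Shared run-length statistic roster (used by GLRLM)."""
    nr = counts.sum()
    if nr == 0:
        raise ValueError("no runs found")
    p = counts / nr
    g = counts.sum(axis=1).astype(float)  # per gray level
    r = counts.sum(axis=0).astype(float)  # per run length
    i = np.arange(1, counts.shape[0] + 1, dtype=float)
    j = np.arange(1, counts.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    mu_i = float((p * ii).sum())
    mu_j = float((p * jj).sum())
    return {
        "SRE": float((r / j**2).sum() / nr),
        "LRE": float((r * j**2).sum() / nr),
        "LGLRE": float((g / i**2).sum() / nr),
        "HGLRE": float((g * i**2).sum() / nr),
        "SRLGLE": float((counts / (ii**2 * jj**2)).sum() / nr),
        "SRHGLE": float((counts * ii**2 / jj**2).sum() / nr),
        "LRLGLE": float((counts * jj**2 / ii**2).sum() / nr),
        "LRHGLE": float((counts * ii**2 * jj**2).sum() / nr),
        "GLN": float((g**2).sum() / nr),
        "GLNN": float((g**2).sum() / nr**2),
        "RLN": float((r**2).sum() / nr),
        "RLNN": float((r**2).sum() / nr**2),
        "RP": float(nr / (n_voxels * n_directions)),
        "GLV": float((p * (ii - mu_i) ** 2).sum()),
        "RLV": float((p * (jj - mu_j) ** 2).sum()),
        "RE": float(-_xlogx(p).sum()),
    }


def glrlm_features(
    d: DiscretizedROI,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> dict[str, float]:
    return _rl_features(glrlm_matrix(d, directions), d.n_voxels, len(directions))


# ---------------------------------------------------------------------------
# GLSZM / GLDZM


def _zones(d: DiscretizedROI):
    """Yield (level, zone_size, zone_voxel_coords) for 26-connected zones."""
    for level in range(1, d.n_levels + 1):
        binary = d.levels == level
        if not binary.any():
            continue
        labeled, n = ndimage.label(binary, structure=_STRUCT_26)
        for z in range(1, n + 1):
            coords = np.argwhere(labeled == z)
            yield level, len(coords), coords


def glszm_matrix(d: DiscretizedROI) -> np.ndarray:
    """Zone counts S[level-1, size-1] over 26-connected equal-level zones."""
    sizes: list[tuple[int, int]] = [(lvl, sz) for lvl, sz, _ in _zones(d)]
    max_size = max(sz for _, sz in sizes)
    counts = np.zeros((d.n_levels, max_size), dtype=np.int64)
    for lvl, sz in sizes:
        counts[lvl - 1, sz - 1] += 1
    return counts


def _zone_features(counts: np.ndarray, n_voxels: int, size_axis: str) -> dict[str, float]:
    """Zone-statistic roster shared by GLSZM (size) and GLDZM (distance).

    ``size_axis`` selects the column-emphasis names: "A" (area) or "D"
    (distance).
    """
    nz = counts.sum()
    if nz == 0:
        raise ValueError("no zones found")
    p = counts / nz
    g = counts.sum(axis=1).astype(float)
    s = counts.sum(axis=0).astype(float)
    i = np.arange(1, counts.shape[0] + 1, dtype=float)
    j = np.arange(1, counts.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    mu_i = float((p * ii).sum())
    mu_j = float((p * jj).sum())
    small, large = (f"S{size_axis}E", f"L{size_axis}E")
    a = size_axis
    return {
        small: float((s / j**2).sum() / nz),
        large: float((s * j**2).sum() / nz),
        "LGLZE": float((g / i**2).sum() / nz),
        "HGLZE": float((g * i**2).sum() / nz),
        f"S{a}LGLE": float((counts / (ii**2 * jj**2)).sum() / nz),
        f"S{a}HGLE": float((counts * ii**2 / jj**2).sum() / nz),
        f"L{a}LGLE": float((counts * jj**2 / ii**2).sum() / nz),
        f"L{a}HGLE": float((counts * ii**2 * jj**2).sum() / nz),
        "GLN": float((g**2).sum() / nz),
        "GLNN": float((g**2).sum() / nz**2),
        f"Z{'S' if a == 'A' else 'D'}N": float((s**2).sum() / nz),
        f"Z{'S' if a == 'A' else 'D'}NN": float((s**2).sum() / nz**2),
        "ZP": float(nz / n_voxels),
        "GLV": float((p * (ii - mu_i) ** 2).sum()),
        f"Z{'S' if a == 'A' else 'D'}V": float((p * (jj - mu_j) ** 2).sum()),
        f"Z{'S' if a == 'A' else 'D'}E": float(-_xlogx(p).sum()),
    }


def glszm_features(d: DiscretizedROI) -> dict[str, float]:
    return _zone_features(glszm_matrix(d), d.n_voxels, "A")


def gldzm_matrix(d: DiscretizedROI) -> np.ndarray:
    """Zone counts by level and minimum city-block distance to the ROI edge.

    A voxel adjacent to the ROI border (or to the image border) has distance
    1; the zone distance is the minimum over its voxels.
    """
    padded = np.pad(d.mask, 1)
    dist = ndimage.distance_transform_cdt(padded, metric="taxicab")[1:-1, 1:-1, 1:-1]
    entries = []
    for lvl, _sz, coords in _zones(d):
        zone_dist = int(dist[coords[:, 0], coords[:, 1], coords[:, 2]].min())
        entries.append((lvl, zone_dist))
    max_dist = max(dd for _, dd in entries)
    counts = np.zeros((d.n_levels, max_dist), dtype=np.int64)
    for lvl, dd in entries:
        counts[lvl - 1, dd - 1] += 1
    return counts


def gldzm_features(d: DiscretizedROI) -> dict[str, float]:
    return _zone_features(gldzm_matrix(d), d.n_voxels, "D")


# ---------------------------------------------------------------------------
# NGLDM


def ngldm_matrix(d: DiscretizedROI) -> np.ndarray:
    """Dependence counts M[level-1, j-1], j = 1 + matching 26-neighbors.

    A neighbor "matches" when it lies in the ROI and has the same level
    (coarseness alpha = 0). Columns therefore run from j=1 (no dependent
    neighbor) to j=27.
    """
    lv = np.pad(d.levels, 1)
    core = lv[1:-1, 1:-1, 1:-1]
    dep = np.zeros(d.levels.shape, dtype=np.int64)
    for (a, b, c) in DIRECTIONS_13:
        for sa, sb, sc in ((a, b, c), (-a, -b, -c)):
            nb = lv[1 + sa:lv.shape[0] - 1 + sa,
                    1 + sb:lv.shape[1] - 1 + sb,
                    1 + sc:lv.shape[2] - 1 + sc]
            dep += (nb > 0) & (nb == core)
    counts = np.zeros((d.n_levels, 27), dtype=np.int64)
    roi = d.mask
    np.add.at(counts, (d.levels[roi] - 1, dep[roi]), 1)
    # trim trailing all-zero dependence columns
    last = np.flatnonzero(counts.sum(axis=0))[-1]
    return counts[:, : last + 1]


def ngldm_features(d: DiscretizedROI) -> dict[str, float]:
    counts = ngldm_matrix(d)
    ns = counts.sum()
    p = counts / ns
    g = counts.sum(axis=1).astype(float)
    s = counts.sum(axis=0).astype(float)
    i = np.arange(1, counts.shape[0] + 1, dtype=float)
    j = np.arange(1, counts.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    mu_i = float((p * ii).sum())
    mu_j = float((p * jj).sum())
    return {
        "SDE": float((s / j**2).sum() / ns),
        "LDE": float((s * j**2).sum() / ns),
        "LGLE": float((g / i**2).sum() / ns),
        "HGLE": float((g * i**2).sum() / ns),
        "SDLGLE": float((counts / (ii**2 * jj**2)).sum() / ns),
        "SDHGLE": float((counts * ii**2 / jj**2).sum() / ns),
        "LDLGLE": float((counts * jj**2 / ii**2).sum() / ns),
        "LDHGLE": float((counts * ii**2 * jj**2).sum() / ns),
        "GLN": float((g**2).sum() / ns),
        "GLNN": float((g**2).sum() / ns**2),
        "DN": float((s**2).sum() / ns),
        "DNN": float((s**2).sum() / ns**2),
        "GLV": float((p * (ii - mu_i) ** 2).sum()),
        "DV": float((p * (jj - mu_j) ** 2).sum()),
        "DE": float(-_xlogx(p).sum()),
    }
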