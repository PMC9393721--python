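"""First-order (intensity) features on raw ROI intensities.

Thirteen statistics computed on the undiscretized voxel values, except the
histogram entropy, which uses the fixed-bin-number discretized levels so it
stays comparable across modalities. Zero-variance ROIs get skewness and
kurtosis 0 by convention. Kurtosis is the excess kurtosis (normal = 0).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .texture import _xlogx, discretize

__all__ = ["intensity_features", "INTENSITY_NAMES"]

INTENSITY_NAMES = (
    "Mean",
    "Median",
    "Min",
    "Max",
    "Range",
    "Variance",
    "StdDev",
    "Skewness",
    "Kurtosis",
    "Energy",
    "Entropy",
    "P10",
    "P90",
)


def intensity_features(
    image_data: np.ndarray, mask_data: np.ndarray, n_bins: int = 32
) -> dict[str, float]:
    mask = np.asarray(mask_data).astype(bool)
    if not mask.any():
        raise ValueError("ROI is empty")
    x = np.asarray(image_data, dtype=float)[mask]
    if x.max() == x.min():  # constant ROI: exact zero spread by convention
        var = skew = kurt = 0.0
    else:
        var = float(np.var(x))
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x))
    d = discretize(image_data, mask_data, n_bins)
    p = np.bincount(d.levels[d.mask], minlength=n_bins + 1)[1:] / d.n_voxels
    return {
        "Mean": float(x.mean()),
        "Median": float(np.median(x)),
        "Min": float(x.min()),
        "Max": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Variance": var,
        "StdDev": float(np.sqrt(var)),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float((x**2).sum()),
        "Entropy": float(-_xlogx(p).sum()),
        "P10": float(np.percentile(x, 10)),
        "P90": float(np.percentile(x, 90)),
    }
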