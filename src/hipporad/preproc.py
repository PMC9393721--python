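"""Motion QC, nuisance regression, and slow-5 ALFF maps.

The amplitude of low-frequency fluctuation (ALFF) of a voxel is the mean
single-sided spectral amplitude ``2|X(f)|/N`` of its (detrended,
confound-regressed) BOLD series over the discrete frequency bins falling in a
low-frequency band — here the slow-5 band, 0.01–0.027 Hz. The DC bin is always
excluded; band edges are closed (a bin is used iff ``low <= f <= high``).

Motion quality control uses the rigid-body realignment parameters: subjects
are excluded when any translation exceeds 3 mm, any rotation exceeds 3
degrees, or mean framewise displacement (FD, Power convention with a 50 mm
head radius) exceeds 0.5 mm. Nuisance regression supports a linear trend,
the Friston 24-parameter motion expansion, and precomputed tissue (WM/CSF)
mean signals.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .images import ROIMask, TimeSeriesImage, VolumeImage

__all__ = [
    "MotionTrace",
    "QCThresholds",
    "BandSpec",
    "ALFFMap",
    "framewise_displacement",
    "qc_summary",
    "qc_exclude",
    "friston24",
    "regress_confounds",
    "compute_alff",
    "alff_pipeline",
]

#: Rotational displacement is converted to arc length on a sphere of this
#: radius (mm), the Power et al. framewise-displacement convention.
HEAD_RADIUS_MM = 50.0


@dataclass
class MotionTrace:
    """Per-volume rigid-body parameters: tx, ty, tz (mm), rx, ry, rz (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"motion trace must be (n_volumes, 6), got {self.params.shape}")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion trace contains non-finite values")

    def __len__(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]

    def save(self, path: str | Path) -> None:
        np.savetxt(str(path), self.params, fmt="%.10g")

    @classmethod
    def load(cls, path: str | Path) -> "MotionTrace":
        return cls(np.loadtxt(str(path), ndmin=2))


@dataclass(frozen=True)
class QCThresholds:
    """Motion exclusion thresholds (all strictly positive)."""

    max_translation_mm: float = 3.0
    max_rotation_deg: float = 3.0
    max_mean_fd_mm: float = 0.5

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if not getattr(self, f.name) > 0:
                raise ValueError(f"{f.name} must be > 0")


@dataclass(frozen=True)
class BandSpec:
    """Analysis frequency band (Hz) and number of initial volumes discarded."""

    low_hz: float = 0.01
    high_hz: float = 0.027
    n_discard: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"need 0 < low_hz < high_hz, got {self.low_hz}, {self.high_hz}")
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")

    def validate_for_tr(self, tr: float) -> None:
        nyquist = 1.0 / (2.0 * tr)
        if self.high_hz > nyquist:
            raise ValueError(
                f"band high edge {self.high_hz} Hz exceeds Nyquist {nyquist} Hz for TR={tr}s"
            )


@dataclass
class ALFFMap:
    """Per-voxel band-averaged spectral amplitude; zero outside the mask."""

    volume: VolumeImage
    band: BandSpec
    n_volumes_used: int


def framewise_displacement(motion: MotionTrace) -> np.ndarray:
    """Power-style FD series in mm; FD[0] = 0.

    FD[t] = sum |delta translations| + 50 * sum |delta rotations (rad)|.
    Depends only on successive differences of the parameters.
    """
    if len(motion) < 2:
        raise ValueError("framewise displacement needs at least 2 volumes")
    d = np.abs(np.diff(motion.params, axis=0))
    fd = d[:, :3].sum(axis=1) + HEAD_RADIUS_MM * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def qc_summary(motion: MotionTrace, thresholds: QCThresholds | None = None) -> dict:
    """Summarize one subject's motion against the exclusion thresholds."""
    thresholds = thresholds or QCThresholds()
    fd = framewise_displacement(motion)
    max_trans = float(np.abs(motion.translations).max())
    max_rot_deg = float(np.degrees(np.abs(motion.rotations).max()))
    mean_fd = float(fd.mean())
    reasons = []
    if max_trans > thresholds.max_translation_mm:
        reasons.append("translation")
    if max_rot_deg > thresholds.max_rotation_deg:
        reasons.append("rotation")
    if mean_fd > thresholds.max_mean_fd_mm:
        reasons.append("FD")
    return {
        "max_trans": max_trans,
        "max_rot_deg": max_rot_deg,
        "mean_fd": mean_fd,
        "kept": not reasons,
        "reason": ";".join(reasons),
    }


def qc_exclude(
    motions: dict[str, MotionTrace],
    thresholds: QCThresholds | None = None,
) -> tuple[list[str], list[tuple[str, str]], pd.DataFrame]:
    """Partition subjects into kept and excluded (with reasons).

    Returns ``(kept_ids, [(excluded_id, reason), ...], report)`` where the
    report has one row per subject (columns: subject_id, max_trans,
    max_rot_deg, mean_fd, kept, reason).
    """
    thresholds = thresholds or QCThresholds()
    rows = []
    kept: list[str] = []
    excluded: list[tuple[str, str]] = []
    for sid, motion in motions.items():
        if motion is None:
            raise ValueError(f"subject {sid} has no motion trace")
        s = qc_summary(motion, thresholds)
        rows.append({"subject_id": sid, **s})
        if s["kept"]:
            kept.append(sid)
        else:
            excluded.append((sid, s["reason"]))
    return kept, excluded, pd.DataFrame(rows)


def friston24(motion: MotionTrace) -> np.ndarray:
    """Friston 24-parameter expansion: [R(t), R(t-1), R(t)^2, R(t-1)^2].

    The lagged row 0 is zero-filled. Output shape (n_volumes, 24).
    """
    if len(motion) < 2:
        raise ValueError("friston24 needs at least 2 volumes")
    r = motion.params
    r_lag = np.vstack([np.zeros(6), r[:-1]])
    return np.hstack([r, r_lag, r**2, r_lag**2])


def _drop_collinear(design: np.ndarray) -> np.ndarray:
    """Greedily drop columns that do not increase the design rank."""
    keep: list[int] = []
    rank = 0
    for j in range(design.shape[1]):
        cand = design[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
    if len(keep) < design.shape[1]:
        warnings.warn(
            f"design rank-deficient: dropped {design.shape[1] - len(keep)} collinear column(s)",
            stacklevel=3,
        )
    return design[:, keep]


def regress_confounds(
    ts: TimeSeriesImage,
    mask: ROIMask,
    confounds: np.ndarray | None = None,
    include_linear_trend: bool = True,
    tissue_signals: np.ndarray | None = None,
) -> TimeSeriesImage:
    """Voxelwise OLS residualization against intercept (+ trend, confounds).

    Only voxels inside ``mask`` are regressed; voxels outside are zeroed.
    Residuals are orthogonal to every retained design column.
    """
    if not ts.same_grid(mask):
        raise ValueError("time series and mask geometries differ")
    n = ts.n_volumes
    cols = [np.ones(n)]
    if include_linear_trend:
        cols.append(np.linspace(-1.0, 1.0, n))
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.shape[0] != n:
            raise ValueError(f"confounds rows ({confounds.shape[0]}) != volumes ({n})")
        cols.append(confounds)
    if tissue_signals is not None:
        tissue_signals = np.asarray(tissue_signals, dtype=float)
        if tissue_signals.ndim == 1:
            tissue_signals = tissue_signals[:, None]
        if tissue_signals.shape[0] != n:
            raise ValueError("tissue signal rows != volumes")
        cols.append(tissue_signals)
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        design = _drop_collinear(design)

    y = ts.data[mask.data].T  # (T, V)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    out = np.zeros_like(ts.data)
    out[mask.data] = resid.T
    return TimeSeriesImage(out, ts.affine, ts.tr)


def compute_alff(ts: TimeSeriesImage, mask: ROIMask, band: BandSpec | None = None) -> ALFFMap:
    """Band-averaged single-sided spectral amplitude per masked voxel.

    The first ``band.n_discard`` volumes are dropped, then for each voxel the
    amplitude spectrum ``2|X(f)|/N`` is averaged over the bins with
    ``low <= f <= high`` (DC excluded). Raises if no bin falls in the band.
    """
    band = band or BandSpec()
    band.validate_for_tr(ts.tr)
    if not ts.same_grid(mask):
        raise ValueError("time series and mask geometries differ")
    n = ts.n_volumes - band.n_discard
    if n < 32:
        raise ValueError(f"only {n} volumes remain after discarding {band.n_discard}; need >= 32")
    y = ts.data[mask.data][:, band.n_discard:]  # (V, N)
    y = y - y.mean(axis=1, keepdims=True)  # DC removed exactly
    freqs = np.fft.rfftfreq(n, d=ts.tr)
    in_band = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    in_band[0] = False  # DC always excluded
    if not in_band.any():
        raise ValueError(
            f"no frequency bin in [{band.low_hz}, {band.high_hz}] Hz "
            f"with {n} volumes at TR={ts.tr}s"
        )
    amp = 2.0 * np.abs(np.fft.rfft(y, axis=1)[:, in_band]) / n
    alff = amp.mean(axis=1)
    out = np.zeros(ts.shape[:3])
    out[mask.data] = alff
    return ALFFMap(VolumeImage(out, ts.affine), band, n)


def alff_pipeline(
    ts: TimeSeriesImage,
    mask: ROIMask,
    motion: MotionTrace | None = None,
    band: BandSpec | None = None,
    tissue_signals: np.ndarray | None = None,
) -> ALFFMap:
    """Discard initial volumes, regress nuisance signals, compute ALFF.

    Order of operations: (1) drop the first ``band.n_discard`` volumes of the
    series and of the motion trace; (2) regress a linear trend, the Friston-24
    motion expansion (when a trace is given) and optional tissue signals;
    (3) compute the band amplitude on the residuals.
    """
    band = band or BandSpec()
    k = band.n_discard
    if ts.n_volumes - k < 32:
        raise ValueError(f"too few volumes ({ts.n_volumes}) for n_discard={k}")
    trimmed = TimeSeriesImage(ts.data[..., k:], ts.affine, ts.tr)
    confounds = None
    if motion is not None:
        if len(motion) != ts.n_volumes:
            raise ValueError(
                f"motion trace length ({len(motion)}) != n_volumes ({ts.n_volumes})"
            )
        confounds = friston24(MotionTrace(motion.params[k:]))
    if tissue_signals is not None:
        tissue_signals = np.asarray(tissue_signals, dtype=float)[k:]
    resid = regress_confounds(
        trimmed, mask, confounds=confounds, include_linear_trend=True,
        tissue_signals=tissue_signals,
    )
    return compute_alff(resid, mask, dataclasses.replace(band, n_discard=0))
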