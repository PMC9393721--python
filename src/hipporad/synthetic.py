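"""Synthetic cohorts of paired structural/functional images with known effects.

Each subject carries a structural volume, a 4D functional series, left/right
ellipsoidal hippocampus-like ROI masks, a 6-column rigid-body motion trace and
a clinical (MMSE-like) score. Two planted, independently tunable group
effects drive the downstream models:

* ``texture_effect`` widens the Gaussian smoothing kernel of the structural
  random field inside the ROI for patient groups. The field is re-standardized
  after smoothing, so first-order intensity statistics are unchanged and only
  spatial texture (e.g. GLCM correlation/entropy) differs between groups.
* ``alff_effect`` scales the amplitude of low-frequency sinusoids
  (0.0125, 0.02, 0.025 Hz — inside the 0.01–0.027 Hz slow-5 band and
  bin-aligned at the default TR=2 s with 200 retained volumes) added to the
  functional ROI series, on top of white noise and a linear drift.

Per-group susceptibility is expressed through each group's ``texture_scale``
and ``alff_scale`` in [0, 1] (0 for controls), so a three-group cohort can
emulate a severity gradient. Between-subject variability enters through
lognormal jitter of the oscillation amplitude and of the smoothing width;
with both effects at 0 the groups are exchangeable by construction.

Reproducibility: one master seed; per-subject generators are spawned from
``numpy.random.SeedSequence([master_seed, subject_seed])``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .images import ROIMask, TimeSeriesImage, VolumeImage
from .preproc import MotionTrace

__all__ = [
    "GroupSpec",
    "EllipsoidROI",
    "MotionOverride",
    "MotionProfile",
    "CohortSpec",
    "SyntheticSubject",
    "Cohort",
    "generate_subject",
    "generate_cohort",
    "save_cohort",
    "default_study_spec",
]


@dataclass(frozen=True)
class GroupSpec:
    """One diagnostic label: size, effect susceptibilities, score model."""

    n: int
    texture_scale: float = 0.0  # in [0, 1]; 0 for controls
    alff_scale: float = 0.0
    score_mean: float = 29.0
    score_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2")
        if not (0 <= self.texture_scale <= 1 and 0 <= self.alff_scale <= 1):
            raise ValueError("effect scales must lie in [0, 1]")


@dataclass(frozen=True)
class EllipsoidROI:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def mask_array(self, shape: tuple[int, int, int]) -> np.ndarray:
        for c, r, s in zip(self.center, self.radii, shape):
            if c - r < 0 or c + r > s - 1:
                raise ValueError(
                    f"ellipsoid (center={self.center}, radii={self.radii}) "
                    f"extends outside image shape {shape}"
                )
        grids = np.indices(shape, dtype=float)
        q = sum(
            ((g - c) / r) ** 2 for g, c, r in zip(grids, self.center, self.radii)
        )
        return q <= 1.0


@dataclass(frozen=True)
class MotionOverride:
    """Planted motion pathology for a single subject."""

    jump_translation_mm: float = 0.0
    jump_rotation_deg: float = 0.0
    step_scale: float = 1.0  # scales the random-walk step size (drives mean FD)


@dataclass(frozen=True)
class MotionProfile:
    """Random-walk realignment parameters plus per-subject overrides."""

    step_translation_mm: float = 0.02
    step_rotation_rad: float = 0.0004
    overrides: dict[str, MotionOverride] = field(default_factory=dict)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; validated on construction."""

    groups: dict[str, GroupSpec]
    image_shape: tuple[int, int, int] = (24, 24, 20)
    roi_left: EllipsoidROI = EllipsoidROI((7.0, 12.0, 10.0), (4.0, 3.0, 3.0))
    roi_right: EllipsoidROI = EllipsoidROI((16.0, 12.0, 10.0), (4.0, 3.0, 3.0))
    tr_seconds: float = 2.0
    n_volumes: int = 210
    texture_effect: float = 0.5
    alff_effect: float = 0.5
    noise_sd: float = 1.0
    drift_slope: float = 0.02  # intensity units per second
    motion: MotionProfile = field(default_factory=MotionProfile)
    seed: int = 0
    # generator calibration (kept fixed across analyses)
    baseline_functional: float = 1000.0
    baseline_structural: float = 100.0
    osc_freqs: tuple[float, ...] = (0.0125, 0.02, 0.025)
    osc_amp: float = 1.0
    subject_amp_sd: float = 0.35  # lognormal sd of per-subject amplitude
    struct_sigma: float = 0.6  # base smoothing kernel width (voxels)
    struct_sigma_sd: float = 0.25  # lognormal sd of per-subject kernel width
    struct_amp: float = 10.0  # within-ROI field standard deviation
    voxel_size_mm: float = 3.0
    n_discard_hint: int = 10  # functional length must exceed this

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("spec needs at least one group")
        if self.texture_effect < 0 or self.alff_effect < 0:
            raise ValueError("effects must be >= 0")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_volumes <= self.n_discard_hint:
            raise ValueError(
                f"n_volumes ({self.n_volumes}) must exceed the number of "
                f"discarded initial volumes ({self.n_discard_hint})"
            )
        n_retained = self.n_volumes - self.n_discard_hint
        df = 1.0 / (n_retained * self.tr_seconds)
        if df > 0.017:  # need at least one bin inside the slow-5 band
            raise ValueError(
                f"n_volumes too small for slow-5 band resolution (df={df:.4f} Hz)"
            )
        # validate ROI placement eagerly
        self.roi_left.mask_array(self.image_shape)
        self.roi_right.mask_array(self.image_shape)

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size_mm] * 3 + [1.0])

    def group_label_of(self, index: int) -> str:
        total = 0
        for name, g in self.groups.items():
            total += g.n
            if index < total:
                return name
        raise IndexError(index)

    @property
    def n_subjects(self) -> int:
        return sum(g.n for g in self.groups.values())


def default_study_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The emulated study cohort: AD 84 / aMCI 50 / NC 44 with an
    MMSE-like score model (AD 17.512±5.084, aMCI 26.200±0.881,
    NC 29.023±0.902) and a severity gradient in both planted effects."""
    groups = {
        "AD": GroupSpec(84, texture_scale=1.0, alff_scale=1.0,
                        score_mean=17.512, score_sd=5.084),
        "aMCI": GroupSpec(50, texture_scale=0.6, alff_scale=0.6,
                          score_mean=26.200, score_sd=0.881),
        "NC": GroupSpec(44, texture_scale=0.0, alff_scale=0.0,
                        score_mean=29.023, score_sd=0.902),
    }
    return CohortSpec(groups=groups, seed=seed, **overrides)


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    structural: VolumeImage
    functional: TimeSeriesImage
    mask_left: ROIMask
    mask_right: ROIMask
    motion: MotionTrace
    score: float


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[SyntheticSubject]
    table: pd.DataFrame  # subject_id, group, score (motion_path added on save)


def _standardize(field_values: np.ndarray, where: np.ndarray) -> np.ndarray:
    v = field_values[where]
    sd = v.std()
    if sd == 0:
        return np.zeros_like(field_values)
    return (field_values - v.mean()) / sd


def generate_subject(spec: CohortSpec, group: str, subject_seed: int) -> SyntheticSubject:
    """One fully reproducible subject; bit-identical for identical inputs."""
    if group not in spec.groups:
        raise KeyError(f"unknown group {group!r}")
    g = spec.groups[group]
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_seed]))
    shape = spec.image_shape
    affine = spec.affine
    left = spec.roi_left.mask_array(shape)
    right = spec.roi_right.mask_array(shape)
    roi = left | right
    sid = f"sub-{subject_seed:03d}"

    # --- structural: smoothed Gaussian random field, kernel width by group
    sigma = (
        spec.struct_sigma
        * (1.0 + spec.texture_effect * g.texture_scale)
        * np.exp(rng.normal(0.0, spec.struct_sigma_sd))
    )
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, sigma)
    field_roi = _standardize(smooth, roi) * spec.struct_amp
    structural = spec.baseline_structural + rng.standard_normal(shape) * spec.struct_amp
    structural[roi] = spec.baseline_structural + field_roi[roi]

    # --- functional: baseline + drift + in-band sinusoids (ROI) + noise
    n_t = spec.n_volumes
    t_sec = np.arange(n_t) * spec.tr_seconds
    func = rng.standard_normal(shape + (n_t,)) * spec.noise_sd
    func += spec.baseline_functional + spec.drift_slope * t_sec
    amp_subject = (
        spec.osc_amp
        * (1.0 + spec.alff_effect * g.alff_scale)
        * np.exp(rng.normal(0.0, spec.subject_amp_sd))
    )
    # smooth per-voxel modulation field -> spatial texture in the ALFF map
    mod = 1.0 + 0.15 * _standardize(gaussian_filter(rng.standard_normal(shape), 1.0), roi)
    mod = np.clip(mod, 0.2, None)[roi]  # (V,)
    n_vox = int(roi.sum())
    signal = np.zeros((n_vox, n_t))
    for f_hz in spec.osc_freqs:
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_vox)
        signal += np.sin(2.0 * np.pi * f_hz * t_sec[None, :] + phases[:, None])
        # amplitude applied below so every component shares the subject factor
    func[roi] += amp_subject * mod[:, None] * signal

    # --- motion: random walk with optional planted jump / scaled steps
    ov = spec.motion.overrides.get(sid, MotionOverride())
    steps = rng.normal(0.0, 1.0, size=(n_t, 6))
    steps[:, :3] *= spec.motion.step_translation_mm * ov.step_scale
    steps[:, 3:] *= spec.motion.step_rotation_rad * ov.step_scale
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    if ov.jump_translation_mm or ov.jump_rotation_deg:
        half = n_t // 2
        params[half:, 0] += ov.jump_translation_mm
        params[half:, 3] += np.radians(ov.jump_rotation_deg)
    motion = MotionTrace(params)

    score = float(rng.normal(g.score_mean, g.score_sd))

    return SyntheticSubject(
        subject_id=sid,
        group=group,
        structural=VolumeImage(structural, affine),
        functional=TimeSeriesImage(func, affine, spec.tr_seconds),
        mask_left=ROIMask(left, affine),
        mask_right=ROIMask(right, affine),
        motion=motion,
        score=score,
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """All subjects of the spec, in group order, with the subject table."""
    subjects = []
    idx = 0
    for group, g in spec.groups.items():
        for _ in range(g.n):
            subjects.append(generate_subject(spec, group, idx))
            idx += 1
    table = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "group": [s.group for s in subjects],
            "score": [s.score for s in subjects],
        }
    )
    return Cohort(spec, subjects, table)


def _spec_to_jsonable(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["groups"] = {k: dataclasses.asdict(v) for k, v in spec.groups.items()}
    d["motion"]["overrides"] = {
        k: dataclasses.asdict(v) for k, v in spec.motion.overrides.items()
    }
    return d


def save_cohort(cohort: Cohort, outdir: str | Path) -> pd.DataFrame:
    """Write NIfTI images, masks, motion text files, table CSV and sidecar.

    Returns the subject table with the ``motion_path`` column filled in.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    motion_paths = []
    for s in cohort.subjects:
        s.structural.save(outdir / f"{s.subject_id}_T1w.nii.gz")
        s.functional.save(outdir / f"{s.subject_id}_bold.nii.gz")
        s.mask_left.save(outdir / f"{s.subject_id}_mask-left.nii.gz")
        s.mask_right.save(outdir / f"{s.subject_id}_mask-right.nii.gz")
        mpath = outdir / f"{s.subject_id}_motion.txt"
        s.motion.save(mpath)
        motion_paths.append(mpath.name)
    table = cohort.table.copy()
    table["motion_path"] = motion_paths
    table.to_csv(outdir / "subjects.csv", index=False)
    sidecar = {"spec": _spec_to_jsonable(cohort.spec), "seed": cohort.spec.seed}
    (outdir / "cohort.json").write_text(json.dumps(sidecar, indent=2, default=str))
    return table
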