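"""Declarative pipeline configuration (YAML) with explicit validation.

All defaults equal the emulated study's stated parameters: slow-5 band
0.01–0.027 Hz, 10 discarded volumes, motion limits 3 mm / 3 deg / mean FD
0.5 mm, 32 gray levels, mRMR top 20, 10-fold LASSO CV, stratified 70/30
splits repeated 10 times. Validation errors name the offending field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluation import SplitScheme
from .preproc import BandSpec, QCThresholds

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised with the name of the offending config field."""


@dataclass
class CohortConfig:
    simulate: bool = True
    path: str | None = None  # existing cohort directory (subjects.csv inside)
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"AD": 84, "aMCI": 50, "NC": 44}
    )
    texture_effect: float = 0.5
    alff_effect: float = 0.5
    image_shape: tuple[int, int, int] = (24, 24, 20)
    n_volumes: int = 210
    tr_seconds: float = 2.0
    noise_sd: float = 1.0


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "hipporad-out"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    band: BandSpec = field(default_factory=BandSpec)
    qc: QCThresholds = field(default_factory=QCThresholds)
    n_bins: int = 32
    mrmr_k: int = 20
    folds: int = 10
    split: SplitScheme = field(default_factory=SplitScheme)
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("AD", "NC"), ("aMCI", "NC")]
    )
    rois: list[str] = field(default_factory=lambda: ["left", "right"])
    modalities: list[str] = field(default_factory=lambda: ["T1-w", "ALFF", "combined"])

    def validate(self) -> None:
        if self.n_bins < 2:
            raise ConfigError("n_bins must be >= 2")
        if self.mrmr_k < 1:
            raise ConfigError("mrmr_k must be >= 1")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        for roi in self.rois:
            if roi not in ("left", "right", "bilateral"):
                raise ConfigError(f"rois: unknown ROI {roi!r}")
        for m in self.modalities:
            if m not in ("T1-w", "ALFF", "combined"):
                raise ConfigError(f"modalities: unknown modality {m!r}")
        if not self.cohort.simulate:
            if not self.cohort.path:
                raise ConfigError("cohort.path is required when cohort.simulate is false")
            p = Path(self.cohort.path)
            if not (p / "subjects.csv").exists():
                raise ConfigError(f"cohort.path: no subjects.csv under {p}")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        from . import __version__

        return {"config_hash": self.hash(), "seed": self.seed, "version": __version__}


_SECTION_TYPES = {
    "cohort": CohortConfig,
    "band": BandSpec,
    "qc": QCThresholds,
    "split": SplitScheme,
}


def _build(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{section}: unknown field(s) {sorted(unknown)}")
    try:
        return cls(**{
            k: tuple(v) if isinstance(v, list) and k == "image_shape" else v
            for k, v in data.items()
        })
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{section}: {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    top_names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - top_names
    if unknown:
        raise ConfigError(f"unknown top-level field(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigError(f"{key}: must be a mapping")
            kwargs[key] = _build(_SECTION_TYPES[key], value, key)
        elif key == "contrasts":
            kwargs[key] = [tuple(c) for c in value]
        else:
            kwargs[key] = value
    cfg = _build(PipelineConfig, kwargs, "config")
    cfg.validate()
    return cfg
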