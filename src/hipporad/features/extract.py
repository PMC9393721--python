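"""Feature-vector assembly: 13 intensity + 88 textural = 101 named features.

The textural roster spans five matrix families (GLCM 25, GLRLM 16, GLSZM 16,
GLDZM 16, NGLDM 15). Feature names are prefixed with the modality and family,
e.g. ``T1-w_GLRLM_RLN`` or ``ALFF_GLCM_Correlation``, matching the naming
used in hippocampal radiomics reports. A combined structural+ALFF extraction
therefore yields 202 candidate features per ROI.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..images import ROIMask, VolumeImage
from .intensity import INTENSITY_NAMES, intensity_features
from .texture import (
    discretize,
    glcm_features,
    gldzm_features,
    glrlm_features,
    glszm_features,
    ngldm_features,
)

__all__ = [
    "FEATURE_ROSTER",
    "feature_names",
    "roster_manifest",
    "extract_feature_vector",
    "extract_table",
]

_GLCM = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Dissimilarity", "Energy", "Entropy", "IMC1", "IMC2",
    "InverseDifference", "InverseDifferenceMoment",
    "InverseDifferenceMomentNormalized", "InverseDifferenceNormalized",
    "InverseVariance", "JointAverage", "JointMaximum", "JointVariance",
    "SumAverage", "SumEntropy", "SumVariance",
)
_GLRLM = (
    "SRE", "LRE", "LGLRE", "HGLRE", "SRLGLE", "SRHGLE", "LRLGLE", "LRHGLE",
    "GLN", "GLNN", "RLN", "RLNN", "RP", "GLV", "RLV", "RE",
)
_GLSZM = (
    "SAE", "LAE", "LGLZE", "HGLZE", "SALGLE", "SAHGLE", "LALGLE", "LAHGLE",
    "GLN", "GLNN", "ZSN", "ZSNN", "ZP", "GLV", "ZSV", "ZSE",
)
_GLDZM = (
    "SDE", "LDE", "LGLZE", "HGLZE", "SDLGLE", "SDHGLE", "LDLGLE", "LDHGLE",
    "GLN", "GLNN", "ZDN", "ZDNN", "ZP", "GLV", "ZDV", "ZDE",
)
_NGLDM = (
    "SDE", "LDE", "LGLE", "HGLE", "SDLGLE", "SDHGLE", "LDLGLE", "LDHGLE",
    "GLN", "GLNN", "DN", "DNN", "GLV", "DV", "DE",
)

#: Family -> ordered feature names. 13 + 25 + 16 + 16 + 16 + 15 = 101.
FEATURE_ROSTER: dict[str, tuple[str, ...]] = {
    "Intensity": INTENSITY_NAMES,
    "GLCM": _GLCM,
    "GLRLM": _GLRLM,
    "GLSZM": _GLSZM,
    "GLDZM": _GLDZM,
    "NGLDM": _NGLDM,
}

_TEXTURE_FUNCS = {
    "GLCM": glcm_features,
    "GLRLM": glrlm_features,
    "GLSZM": glszm_features,
    "GLDZM": gldzm_features,
    "NGLDM": ngldm_features,
}


def feature_names(modality: str = "T1-w") -> list[str]:
    """Ordered, modality-prefixed names of the 101 features."""
    return [
        f"{modality}_{family}_{name}"
        for family, names in FEATURE_ROSTER.items()
        for name in names
    ]


def roster_manifest() -> dict:
    """JSON-serializable roster description (counts and names per family)."""
    return {
        "n_features": sum(len(v) for v in FEATURE_ROSTER.values()),
        "n_intensity": len(FEATURE_ROSTER["Intensity"]),
        "n_textural": sum(len(v) for k, v in FEATURE_ROSTER.items() if k != "Intensity"),
        "families": {k: list(v) for k, v in FEATURE_ROSTER.items()},
    }


def save_roster_manifest(path: str | Path) -> None:
    Path(path).write_text(json.dumps(roster_manifest(), indent=2))


def extract_feature_vector(
    image: VolumeImage | np.ndarray,
    mask: ROIMask | np.ndarray,
    n_bins: int = 32,
    modality: str = "T1-w",
) -> pd.Series:
    """All 101 features of one image restricted to one ROI.

    Deterministic; raises on an empty ROI or non-finite intensities.
    """
    img = image.data if isinstance(image, VolumeImage) else np.asarray(image, dtype=float)
    msk = mask.data if isinstance(mask, ROIMask) else np.asarray(mask).astype(bool)
    if isinstance(image, VolumeImage) and isinstance(mask, ROIMask) and not image.same_grid(mask):
        raise ValueError("image and mask geometries differ")
    values: dict[str, float] = {}
    fam = intensity_features(img, msk, n_bins)
    for name in FEATURE_ROSTER["Intensity"]:
        values[f"{modality}_Intensity_{name}"] = fam[name]
    d = discretize(img, msk, n_bins)
    for family, func in _TEXTURE_FUNCS.items():
        fam = func(d)
        for name in FEATURE_ROSTER[family]:
            values[f"{modality}_{family}_{name}"] = fam[name]
    s = pd.Series(values, dtype=float)
    if not np.all(np.isfinite(s.to_numpy())):
        bad = s.index[~np.isfinite(s.to_numpy())].tolist()
        raise ValueError(f"non-finite feature values: {bad}")
    return s


def extract_table(
    images: dict[str, VolumeImage],
    masks: dict[str, ROIMask],
    n_bins: int = 32,
    modality: str = "T1-w",
) -> pd.DataFrame:
    """Feature table (subjects x 101) for one modality and one ROI.

    ``images`` and ``masks`` are keyed by subject id; masks may be shared
    (same object) across subjects.
    """
    rows = {}
    for sid, img in images.items():
        rows[sid] = extract_feature_vector(img, masks[sid], n_bins, modality)
    return pd.DataFrame.from_dict(rows, orient="index")
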