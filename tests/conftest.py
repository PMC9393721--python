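import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from hipporad import CohortSpec, EllipsoidROI, GroupSpec, MotionProfile


def small_spec(
    n_case: int = 8,
    n_control: int = 8,
    texture_effect: float = 0.0,
    alff_effect: float = 0.0,
    seed: int = 0,
    motion: MotionProfile | None = None,
    n_volumes: int = 210,
) -> CohortSpec:
    """A compact two-group cohort used throughout the suite: 16x16x12
    voxels, two ~80-voxel ellipsoidal ROIs, study-default timing."""
    return CohortSpec(
        groups={
            "case": GroupSpec(n_case, texture_scale=1.0, alff_scale=1.0,
                              score_mean=20.0, score_sd=3.0),
            "control": GroupSpec(n_control, score_mean=29.0, score_sd=1.0),
        },
        image_shape=(16, 16, 12),
        roi_left=EllipsoidROI((4.5, 8.0, 6.0), (3.0, 3.0, 2.5)),
        roi_right=EllipsoidROI((11.5, 8.0, 6.0), (3.0, 3.0, 2.5)),
        texture_effect=texture_effect,
        alff_effect=alff_effect,
        n_volumes=n_volumes,
        seed=seed,
        motion=motion or MotionProfile(),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


def random_levels(rng, shape=(4, 4, 4), n_levels=4, p_roi=0.8) -> np.ndarray:
    """Random small discretized ROI: levels 1..n_levels, 0 = outside."""
    lv = rng.integers(1, n_levels + 1, size=shape)
    lv[rng.random(shape) > p_roi] = 0
    if not (lv > 0).any():
        lv[0, 0, 0] = 1
    return lv.astype(np.int32)
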