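"""Canned simulation studies on synthetic cohorts.

These drive the package's calibration and recovery experiments: null
calibration of the full signature pipeline (planted effects = 0 must give
chance-level test AUC), monotone response of the test AUC to the planted
ALFF effect, modality ordering under a function-only effect, and the
combined-model advantage under dual effects. They are also reused by the
statistical null calibrations of the DeLong and rank-sum tests.

All sizes are parameters; the defaults are the scaled-down conditions the
package documents in its methods note (two groups of 20 subjects on a
16x16x12 grid, 210 volumes at TR=2 s, slow-5 band, bilateral ROI, 5
repetitions of the 70/30 split per cohort).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import SplitScheme, auc_mann_whitney, delong_test, split_cohort, wilcoxon_ranksum
from .features import extract_feature_vector
from .preproc import BandSpec, alff_pipeline
from .roi import combine_bilateral
from .signature import build_signature, radscore
from .synthetic import CohortSpec, EllipsoidROI, GroupSpec, generate_subject

__all__ = [
    "two_group_spec",
    "cohort_feature_tables",
    "pipeline_test_aucs",
    "null_auc_study",
    "effect_grid_study",
    "modality_comparison_study",
    "dual_effect_study",
    "delong_null_rejection_rate",
    "wilcoxon_null_rejection_rate",
]


def two_group_spec(
    n_per_group: int = 20,
    texture_effect: float = 0.0,
    alff_effect: float = 0.0,
    seed: int = 0,
) -> CohortSpec:
    """A compact patient/control cohort on a 16x16x12 grid."""
    return CohortSpec(
        groups={
            "case": GroupSpec(n_per_group, texture_scale=1.0, alff_scale=1.0,
                              score_mean=20.0, score_sd=3.0),
            "control": GroupSpec(n_per_group, score_mean=29.0, score_sd=1.0),
        },
        image_shape=(16, 16, 12),
        roi_left=EllipsoidROI((4.5, 8.0, 6.0), (3.0, 3.0, 2.5)),
        roi_right=EllipsoidROI((11.5, 8.0, 6.0), (3.0, 3.0, 2.5)),
        texture_effect=texture_effect,
        alff_effect=alff_effect,
        seed=seed,
    )


def cohort_feature_tables(
    spec: CohortSpec,
    modalities: tuple[str, ...] = ("T1-w", "ALFF"),
    band: BandSpec | None = None,
    n_bins: int = 32,
) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Generate the cohort and extract bilateral-ROI feature tables.

    Returns ``({modality: table}, labels)`` with labels True for the first
    (patient) group. The ALFF channel runs the full preprocessing chain
    (discard, Friston-24 + trend regression, band amplitude).
    """
    band = band or BandSpec()
    need_alff = "ALFF" in modalities
    rows: dict[str, dict[str, pd.Series]] = {m: {} for m in modalities}
    labels = {}
    idx = 0
    group_names = list(spec.groups)
    for gi, group in enumerate(group_names):
        for _ in range(spec.groups[group].n):
            s = generate_subject(spec, group, idx)
            idx += 1
            mask = combine_bilateral(s.mask_left, s.mask_right)
            if "T1-w" in modalities:
                rows["T1-w"][s.subject_id] = extract_feature_vector(
                    s.structural, mask, n_bins=n_bins, modality="T1-w"
                )
            if need_alff:
                amap = alff_pipeline(s.functional, mask, s.motion, band)
                rows["ALFF"][s.subject_id] = extract_feature_vector(
                    amap.volume, mask, n_bins=n_bins, modality="ALFF"
                )
            labels[s.subject_id] = gi == 0
    tables = {m: pd.DataFrame.from_dict(rows[m], orient="index") for m in modalities}
    return tables, pd.Series(labels)


def pipeline_test_aucs(
    tables: dict[str, pd.DataFrame],
    labels: pd.Series,
    modalities: tuple[str, ...],
    n_repetitions: int = 5,
    mrmr_k: int = 20,
    folds: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Mean held-out AUC per modality over repeated stratified 70/30 splits.

    "combined" concatenates the structural and ALFF tables column-wise.
    Splits are shared across modalities within a repetition.
    """
    scheme = SplitScheme(n_repetitions=n_repetitions, seed=seed)
    full = dict(tables)
    if "combined" in modalities:
        full["combined"] = pd.concat([tables["T1-w"], tables["ALFF"]], axis=1)
    aucs: dict[str, list[float]] = {m: [] for m in modalities}
    for rep in range(n_repetitions):
        train_ids, test_ids = split_cohort(labels, scheme, rep)
        for m in modalities:
            t = full[m]
            rep_seed = int(
                np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31 - 1)
            )
            model = build_signature(
                t.loc[train_ids], labels.loc[train_ids],
                mrmr_k=mrmr_k, folds=folds, seed=rep_seed,
            )
            scores = radscore(model, t.loc[test_ids])
            aucs[m].append(
                auc_mann_whitney(scores.to_numpy(), labels.loc[test_ids].to_numpy())
            )
    return {m: float(np.mean(v)) for m, v in aucs.items()}


def _run_cohorts(
    n_cohorts: int,
    seed: int,
    modalities: tuple[str, ...],
    texture_effect: float,
    alff_effect: float,
    n_per_group: int,
    n_repetitions: int,
    folds: int,
) -> list[dict[str, float]]:
    out = []
    for c in range(n_cohorts):
        cohort_seed = int(np.random.SeedSequence([seed, c]).generate_state(1)[0] % (2**31 - 1))
        spec = two_group_spec(
            n_per_group=n_per_group, texture_effect=texture_effect,
            alff_effect=alff_effect, seed=cohort_seed,
        )
        base = tuple(m for m in ("T1-w", "ALFF") if m in modalities or "combined" in modalities)
        tables, labels = cohort_feature_tables(spec, base)
        out.append(
            pipeline_test_aucs(
                tables, labels, modalities,
                n_repetitions=n_repetitions, folds=folds, seed=cohort_seed,
            )
        )
    return out


def null_auc_study(
    n_cohorts: int = 20, n_per_group: int = 20, seed: int = 0,
    n_repetitions: int = 5, folds: int = 10,
    with_permutation_reference: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Per-cohort mean test AUC of the structural signature with both
    planted effects at zero (groups exchangeable).

    Note that the expectation of held-out AUC under the null is slightly
    below 0.5: repeated 70/30 splitting of a small finite cohort without
    replacement anti-correlates the train-selected features with the
    complementary test subjects (split-induced pessimism). With
    ``with_permutation_reference=True`` the same cohorts are re-evaluated
    with randomly permuted labels, giving the correct Monte-Carlo null
    reference of the identical procedure; returns ``(aucs, aucs_permuted)``.
    """
    aucs = []
    aucs_perm = []
    for c in range(n_cohorts):
        cohort_seed = int(np.random.SeedSequence([seed, c]).generate_state(1)[0] % (2**31 - 1))
        spec = two_group_spec(n_per_group=n_per_group, seed=cohort_seed)
        tables, labels = cohort_feature_tables(spec, ("T1-w",))
        res = pipeline_test_aucs(tables, labels, ("T1-w",),
                                 n_repetitions=n_repetitions, folds=folds,
                                 seed=cohort_seed)
        aucs.append(res["T1-w"])
        if with_permutation_reference:
            rng = np.random.default_rng(np.random.SeedSequence([seed, c, 1]))
            permuted = pd.Series(
                rng.permutation(labels.to_numpy()), index=labels.index
            )
            res_p = pipeline_test_aucs(tables, permuted, ("T1-w",),
                                       n_repetitions=n_repetitions, folds=folds,
                                       seed=cohort_seed + 1)
            aucs_perm.append(res_p["T1-w"])
    if with_permutation_reference:
        return np.array(aucs), np.array(aucs_perm)
    return np.array(aucs)


def effect_grid_study(
    alff_effects: tuple[float, ...] = (0.0, 0.6, 1.5),
    n_cohorts: int = 10, n_per_group: int = 20, seed: int = 0,
    n_repetitions: int = 5, folds: int = 10,
) -> dict[float, np.ndarray]:
    """Per-cohort ALFF-signature test AUCs along a planted-effect grid."""
    out = {}
    for k, eff in enumerate(alff_effects):
        res = _run_cohorts(n_cohorts, seed + 7919 * k, ("ALFF",), 0.0, eff,
                           n_per_group, n_repetitions, folds)
        out[eff] = np.array([r["ALFF"] for r in res])
    return out


def modality_comparison_study(
    alff_effect: float = 1.0, n_cohorts: int = 10, n_per_group: int = 20,
    seed: int = 0, n_repetitions: int = 5, folds: int = 10,
) -> dict[str, np.ndarray]:
    """Function-only planted effect: ALFF vs structural signature AUCs."""
    res = _run_cohorts(n_cohorts, seed, ("T1-w", "ALFF"), 0.0, alff_effect,
                       n_per_group, n_repetitions, folds)
    return {
        "ALFF": np.array([r["ALFF"] for r in res]),
        "T1-w": np.array([r["T1-w"] for r in res]),
    }


def dual_effect_study(
    texture_effect: float = 1.0, alff_effect: float = 1.0,
    n_cohorts: int = 10, n_per_group: int = 20, seed: int = 0,
    n_repetitions: int = 5, folds: int = 10,
) -> list[dict[str, float]]:
    """Both effects planted: per-cohort AUC of all three modality models."""
    return _run_cohorts(n_cohorts, seed, ("T1-w", "ALFF", "combined"),
                        texture_effect, alff_effect, n_per_group,
                        n_repetitions, folds)


def combined_best_fraction(results: list[dict[str, float]], slack: float = 0.02) -> float:
    """Fraction of cohorts where the combined model is within ``slack`` of
    (or above) the best single-modality model."""
    wins = sum(
        1 for r in results
        if r["combined"] >= max(r["T1-w"], r["ALFF"]) - slack
    )
    return wins / len(results)


def delong_null_rejection_rate(
    n_reps: int = 5000, n_pos: int = 60, n_neg: int = 40,
    alpha: float = 0.05, seed: int = 0,
) -> float:
    """Empirical type-I error of the paired AUC comparison under
    independent-noise scores."""
    rng = np.random.default_rng(seed)
    y = np.r_[np.ones(n_pos), np.zeros(n_neg)].astype(bool)
    hits = 0
    for _ in range(n_reps):
        a = rng.normal(size=n_pos + n_neg)
        b = rng.normal(size=n_pos + n_neg)
        if delong_test(a, b, y).p < alpha:
            hits += 1
    return hits / n_reps


def wilcoxon_null_rejection_rate(
    n_reps: int = 5000, n_per_group: int = 30, alpha: float = 0.05, seed: int = 0
) -> float:
    """Empirical type-I error of the rank-sum test on identical normals."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        a = rng.normal(size=n_per_group)
        b = rng.normal(size=n_per_group)
        if wilcoxon_ranksum(a, b)[1] < alpha:
            hits += 1
    return hits / n_reps
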