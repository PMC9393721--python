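"""Repeated-split evaluation of radiomic signatures.

For every (contrast x ROI x modality) cell the experiment repeats, over
stratified 70/30 splits: train the signature on the training rows, score
train and test subjects, and record ROC results. The reported figure of
merit is the arithmetic mean of the per-repetition AUCs. DeLong tests
compare correlated AUCs between modality models fitted on the same split
(combined vs structural, structural vs ALFF), Wilcoxon rank-sum tests
compare case vs control radscores, and Spearman correlations relate the
retained combined-model features to the clinical score of case subjects.

The AUC is the Mann-Whitney statistic (ties weighted 1/2); its 95% CI uses
the DeLong variance with a normal interval truncated to [0, 1]. Accuracy is
reported at the Youden-optimal threshold of the training ROC, applied
unchanged to the test set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .signature import SignatureModel, build_signature, radscore

__all__ = [
    "SplitScheme",
    "ROCResult",
    "DeLongResult",
    "CorrelationResult",
    "split_cohort",
    "roc_auc",
    "auc_mann_whitney",
    "delong_test",
    "wilcoxon_ranksum",
    "spearman",
    "run_experiment",
    "apply_frozen_model",
    "EvaluationReport",
]


@dataclass(frozen=True)
class SplitScheme:
    train_fraction: float = 0.7
    stratified: bool = True
    n_repetitions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


def split_cohort(
    labels: pd.Series, scheme: SplitScheme, repetition: int
) -> tuple[list, list]:
    """Stratified train/test split, reproducible per (scheme, repetition).

    Per class, ``round(train_fraction * n_class)`` subjects go to training.
    """
    y = pd.Series(labels)
    train: list = []
    test: list = []
    rng = np.random.default_rng(np.random.SeedSequence([scheme.seed, repetition]))
    classes = sorted(y.unique(), key=str) if scheme.stratified else [None]
    for cls in classes:
        ids = y.index[y == cls].to_numpy() if cls is not None else y.index.to_numpy()
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        perm = rng.permutation(len(ids))
        n_train = int(round(scheme.train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[perm[:n_train]])
        test.extend(ids[perm[n_train:]])
    return train, test


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the tie-corrected Mann-Whitney statistic U / (n1 * n0)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = labels.sum(), (~labels).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _delong_placements(scores: np.ndarray, labels: np.ndarray):
    """Placement values (structural components) V10 (cases), V01 (controls)."""
    pos = scores[labels]
    neg = scores[~labels]
    # midrank-based placements
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01


def _delong_variance(v10a, v01a, v10b=None, v01b=None) -> float:
    m, n = len(v10a), len(v01a)
    if v10b is None:
        return float(np.var(v10a, ddof=1) / m + np.var(v01a, ddof=1) / n)
    s10 = np.cov(v10a, v10b, ddof=1)
    s01 = np.cov(v01a, v01b, ddof=1)
    return float(
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )


@dataclass
class ROCResult:
    auc: float
    ci: tuple[float, float]
    accuracy: float
    threshold: float
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


@dataclass
class DeLongResult:
    z: float
    p: float
    auc_diff: float


@dataclass
class CorrelationResult:
    feature: str
    rho: float
    p: float


def roc_auc(
    scores: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    threshold: float | None = None,
) -> ROCResult:
    """AUC with DeLong 95% CI, ROC curve, and accuracy at a threshold.

    When ``threshold`` is None, the Youden-optimal threshold of this ROC is
    used (score > threshold predicts the positive class).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    auc = auc_mann_whitney(s, y)
    v10, v01 = _delong_placements(s, y)
    var = _delong_variance(v10, v01)
    se = np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - 1.959963984540054 * se), min(1.0, auc + 1.959963984540054 * se))

    order = np.argsort(-s, kind="stable")
    thresholds = s[order]
    tps = np.cumsum(y[order])
    fps = np.cumsum(~y[order])
    # collapse tied scores to the last index of each tie block
    distinct = np.flatnonzero(np.diff(thresholds) != 0)
    idx = np.concatenate([distinct, [len(s) - 1]])
    tpr = np.concatenate([[0.0], tps[idx] / y.sum()])
    fpr = np.concatenate([[0.0], fps[idx] / (~y).sum()])
    if threshold is None:
        youden = tpr[1:] - fpr[1:]
        best = int(np.argmax(youden))
        threshold = float(thresholds[idx[best]])
    pred = s >= threshold
    accuracy = float((pred == y).mean())
    return ROCResult(auc, ci, accuracy, float(threshold), fpr, tpr)


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> DeLongResult:
    """DeLong test for the difference of two correlated AUCs."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(bool)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("paired scores must share the subjects")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    auc_a = auc_mann_whitney(a, y)
    auc_b = auc_mann_whitney(b, y)
    diff = auc_a - auc_b
    v10a, v01a = _delong_placements(a, y)
    v10b, v01b = _delong_placements(b, y)
    var = _delong_variance(v10a, v01a, v10b, v01b)
    if var <= 0:
        if diff == 0:
            return DeLongResult(0.0, 1.0, 0.0)
        raise ValueError("zero variance with nonzero AUC difference")
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongResult(float(z), float(max(p, np.finfo(float).tiny)), float(diff))


def wilcoxon_ranksum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample rank-sum test; exact for n <= 10 per group without ties,
    tie-corrected normal approximation otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def spearman(x: np.ndarray, y: np.ndarray, feature: str = "") -> CorrelationResult:
    """Spearman rank correlation (midranks for ties) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("zero rank variance")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(feature, float(rho), float(p))


# ---------------------------------------------------------------------------
# Experiment driver


@dataclass
class EvaluationReport:
    """Per-repetition and aggregated results of the signature experiment."""

    cells: list[dict]
    delong: list[dict]
    wilcoxon: list[dict]
    correlations: list[dict]
    scheme: SplitScheme
    n_signatures: int

    def cell_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            for r in c["repetitions"]:
                rows.append(
                    {
                        "contrast": c["contrast"],
                        "roi": c["roi"],
                        "modality": c["modality"],
                        **{k: r[k] for k in (
                            "repetition", "train_auc", "test_auc",
                            "train_accuracy", "test_accuracy",
                        )},
                    }
                )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "contrast": c["contrast"],
                "roi": c["roi"],
                "modality": c["modality"],
                "mean_train_auc": c["mean_train_auc"],
                "mean_test_auc": c["mean_test_auc"],
                "train_auc_ci_low": c["train_auc_ci"][0],
                "train_auc_ci_high": c["train_auc_ci"][1],
            }
            for c in self.cells
        ]
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path, provenance: dict | None = None) -> None:
        d = {
            "provenance": provenance or {},
            "scheme": {
                "train_fraction": self.scheme.train_fraction,
                "stratified": self.scheme.stratified,
                "n_repetitions": self.scheme.n_repetitions,
                "seed": self.scheme.seed,
            },
            "n_signatures": self.n_signatures,
            "cells": self.cells,
            "delong": self.delong,
            "wilcoxon": self.wilcoxon,
            "correlations": self.correlations,
        }
        Path(path).write_text(json.dumps(d, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _signature_seed(scheme_seed: int, *indices: int) -> int:
    ss = np.random.SeedSequence([scheme_seed, *indices])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_experiment(
    tables: dict[tuple[str, str], pd.DataFrame],
    groups: pd.Series,
    clinical: pd.Series | None,
    contrasts: list[tuple[str, str]],
    rois: list[str],
    modalities: list[str] = ("T1-w", "ALFF", "combined"),
    scheme: SplitScheme | None = None,
    mrmr_k: int = 20,
    folds: int = 10,
    delong_on: str = "train",
    keep_models: bool = False,
) -> EvaluationReport:
    """The full (contrast x ROI x modality) signature experiment.

    ``tables`` maps (roi, modality) to a subjects-x-features frame; the
    "combined" modality is formed by column-concatenating the "T1-w" and
    "ALFF" tables of the same ROI when not supplied explicitly. The same
    train/test split (per contrast and repetition) is shared across ROIs and
    modalities so DeLong comparisons are paired. Cells that fail are recorded
    with their error and do not interrupt the experiment.
    """
    scheme = scheme or SplitScheme()
    modalities = list(modalities)
    cells: list[dict] = []
    delong_rows: list[dict] = []
    wilcoxon_rows: list[dict] = []
    correlations: list[dict] = []

    def _table(roi: str, modality: str) -> pd.DataFrame:
        if (roi, modality) in tables:
            return tables[(roi, modality)]
        if modality == "combined":
            return pd.concat([tables[(roi, "T1-w")], tables[(roi, "ALFF")]], axis=1)
        raise KeyError(f"no feature table for ({roi}, {modality})")

    n_signatures = 0
    for ci, (case, control) in enumerate(contrasts):
        contrast = f"{case}-vs-{control}"
        sel = groups[groups.isin([case, control])]
        y_all = (sel == case)
        splits = [split_cohort(y_all, scheme, rep) for rep in range(scheme.n_repetitions)]
        # per-(roi, rep): modality -> train scores (for paired DeLong)
        train_scores: dict[tuple[str, int], dict[str, np.ndarray]] = {}
        for ri, roi in enumerate(rois):
            retained_counts: dict[str, int] = {}
            for mi, modality in enumerate(modalities):
                cell = {
                    "contrast": contrast, "roi": roi, "modality": modality,
                    "repetitions": [], "failed": False, "error": None,
                }
                try:
                    table = _table(roi, modality).loc[sel.index]
                    models = []
                    for rep, (train_ids, test_ids) in enumerate(splits):
                        seed = _signature_seed(scheme.seed, ci, ri, mi, rep)
                        model = build_signature(
                            table.loc[train_ids], y_all.loc[train_ids],
                            mrmr_k=mrmr_k, folds=folds, seed=seed,
                        )
                        s_train = radscore(model, table.loc[train_ids])
                        s_test = radscore(model, table.loc[test_ids])
                        roc_train = roc_auc(s_train, y_all.loc[train_ids])
                        roc_test = roc_auc(
                            s_test, y_all.loc[test_ids], threshold=roc_train.threshold
                        )
                        key = (roi, rep)
                        train_scores.setdefault(key, {})[modality] = (
                            s_train.to_numpy(), y_all.loc[train_ids].to_numpy()
                        )
                        if modality == "combined":
                            for f in model.feature_names:
                                retained_counts[f] = retained_counts.get(f, 0) + 1
                        w_tr = wilcoxon_ranksum(
                            s_train[y_all.loc[train_ids]], s_train[~y_all.loc[train_ids]]
                        )
                        w_te = wilcoxon_ranksum(
                            s_test[y_all.loc[test_ids]], s_test[~y_all.loc[test_ids]]
                        )
                        wilcoxon_rows.append({
                            "contrast": contrast, "roi": roi, "modality": modality,
                            "repetition": rep, "train_p": w_tr[1], "test_p": w_te[1],
                        })
                        cell["repetitions"].append({
                            "repetition": rep,
                            "train_auc": roc_train.auc,
                            "train_auc_ci": roc_train.ci,
                            "test_auc": roc_test.auc,
                            "test_auc_ci": roc_test.ci,
                            "train_accuracy": roc_train.accuracy,
                            "test_accuracy": roc_test.accuracy,
                            "threshold": roc_train.threshold,
                            "n_features": len(model.feature_names),
                            "features": model.feature_names,
                        })
                        models.append(model)
                    reps = cell["repetitions"]
                    cell["mean_train_auc"] = float(np.mean([r["train_auc"] for r in reps]))
                    cell["mean_test_auc"] = float(np.mean([r["test_auc"] for r in reps]))
                    cell["train_auc_ci"] = [
                        float(np.mean([r["train_auc_ci"][0] for r in reps])),
                        float(np.mean([r["train_auc_ci"][1] for r in reps])),
                    ]
                    cell["mean_train_accuracy"] = float(
                        np.mean([r["train_accuracy"] for r in reps])
                    )
                    cell["mean_test_accuracy"] = float(
                        np.mean([r["test_accuracy"] for r in reps])
                    )
                    if keep_models:
                        cell["models"] = models
                    n_signatures += 1
                except Exception as exc:  # noqa: BLE001 — cell isolation by contract
                    cell["failed"] = True
                    cell["error"] = f"{type(exc).__name__}: {exc}"
                cells.append(cell)

            # paired DeLong comparisons within this (contrast, roi)
            for pair in (("combined", "T1-w"), ("T1-w", "ALFF")):
                if pair[0] not in modalities or pair[1] not in modalities:
                    continue
                for rep in range(scheme.n_repetitions):
                    got = train_scores.get((roi, rep), {})
                    if pair[0] in got and pair[1] in got:
                        sa, ya = got[pair[0]]
                        sb, _ = got[pair[1]]
                        try:
                            res = delong_test(sa, sb, ya)
                            delong_rows.append({
                                "contrast": contrast, "roi": roi,
                                "model_a": pair[0], "model_b": pair[1],
                                "repetition": rep, "z": res.z, "p": res.p,
                                "auc_diff": res.auc_diff, "on": delong_on,
                            })
                        except ValueError:
                            pass

            # Spearman of retained combined-model features vs clinical score
            if clinical is not None and retained_counts:
                case_ids = sel.index[sel == case]
                half = scheme.n_repetitions / 2.0
                for f, cnt in sorted(retained_counts.items()):
                    if cnt < half:
                        continue
                    table = _table(roi, "combined").loc[case_ids]
                    try:
                        res = spearman(
                            table[f].to_numpy(), clinical.loc[case_ids].to_numpy(), f
                        )
                        correlations.append({
                            "contrast": contrast, "roi": roi, "feature": f,
                            "rho": res.rho, "p": res.p, "n_retained": cnt,
                        })
                    except ValueError:
                        pass

    return EvaluationReport(
        cells=cells,
        delong=delong_rows,
        wilcoxon=wilcoxon_rows,
        correlations=correlations,
        scheme=scheme,
        n_signatures=n_signatures,
    )


def apply_frozen_model(
    model: SignatureModel,
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    threshold: float | None = None,
) -> ROCResult:
    """Score an external cohort with a stored model; nothing is re-fitted."""
    scores = radscore(model, table)
    return roc_auc(scores, np.asarray(labels).astype(bool), threshold=threshold)
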