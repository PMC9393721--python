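"""Radiomic signature construction.

A signature is a sparse linear model over z-normalized radiomic features:
``radscore = intercept + sum_f coef_f * z_f``. Training follows the order
z-normalize (training statistics only) -> SMOTE minority oversampling ->
mRMR filtering to the top 20 features -> L1-penalized logistic regression
with 10-fold cross-validated penalty choice (minimum mean held-out binomial
deviance). Every fitted quantity — normalization parameters, selected names,
coefficients, intercept, lambda — is estimated on training rows only, so the
model can be serialized and applied frozen to test or external cohorts.

mRMR uses the greedy mutual-information difference (MID) criterion: the
first feature maximizes MI with the label; each next feature maximizes
relevance minus mean redundancy with the already-selected set. MI is
computed after discretizing each feature into 3 states at mean +/- sd.
Ties are broken by column name.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "NormalizationParams",
    "SignatureModel",
    "zscore_fit",
    "zscore_apply",
    "smote",
    "mrmr_select",
    "lasso_cv_fit",
    "radscore",
    "build_signature",
]


@dataclass
class NormalizationParams:
    """Per-feature mean and sample (n-1) standard deviation of training rows."""

    mean: pd.Series
    sd: pd.Series
    zero_sd: list[str] = field(default_factory=list)


def zscore_fit(train: pd.DataFrame) -> NormalizationParams:
    if train.empty:
        raise ValueError("training table is empty")
    # stats on a fresh C-contiguous array: bit-reproducible regardless of
    # the frame's internal block layout
    values = np.ascontiguousarray(train.to_numpy(dtype=float))
    mean = pd.Series(values.mean(axis=0), index=train.columns)
    sd = pd.Series(values.std(axis=0, ddof=1), index=train.columns)
    zero = sd.index[(sd == 0) | sd.isna()].tolist()
    if zero:
        warnings.warn(f"{len(zero)} zero-variance feature(s) transformed to zeros", stacklevel=2)
    return NormalizationParams(mean, sd, zero)


def zscore_apply(params: NormalizationParams, table: pd.DataFrame) -> pd.DataFrame:
    missing = params.mean.index.difference(table.columns)
    if len(missing):
        raise KeyError(f"table missing feature column(s): {list(missing)[:5]}")
    t = table[params.mean.index]
    sd = params.sd.replace(0.0, np.nan)
    z = (t - params.mean) / sd
    z[params.zero_sd] = 0.0
    return z.fillna(0.0)


def smote(
    train: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic minority oversampling to exact class balance.

    Each synthetic row is a convex combination ``x + u * (nn - x)`` of a
    minority row and one of its k nearest minority neighbors (u ~ U[0, 1]).
    Originals are preserved; an already-balanced input is returned unchanged.
    """
    y = pd.Series(np.asarray(labels), index=train.index)
    counts = y.value_counts()
    if len(counts) != 2:
        raise ValueError(f"SMOTE needs exactly 2 classes, got {len(counts)}")
    minority, majority = counts.index[-1], counts.index[0]
    n_min, n_maj = counts[minority], counts[majority]
    if n_min == n_maj:
        return train.copy(), y.copy()
    if n_min < 2:
        raise ValueError("minority class has a single row; cannot interpolate")
    if k > n_min - 1:
        warnings.warn(f"k reduced from {k} to {n_min - 1} (minority size)", stacklevel=2)
        k = n_min - 1
    rng = np.random.default_rng(seed)
    x_min = train[y == minority].to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x_min)
    _, idx = nn.kneighbors(x_min)  # column 0 is the point itself
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    nb_choice = idx[base, rng.integers(1, k + 1, size=n_new)]
    u = rng.uniform(0.0, 1.0, size=n_new)[:, None]
    synthetic = x_min[base] + u * (x_min[nb_choice] - x_min[base])
    syn_index = [f"smote-{i}" for i in range(n_new)]
    out_x = pd.concat(
        [train, pd.DataFrame(synthetic, columns=train.columns, index=syn_index)]
    )
    out_y = pd.concat([y, pd.Series([minority] * n_new, index=syn_index)])
    return out_x, out_y


def _discretize_3state(x: np.ndarray) -> np.ndarray:
    m, s = x.mean(), x.std()
    return np.digitize(x, [m - s, m + s])


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI (nats) between two small discrete arrays via the joint histogram."""
    na, nb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb) / len(a)
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def mrmr_select(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    k: int = 20,
    criterion: str = "MID",
) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance feature filter.

    ``criterion``: "MID" (relevance minus mean redundancy, default), "MIQ"
    (relevance over mean redundancy), or "relevance" (top-k by label MI
    only). Returns exactly k names in selection order (all candidates, with
    a warning, when fewer than k exist).
    """
    if criterion not in ("MID", "MIQ", "relevance"):
        raise ValueError(f"unknown mRMR criterion {criterion!r}")
    y = pd.factorize(pd.Series(np.asarray(labels)))[0]
    if len(np.unique(y)) < 2:
        raise ValueError("mRMR needs at least 2 classes")
    cols = list(table.columns)
    if len(cols) < k:
        warnings.warn(f"only {len(cols)} candidates for k={k}; returning all", stacklevel=2)
        k = len(cols)
    disc = {c: _discretize_3state(table[c].to_numpy(dtype=float)) for c in cols}
    relevance = {c: _mutual_information(disc[c], y) for c in cols}

    def _argbest(scores: dict[str, float]) -> str:
        best = max(scores.values())
        return min(c for c, v in scores.items() if v == best)  # name tie-break

    if criterion == "relevance":
        return sorted(cols, key=lambda c: (-relevance[c], c))[:k]

    selected = [_argbest(relevance)]
    redundancy_sum = {c: 0.0 for c in cols}
    while len(selected) < k:
        last = selected[-1]
        candidates = [c for c in cols if c not in selected]
        for c in candidates:
            redundancy_sum[c] += _mutual_information(disc[c], disc[last])
        m = len(selected)
        if criterion == "MID":
            scores = {c: relevance[c] - redundancy_sum[c] / m for c in candidates}
        else:
            scores = {c: relevance[c] / (redundancy_sum[c] / m + 1e-12) for c in candidates}
        selected.append(_argbest(scores))
    return selected


@dataclass
class SignatureModel:
    """A frozen radscore definition.

    Applying the model means: z-normalize the raw features with the stored
    training statistics, then ``intercept + coefficients . z``.
    """

    normalization: NormalizationParams
    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    lambda_: float
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("one coefficient per selected feature required")

    def to_json(self, path: str | Path) -> None:
        d = {
            "normalization": {
                "mean": self.normalization.mean.to_dict(),
                "sd": self.normalization.sd.to_dict(),
                "zero_sd": self.normalization.zero_sd,
            },
            "feature_names": self.feature_names,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "lambda": self.lambda_,
            "seed": self.seed,
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        d = json.loads(Path(path).read_text())
        norm = NormalizationParams(
            pd.Series(d["normalization"]["mean"]),
            pd.Series(d["normalization"]["sd"]),
            d["normalization"]["zero_sd"],
        )
        return cls(
            norm,
            d["feature_names"],
            np.asarray(d["coefficients"], dtype=float),
            d["intercept"],
            d["lambda"],
            d["seed"],
            d.get("meta", {}),
        )


def lasso_cv_fit(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 30,
    lambda_min_ratio: float = 1e-3,
    lambdas: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float, dict]:
    """L1 logistic regression with CV over a descending lambda grid.

    The grid spans [lambda_max * lambda_min_ratio, lambda_max] (log-spaced)
    unless ``lambdas`` is given explicitly. Returns
    ``(coefs, intercept, lambda, info)`` for the lambda minimizing mean
    held-out binomial deviance. Coefficients are on the scale of the
    (already normalized) inputs.
    """
    x = table.to_numpy(dtype=float)
    y = np.asarray(pd.factorize(pd.Series(np.asarray(labels)), sort=True)[0])
    n = len(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    if counts.min() < folds:
        raise ValueError(f"need >= {folds} rows per class for {folds}-fold CV")
    if lambdas is None:
        p_bar = y.mean()
        lam_max = np.abs(x.T @ (y - p_bar)).max() / n
        lam_max = max(lam_max, 1e-6)
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)
    else:
        lambdas = np.asarray(lambdas, dtype=float)
    n_lambdas = len(lambdas)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))
    deviance = np.zeros(n_lambdas)
    for tr, te in splits:
        for i, lam in enumerate(lambdas):
            clf = _l1_logistic(lam, len(tr))
            clf.fit(x[tr], y[tr])
            prob = np.clip(clf.predict_proba(x[te])[:, 1], 1e-12, 1 - 1e-12)
            deviance[i] += -2.0 * np.mean(y[te] * np.log(prob) + (1 - y[te]) * np.log(1 - prob))
    deviance /= folds
    best = int(np.argmin(deviance))
    lam = float(lambdas[best])
    clf = _l1_logistic(lam, n)
    clf.fit(x, y)
    coefs = clf.coef_.ravel()
    if not np.any(coefs):
        warnings.warn("LASSO selected no features; intercept-only model", stacklevel=2)
    info = {"lambdas": lambdas.tolist(), "cv_deviance": deviance.tolist()}
    return coefs, float(clf.intercept_[0]), lam, info


def _l1_logistic(lam: float, n: int) -> LogisticRegression:
    # liblinear with a large intercept_scaling leaves the intercept
    # effectively unpenalized while being far faster than saga on the
    # small panels seen here
    return LogisticRegression(
        l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear",
        intercept_scaling=100.0, max_iter=5000, tol=1e-6,
        random_state=0,  # liblinear shuffles internally; pin for determinism
    )


def radscore(model: SignatureModel, table: pd.DataFrame) -> pd.Series:
    """Per-subject signature score; raises naming any missing column."""
    missing = [c for c in model.feature_names if c not in table.columns]
    if missing:
        raise KeyError(f"table missing feature column(s): {missing}")
    z = zscore_apply(model.normalization, table)
    score = model.intercept + z[model.feature_names].to_numpy() @ model.coefficients
    return pd.Series(score, index=table.index, name="radscore")


def build_signature(
    train: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    mrmr_k: int = 20,
    folds: int = 10,
    seed: int = 0,
    smote_k: int = 5,
    mrmr_criterion: str = "MID",
) -> SignatureModel:
    """Full training pipeline on training rows only.

    normalize -> SMOTE -> mRMR(top mrmr_k) -> LASSO(10-fold CV); features
    with zero LASSO coefficient are dropped from the stored model.
    """
    y = pd.Series(np.asarray(labels), index=train.index)
    norm = zscore_fit(train)
    z = zscore_apply(norm, train)
    z_bal, y_bal = smote(z, y, k=smote_k, seed=seed)
    selected = mrmr_select(z_bal, y_bal, k=mrmr_k, criterion=mrmr_criterion)
    coefs, intercept, lam, info = lasso_cv_fit(z_bal[selected], y_bal, folds=folds, seed=seed)
    nonzero = np.flatnonzero(coefs)
    names = [selected[i] for i in nonzero]
    return SignatureModel(
        normalization=norm,
        feature_names=names,
        coefficients=coefs[nonzero],
        intercept=intercept,
        lambda_=lam,
        seed=seed,
        meta={"mrmr_selected": selected, "cv": info},
    )
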