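"""Splits, ROC/AUC, DeLong, Wilcoxon, Spearman, experiment assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hipporad import (
    SplitScheme,
    apply_frozen_model,
    delong_test,
    roc_auc,
    run_experiment,
    spearman,
    split_cohort,
    wilcoxon_ranksum,
)
from hipporad.evaluation import auc_mann_whitney

import oracles


class TestSplitCohort:
    def _labels(self, n_pos=84, n_neg=44):
        return pd.Series([True] * n_pos + [False] * n_neg,
                         index=[f"s{i}" for i in range(n_pos + n_neg)])

    def test_study_sized_split_counts(self):
        y = self._labels()
        train, test = split_cohort(y, SplitScheme(seed=1), 0)
        yt = y.loc[train]
        assert yt.sum() == 59 and (~yt).sum() == 31  # round(0.7*84), round(0.7*44)
        assert len(test) == 128 - 90

    def test_partition_property(self):
        y = self._labels(20, 10)
        train, test = split_cohort(y, SplitScheme(seed=2), 3)
        assert set(train) | set(test) == set(y.index)
        assert not set(train) & set(test)

    def test_reproducible_per_repetition(self):
        y = self._labels(20, 10)
        s = SplitScheme(seed=5)
        assert split_cohort(y, s, 1) == split_cohort(y, s, 1)
        assert split_cohort(y, s, 1) != split_cohort(y, s, 2)

    def test_tiny_class_rejected(self):
        y = pd.Series([True, False, False])
        with pytest.raises(ValueError, match="fewer than 2"):
            split_cohort(y, SplitScheme(), 0)


class TestROCAUC:
    def test_perfect_separation(self):
        r = roc_auc(np.r_[np.ones(5) + 1, np.zeros(5)], np.r_[np.ones(5), np.zeros(5)])
        assert r.auc == 1.0
        assert r.accuracy == 1.0

    def test_pure_ties_give_half(self):
        r = roc_auc(np.full(20, 3.3), np.r_[np.ones(10), np.zeros(10)])
        assert r.auc == 0.5

    def test_auc_equals_pairwise_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 40))
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            assert auc_mann_whitney(scores, labels) == pytest.approx(
                oracles.pairwise_auc(scores, labels), rel=1e-12
            )

    def test_ci_contains_auc_and_bounded(self, rng):
        scores = rng.normal(size=60) + np.r_[np.ones(30), np.zeros(30)]
        r = roc_auc(scores, np.r_[np.ones(30), np.zeros(30)])
        assert 0.0 <= r.ci[0] <= r.auc <= r.ci[1] <= 1.0

    def test_complementation(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50).astype(bool)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        a1 = roc_auc(scores, labels).auc
        a2 = roc_auc(-scores, labels).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.arange(5.0), np.ones(5))


class TestDeLong:
    def test_identical_scores(self, rng):
        s = rng.normal(size=40)
        y = np.r_[np.ones(20), np.zeros(20)].astype(bool)
        res = delong_test(s, s, y)
        assert res.z == 0.0 and res.p == 1.0 and res.auc_diff == 0.0

    def test_antisymmetry(self, rng):
        y = np.r_[np.ones(25), np.zeros(25)].astype(bool)
        a = rng.normal(size=50) + y
        b = rng.normal(size=50) + 0.5 * y
        r1 = delong_test(a, b, y)
        r2 = delong_test(b, a, y)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p == pytest.approx(r2.p)
        assert np.sign(r1.z) == np.sign(r1.auc_diff)

    def test_variance_agrees_with_paired_bootstrap(self):
        """DeLong variance of the AUC difference vs 2000-resample paired
        bootstrap, within 15% relative, averaged over instances."""
        rng = np.random.default_rng(11)
        rel_errs = []
        for _ in range(20):
            n1, n0 = 30, 30
            y = np.r_[np.ones(n1), np.zeros(n0)].astype(bool)
            base = rng.normal(size=n1 + n0)
            a = base + 0.8 * y + 0.3 * rng.normal(size=n1 + n0)
            b = base + 0.4 * y + 0.3 * rng.normal(size=n1 + n0)
            from hipporad.evaluation import _delong_placements, _delong_variance

            p10a, p01a = _delong_placements(a, y)
            p10b, p01b = _delong_placements(b, y)
            var_delong = _delong_variance(p10a, p01a, p10b, p01b)
            diffs = []
            for _ in range(2000):
                ip = rng.integers(0, n1, n1)
                ineg = n1 + rng.integers(0, n0, n0)
                idx = np.r_[ip, ineg]
                yy = y[idx]
                diffs.append(
                    auc_mann_whitney(a[idx], yy) - auc_mann_whitney(b[idx], yy)
                )
            rel_errs.append(abs(var_delong - np.var(diffs)) / np.var(diffs))
        assert np.mean(rel_errs) < 0.15

    def test_null_type_one_error_calibrated(self):
        """Independent-noise scores, n = 60/40: rejection rate at alpha=.05
        stays in [0.04, 0.06] over 5000 replicates."""
        rng = np.random.default_rng(0)
        y = np.r_[np.ones(60), np.zeros(40)].astype(bool)
        rejections = 0
        n_reps = 5000
        for _ in range(n_reps):
            a = rng.normal(size=100)
            b = rng.normal(size=100)
            if delong_test(a, b, y).p < 0.05:
                rejections += 1
        assert 0.04 <= rejections / n_reps <= 0.06


class TestWilcoxon:
    def test_identical_multisets_exact_p_one(self):
        a = np.array([1.5, 2.5, 3.5])
        _, p = wilcoxon_ranksum(a, a.copy())
        assert p == 1.0

    def test_complete_separation_exact_p(self):
        a = np.arange(10.0) + 100
        b = np.arange(10.0)
        _, p = wilcoxon_ranksum(a, b)
        from math import comb

        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_symmetry_in_groups(self, rng):
        a, b = rng.normal(size=15), rng.normal(size=20)
        _, p1 = wilcoxon_ranksum(a, b)
        _, p2 = wilcoxon_ranksum(b, a)
        assert p1 == pytest.approx(p2)

    def test_all_identical_values(self):
        _, p = wilcoxon_ranksum(np.full(5, 2.0), np.full(7, 2.0))
        assert p == 1.0

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(1)
        rejections = 0
        n_reps = 5000
        for _ in range(n_reps):
            a = rng.normal(size=30)
            b = rng.normal(size=30)
            if wilcoxon_ranksum(a, b)[1] < 0.05:
                rejections += 1
        assert 0.04 <= rejections / n_reps <= 0.06


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman(x, np.exp(x)).rho == 1.0
        assert spearman(x, -np.exp(x)).rho == -1.0

    def test_printed_formula_example(self):
        res = spearman(np.array([1.0, 2.0, 3.0]), np.array([3.0, 1.0, 2.0]))
        assert res.rho == pytest.approx(-0.5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_invariant_under_monotone_transforms(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=12)
        y = r.normal(size=12)
        rho1 = spearman(x, y).rho
        rho2 = spearman(np.exp(x), y**3 + 5 * y).rho
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError, match="rank variance"):
            spearman(np.ones(5), np.arange(5.0))


def _feature_tables(rng, n_per_group=14, effect=1.0):
    """Small synthetic feature tables for the experiment driver: one ROI
    pair, two modalities, planted separation in a few columns."""
    ids = [f"s{i}" for i in range(3 * n_per_group)]
    groups = pd.Series(
        ["AD"] * n_per_group + ["aMCI"] * n_per_group + ["NC"] * n_per_group,
        index=ids,
    )
    is_pat = (groups != "NC").to_numpy().astype(float)
    tables = {}
    for roi in ("left", "right"):
        for modality in ("T1-w", "ALFF"):
            x = pd.DataFrame(
                rng.normal(size=(len(ids), 25)),
                index=ids,
                columns=[f"{modality}_{roi}_f{i:02d}" for i in range(25)],
            )
            x.iloc[:, 0] += effect * is_pat
            x.iloc[:, 1] -= 0.5 * effect * is_pat
            tables[(roi, modality)] = x
    clinical = pd.Series(rng.normal(25, 3, len(ids)) - 5 * is_pat, index=ids)
    return tables, groups, clinical


class TestRunExperiment:
    @pytest.fixture(scope="class")
    def report(self, rng):
        tables, groups, clinical = _feature_tables(rng)
        return run_experiment(
            tables, groups, clinical,
            contrasts=[("AD", "NC"), ("aMCI", "NC")],
            rois=["left", "right"],
            scheme=SplitScheme(n_repetitions=3, seed=4),
            mrmr_k=10, folds=5,
        )

    def test_twelve_signatures(self, report):
        assert report.n_signatures == 12
        assert len(report.cells) == 12
        assert not any(c["failed"] for c in report.cells)

    def test_mean_auc_is_arithmetic_mean_of_repetitions(self, report):
        for c in report.cells:
            reps = [r["test_auc"] for r in c["repetitions"]]
            assert c["mean_test_auc"] == np.mean(reps)

    def test_delong_rows_paired_within_cells(self, report):
        assert report.delong  # comparisons present
        for row in report.delong:
            assert row["model_a"] in ("combined", "T1-w")
            assert 0 < row["p"] <= 1

    def test_correlations_reference_existing_features(self, report):
        for row in report.correlations:
            assert -1 <= row["rho"] <= 1

    def test_failed_cell_isolated(self, rng):
        tables, groups, clinical = _feature_tables(rng, n_per_group=14)
        # sabotage one ROI/modality table: constant features break nothing,
        # but dropping rows breaks alignment for that cell only
        tables[("right", "ALFF")] = tables[("right", "ALFF")].iloc[:5]
        rep = run_experiment(
            tables, groups, clinical,
            contrasts=[("AD", "NC")], rois=["left", "right"],
            scheme=SplitScheme(n_repetitions=2, seed=1), mrmr_k=5, folds=5,
        )
        failed = {(c["roi"], c["modality"]) for c in rep.cells if c["failed"]}
        assert ("right", "ALFF") in failed
        assert ("left", "T1-w") not in failed


class TestApplyFrozenModel:
    def test_training_table_reproduces_training_auc(self, rng):
        from hipporad import build_signature, radscore

        x = pd.DataFrame(rng.normal(size=(60, 15)),
                         columns=[f"f{i:02d}" for i in range(15)])
        y = pd.Series(np.r_[np.ones(30), np.zeros(30)].astype(bool), index=x.index)
        x.loc[y, "f00"] += 1.5
        model = build_signature(x, y, mrmr_k=8, folds=5, seed=0)
        direct = roc_auc(radscore(model, x), y)
        applied = apply_frozen_model(model, x, y)
        assert applied.auc == direct.auc

    def test_weaker_external_effect_lowers_auc(self, rng):
        from hipporad import build_signature

        def make(effect, seed):
            r = np.random.default_rng(seed)
            x = pd.DataFrame(r.normal(size=(80, 10)),
                             columns=[f"f{i:02d}" for i in range(10)])
            y = pd.Series(np.r_[np.ones(40), np.zeros(40)].astype(bool), index=x.index)
            x.loc[y, "f00"] += effect
            return x, y

        internal_auc, external_auc = [], []
        for seed in range(8):
            xt, yt = make(2.0, seed)
            model = build_signature(xt, yt, mrmr_k=5, folds=5, seed=seed)
            xi, yi = make(2.0, 100 + seed)
            xe, ye = make(0.5, 200 + seed)
            internal_auc.append(apply_frozen_model(model, xi, yi).auc)
            external_auc.append(apply_frozen_model(model, xe, ye).auc)
        assert np.mean(external_auc) < np.mean(internal_auc)
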