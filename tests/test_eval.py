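"""Tests for MCC, threshold optimisation, AUC, CV and the KS profile."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef

from ramfeat import (
    PredictionScores,
    assemble,
    crossval_10fold,
    evaluate_scores,
    feature_label_correlation_profile,
    mcc,
    optimal_mcc_threshold,
    roc_auc,
    sweep_n,
    train_test,
)
from ramfeat.evaluate import _confusion
from ramfeat.features import table_from_dataframe
from ramfeat.synthetic import SyntheticSpec, generate_sequences


class TestMcc:
    def test_perfect_prediction(self):
        assert mcc(5, 0, 5, 0) == 1.0

    def test_anti_perfect_prediction(self):
        assert mcc(0, 5, 0, 5) == -1.0

    def test_hand_computed_value(self):
        # (3*4 - 1*2) / sqrt(4*5*5*6) = 10 / sqrt(600)
        assert mcc(3, 1, 4, 2) == pytest.approx(10 / math.sqrt(600))

    def test_zero_denominator_convention(self):
        assert mcc(0, 0, 3, 2) == 0.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        tn=st.integers(0, 50), fn=st.integers(0, 50),
    )
    def test_class_swap_symmetry(self, tp, fp, tn, fn):
        assert mcc(tp, fp, tn, fn) == pytest.approx(mcc(tn, fn, tp, fp))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        tp=st.integers(1, 30), fp=st.integers(0, 30),
        tn=st.integers(1, 30), fn=st.integers(0, 30),
    )
    def test_matches_sklearn(self, tp, fp, tn, fn):
        y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
        y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
        assert mcc(tp, fp, tn, fn) == pytest.approx(
            matthews_corrcoef(y_true, y_pred), abs=1e-12
        )


class TestOptimalThreshold:
    def test_perfect_separation(self):
        s = PredictionScores(
            scores=np.array([0.1, 0.2, 0.8, 0.9]), labels=np.array([0, 0, 1, 1])
        )
        t, m = optimal_mcc_threshold(s)
        assert m == 1.0
        assert 0.2 < t < 0.8

    def test_all_scores_equal(self):
        s = PredictionScores(
            scores=np.full(6, 0.5), labels=np.array([0, 1, 0, 1, 0, 1])
        )
        _, m = optimal_mcc_threshold(s)
        assert m == 0.0

    def test_single_class_rejected(self):
        s = PredictionScores(scores=np.array([0.1, 0.9]), labels=np.array([1, 1]))
        with pytest.raises(ValueError):
            optimal_mcc_threshold(s)

    def test_matches_dense_grid_oracle(self, rng):
        scores = rng.uniform(size=20)
        labels = rng.integers(0, 2, size=20)
        labels[0], labels[1] = 0, 1  # both classes present
        s = PredictionScores(scores=scores, labels=labels)
        _, best = optimal_mcc_threshold(s)
        grid = np.linspace(-0.01, 1.01, 10_000)
        oracle = max(mcc(*_confusion(scores, labels, t)) for t in grid)
        assert best == pytest.approx(oracle, abs=1e-12)

    def test_never_worse_than_default_half(self, rng):
        for _ in range(20):
            scores = rng.uniform(size=30)
            labels = rng.integers(0, 2, size=30)
            if len(np.unique(labels)) < 2:
                continue
            s = PredictionScores(scores=scores, labels=labels)
            _, best = optimal_mcc_threshold(s)
            assert best >= mcc(*_confusion(scores, labels, 0.5)) - 1e-12


class TestRocAuc:
    def test_perfect_ranking(self):
        s = PredictionScores(
            scores=np.array([0.1, 0.2, 0.8, 0.9]), labels=np.array([0, 0, 1, 1])
        )
        assert roc_auc(s) == 1.0

    def test_all_tied_scores(self):
        s = PredictionScores(scores=np.full(10, 0.3), labels=np.array([0, 1] * 5))
        assert roc_auc(s) == 0.5

    def test_random_scores_near_half(self, rng):
        n = 10_000
        s = PredictionScores(
            scores=rng.uniform(size=n), labels=rng.integers(0, 2, size=n)
        )
        assert roc_auc(s) == pytest.approx(0.5, abs=0.02)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        a = roc_auc(PredictionScores(scores=scores, labels=labels))
        b = roc_auc(PredictionScores(scores=np.exp(3 * scores), labels=labels))
        assert a == pytest.approx(b, abs=1e-12)


class TestCrossval:
    def test_planted_signal_recovery(self, planted_cv):
        _, report = planted_cv
        assert report.auc >= 0.9

    def test_no_signal_near_chance(self, nosignal_cv):
        _, report = nosignal_cv
        assert 0.4 <= report.auc <= 0.6

    def test_fixed_seed_reproducible(self, planted_table):
        _, r1 = crossval_10fold(planted_table, seed=3, n_folds=5)
        _, r2 = crossval_10fold(planted_table, seed=3, n_folds=5)
        assert r1 == r2

    def test_report_fields_consistent(self, planted_cv):
        scores, report = planted_cv
        tp, fp, tn, fn = report.confusion
        assert tp + fp + tn + fn == len(scores.labels)
        assert report.sn == pytest.approx(tp / (tp + fn))
        assert report.sp == pytest.approx(tn / (tn + fp))
        assert -1 <= report.mcc <= 1
        assert 0 <= report.auc <= 1

    def test_too_few_sites_per_class_rejected(self, planted_table):
        import dataclasses

        tiny = dataclasses.replace(
            planted_table,
            sites=planted_table.sites[:12],
            matrix=planted_table.matrix[:12],
        )
        with pytest.raises(ValueError, match="sites per class"):
            crossval_10fold(tiny, n_folds=10)

    def test_linear_classifier_invariant_to_duplicated_noise(self, planted_table):
        """OLS confidence depends on the column span, and the evaluation
        path is deterministic, so re-running gives identical reports."""
        _, r1 = crossval_10fold(planted_table, classifier="ols", seed=1, n_folds=5)
        _, r2 = crossval_10fold(planted_table, classifier="ols", seed=1, n_folds=5)
        assert r1 == r2


class TestTrainTest:
    def test_train_equals_test_separable(self, planted_table):
        _, report = train_test(planted_table, planted_table, seed=0)
        assert report.auc >= 0.99

    def test_disjoint_draws_match_cv_estimate(self, planted_cv):
        spec_b = SyntheticSpec(n_proteins=100, cys_range=(2, 2), seed=99)
        _, sites_b = generate_sequences(spec_b)
        spec_a = SyntheticSpec(n_proteins=100, cys_range=(2, 2), seed=98)
        _, sites_a = generate_sequences(spec_a)
        table_a = assemble(sites_a, n_seq=6)
        table_b = assemble(sites_b, n_seq=6)
        _, report = train_test(table_a, table_b, seed=0)
        _, cv_report = planted_cv
        assert abs(report.auc - cv_report.auc) < 0.1

    def test_single_feature_threshold_rule(self):
        """With one perfectly separating feature, prediction reduces to
        a threshold rule and test AUC is exactly 1."""
        from ramfeat import FeatureTable, TargetSite

        rngl = np.random.default_rng(0)
        x = np.concatenate([rngl.uniform(0, 1, 30), rngl.uniform(2, 3, 30)])
        labels = np.array([0] * 30 + [1] * 30)
        sites = tuple(
            TargetSite(f"p{i}", "C", 1, int(lab)) for i, lab in enumerate(labels)
        )
        table = FeatureTable(
            sites=sites,
            matrix=x.reshape(-1, 1),
            column_names=("SASA",),
            blocks={"SASA": slice(0, 1)},
        )
        _, report = train_test(table, table, classifier="ols", seed=0)
        assert report.auc == 1.0


class TestSweepN:
    def test_single_point_grid_equals_crossval(self, planted_sites, planted_table):
        result = sweep_n(planted_sites, [6], [6], seed=11, n_folds=10)
        _, report = crossval_10fold(planted_table, seed=11, n_folds=10)
        assert result.auc_grid[0, 0] == pytest.approx(report.auc)
        assert result.best == (6, 6)

    def test_grid_reproducible_and_plateaus(self, planted_sites):
        subset = planted_sites[:100]
        r1 = sweep_n(subset, [1, 3], [6], seed=2, n_folds=5)
        r2 = sweep_n(subset, [1, 3], [6], seed=2, n_folds=5)
        np.testing.assert_array_equal(r1.auc_grid, r2.auc_grid)
        # signal lives at rank 1 of the W row, so even n=1 recovers it
        assert r1.auc_grid.min() >= 0.8

    def test_empty_range_rejected(self, planted_sites):
        with pytest.raises(ValueError):
            sweep_n(planted_sites, [], [6])


class TestCorrelationProfile:
    def test_label_copied_feature_has_correlation_one(self, planted_table):
        import dataclasses

        m = planted_table.matrix.copy()
        m[:, 0] = planted_table.labels()
        t = dataclasses.replace(planted_table, matrix=m)
        profile = feature_label_correlation_profile(t, seed=0)
        assert profile.correlations[0] == pytest.approx(1.0)

    def test_planted_signal_strongest_in_tryptophan_block(self, planted_table):
        """The planted signal shows up exactly where it should: the
        largest-magnitude label correlations are the tryptophan-row
        distance columns, and they are negative (nearer tryptophan ->
        positive label)."""
        from ramfeat import PROTEIN_ALPHABET

        profile = feature_label_correlation_profile(planted_table, seed=0)
        w = PROTEIN_ALPHABET.index("W")
        w_cols = set(range(w * 6, (w + 1) * 6))
        order = np.argsort(-np.abs(profile.correlations))
        assert set(order[:3]) <= w_cols
        assert profile.correlations[order[0]] < -0.5
        null_sd = np.std(profile.random_correlations)
        assert np.abs(profile.correlations).max() > 10 * null_sd

    def test_dense_signal_gives_significant_ks(self, planted_table):
        """When many columns carry label signal, the correlation
        distribution separates decisively from the random baseline."""
        import dataclasses

        rngl = np.random.default_rng(3)
        y = planted_table.labels().astype(float)
        m = rngl.standard_normal(planted_table.matrix.shape)
        m[:, ::2] += y[:, None]  # half the columns carry the label
        t = dataclasses.replace(planted_table, matrix=m)
        profile = feature_label_correlation_profile(t, seed=0)
        assert profile.ks_pvalue < 1e-3

    def test_random_features_match_random_baseline(self, nosignal_table):
        import dataclasses

        rngl = np.random.default_rng(7)
        t = dataclasses.replace(
            nosignal_table, matrix=rngl.standard_normal(nosignal_table.matrix.shape)
        )
        profile = feature_label_correlation_profile(t, seed=5)
        assert profile.ks_pvalue > 0.01

    def test_density_summary_integrates_to_one(self, planted_table):
        profile = feature_label_correlation_profile(planted_table, seed=0)
        grid = profile.density["grid"]
        area = np.trapezoid(profile.density["features"], grid)
        assert area == pytest.approx(1.0, abs=0.05)
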