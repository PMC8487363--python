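"""Trajectory classification, metrics, and the nested cross-validation loop."""

import numpy as np
import pandas as pd
import pytest

from gradoffset import (
    EvaluationReport,
    RunConfig,
    build_trajectory_features,
    classify_trajectories,
    evaluate_metrics,
    fit_weights_loo,
    forecast_dataset,
    generate_cohort,
    run_nested_cv,
    select_best_model,
)

from conftest import make_spec


class TestTrajectoryFeatures:
    def test_dimension_and_content(self, tiny_dataset):
        ds = tiny_dataset([[[1, 2, 3], [4, 5, 6]]], labels=[1])
        X, y = build_trajectory_features(ds)
        assert X.shape == (1, 6)
        np.testing.assert_array_equal(X[0], [1, 2, 3, 4, 5, 6])
        np.testing.assert_array_equal(y, [1])

    def test_forecast_mode_replaces_third_visit(self, coupled_noiseless):
        ds, spec = coupled_noiseless
        model = fit_weights_loo(ds)
        fc = forecast_dataset(ds, model, base_classes=ds.labels)
        X_fc, _ = build_trajectory_features(ds, fc)
        np.testing.assert_array_equal(X_fc[:, 2::3], fc.predicted)
        X_gt, _ = build_trajectory_features(ds)
        np.testing.assert_array_equal(X_gt[:, 2::3], ds.values[:, :, 2])

    def test_incomplete_trajectory_rejected(self, tiny_dataset):
        ds = tiny_dataset(np.ones((2, 1, 2)), labels=[1, 0])
        with pytest.raises(ValueError, match="three-visit"):
            build_trajectory_features(ds)


class TestClassifyTrajectories:
    def test_separable_sides(self):
        X_train = np.array([[0.0], [0.1], [1.0], [1.1]])
        y_train = np.array([0, 0, 1, 1])
        labels, scores = classify_trajectories(X_train, y_train, np.array([[-0.5], [1.6]]))
        np.testing.assert_array_equal(labels, [0, 1])
        assert scores[1] > scores[0]

    def test_scores_monotone_toward_progressor_halfspace(self):
        X_train = np.array([[0.0], [0.2], [0.8], [1.0]])
        y_train = np.array([0, 0, 1, 1])
        depths = np.linspace(-1, 2, 7)[:, None]
        _, scores = classify_trajectories(X_train, y_train, depths)
        assert (np.diff(scores) > 0).all()

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            classify_trajectories(np.zeros((3, 2)), np.ones(3), np.zeros((1, 2)))


class TestEvaluateMetrics:
    def test_perfect_forecast_zero_mae(self):
        obs = np.random.default_rng(0).uniform(size=(4, 3))
        row = evaluate_metrics([1, 0, 1, 0], [1, 0, 1, 0], [1.0, 0.0, 1.0, 0.0], obs, obs)
        assert row["mae_percent"] == 0.0

    def test_perfectly_separated_scores(self):
        row = evaluate_metrics([1, 1, 0, 0], [1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert row["auc"] == 1.0
        assert row["accuracy"] == row["sensitivity"] == row["specificity"] == 1.0

    def test_confusion_matrix_counts(self):
        row = evaluate_metrics([1, 1, 0, 0], [1, 0, 0, 0], [0.9, 0.4, 0.5, 0.1])
        assert row["accuracy"] == pytest.approx(0.75)
        assert row["sensitivity"] == pytest.approx(0.5)
        assert row["specificity"] == pytest.approx(1.0)

    def test_one_class_truth_flags_auc(self, caplog):
        with caplog.at_level("WARNING", logger="gradoffset"):
            row = evaluate_metrics([1, 1], [1, 0], [0.6, 0.4])
        assert np.isnan(row["auc"])
        assert "undefined" in caplog.text

    def test_auc_equals_bruteforce_pair_count(self):
        """Rank-statistic AUC agrees with explicit counting over all
        progressor x stable score pairs (ties worth 1/2) on small instances."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(6, 20))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            row = evaluate_metrics(y, y, scores)
            pos, neg = scores[y == 1], scores[y == 0]
            wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
            assert row["auc"] == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


@pytest.fixture(scope="module")
def moderate_cohort_report():
    spec = make_spec(
        n_progressor=30, n_stable=40, n_markers=4,
        slope_progressor=-0.08, slope_stable=-0.02,
        coupling=0.2 * np.eye(4), subject_slope_sd=0.02, noise_sd=0.02, seed=31,
    )
    ds = generate_cohort(spec)
    return run_nested_cv(ds, RunConfig(max_subset=4, seed=7))


class TestRunNestedCV:
    def test_stratification_contract(self):
        """49 + 70 subjects split 5-fold: both classes everywhere, per-class
        fold sizes differing by at most one."""
        from sklearn.model_selection import StratifiedKFold

        labels = np.r_[np.ones(49, int), np.zeros(70, int)]
        folds = list(StratifiedKFold(5, shuffle=True, random_state=0).split(labels, labels))
        pos_counts = [labels[te].sum() for _, te in folds]
        neg_counts = [(1 - labels[te]).sum() for _, te in folds]
        assert min(pos_counts) >= 1 and min(neg_counts) >= 1
        assert max(pos_counts) - min(pos_counts) <= 1
        assert max(neg_counts) - min(neg_counts) <= 1

    def test_gt_mode_mae_identically_zero(self, moderate_cohort_report):
        gt = moderate_cohort_report.per_fold.query("mode == 'gt'")
        assert (gt["mae_percent"] == 0.0).all()

    def test_report_shape_and_ranges(self, moderate_cohort_report):
        per_fold = moderate_cohort_report.per_fold
        assert len(per_fold) == 2 * 4 * 5  # modes x subsets x folds
        for col in ("auc", "accuracy", "sensitivity", "specificity"):
            assert per_fold[col].between(0, 1).all()
        assert (per_fold["mae_percent"] >= 0).all()

    def test_accuracy_decomposes_into_class_recalls(self, moderate_cohort_report):
        """accuracy = (sens * n_pos + spec * n_neg) / n holds exactly per row."""
        spec31 = make_spec(
            n_progressor=30, n_stable=40, n_markers=4,
            slope_progressor=-0.08, slope_stable=-0.02,
            coupling=0.2 * np.eye(4), subject_slope_sd=0.02, noise_sd=0.02, seed=31,
        )
        labels = generate_cohort(spec31).labels
        from sklearn.model_selection import StratifiedKFold

        fold_counts = {}
        for f, (_, te) in enumerate(
            StratifiedKFold(5, shuffle=True, random_state=7).split(labels, labels)
        ):
            fold_counts[f] = (labels[te].sum(), (1 - labels[te]).sum())
        for _, row in moderate_cohort_report.per_fold.iterrows():
            n_pos, n_neg = fold_counts[row["fold"]]
            expected = (row["sensitivity"] * n_pos + row["specificity"] * n_neg) / (n_pos + n_neg)
            assert row["accuracy"] == pytest.approx(expected, abs=1e-12)

    def test_noiseless_linear_cohort_forecast_equals_gt(self):
        """With zero noise and zero subject variance plus oracle base classes,
        forecasts equal observations, so both modes report identical metrics."""
        spec = make_spec(
            n_progressor=12, n_stable=12, n_markers=3,
            subject_slope_sd=0.0, noise_sd=0.0, seed=19,
        )
        report = run_nested_cv(
            generate_cohort(spec),
            RunConfig(max_subset=3, seed=2, base_classifier="oracle"),
        )
        fc = report.per_fold.query("mode == 'forecast'").drop(columns="mode").reset_index(drop=True)
        gt = report.per_fold.query("mode == 'gt'").drop(columns="mode").reset_index(drop=True)
        assert (fc["mae_percent"] <= 1e-12).all()  # zero up to float rounding
        pd.testing.assert_frame_equal(fc.drop(columns="mae_percent"),
                                      gt.drop(columns="mae_percent"))

    def test_too_few_subjects_rejected(self, tiny_dataset):
        ds = tiny_dataset(np.random.default_rng(0).uniform(0.5, 1, (8, 2, 3)),
                          labels=[1, 1, 1, 1, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="10 subjects"):
            run_nested_cv(ds, RunConfig(max_subset=2))

    def test_within_train_normalization_runs(self):
        spec = make_spec(n_progressor=15, n_stable=15, n_markers=3,
                         noise_sd=0.02, baseline=(5.0, 10.0), seed=5)
        report = run_nested_cv(
            generate_cohort(spec),
            RunConfig(max_subset=2, seed=1, normalization="within_train", mode="forecast"),
        )
        assert (report.per_fold["mae_percent"] >= 0).all()


class TestSelectBestModel:
    @staticmethod
    def _report(aucs):
        agg = pd.DataFrame({
            "mode": "forecast",
            "subset_size": np.arange(1, len(aucs) + 1),
            "mae_percent": 1.0,
            "auc": aucs,
            "accuracy": 0.8,
            "sensitivity": 0.8,
            "specificity": 0.8,
            "auc_pooled": aucs,
        })
        return EvaluationReport(per_fold=agg.assign(fold=0), aggregate=agg,
                                ranked_marker_ids=("a", "b", "c")[: len(aucs)])

    def test_tie_prefers_smaller_subset(self):
        size, row = select_best_model(self._report([0.7, 0.9, 0.9]))
        assert size == 2
        assert row["auc"] == 0.9

    def test_single_subset(self):
        assert select_best_model(self._report([0.6]))[0] == 1

    def test_monotone_increasing_picks_largest(self):
        assert select_best_model(self._report([0.6, 0.7, 0.8]))[0] == 3
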