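"""Trajectory classification, nested cross-validation, and performance metrics.

The outer loop is a stratified 5-fold split: within each training fold the
weight matrix is fitted (with its inner leave-one-out average) and the
base-group SVM trained; test-fold subjects get forecast third visits, and a
linear SVM trained on the training fold's fully observed trajectories
classifies the completed test trajectories as progressor vs. stable. The
whole procedure repeats for every nested marker subset. A ground-truth (GT)
mode classifies observed third visits instead of forecasts — the benchmark
ceiling the forecasting pipeline is measured against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .cohort import LongitudinalDataset
from .dataio import RunConfig
from .forecast import ForecastSet, forecast_dataset, train_base_group_svm
from .gradients import fit_weights_loo
from .preprocessing import marker_scales, normalize_dataset, rank_markers

__all__ = [
    "EvaluationReport",
    "build_trajectory_features",
    "classify_trajectories",
    "evaluate_metrics",
    "run_nested_cv",
    "select_best_model",
    "plot_report",
]

logger = logging.getLogger("gradoffset")

_METRIC_COLUMNS = ["mae_percent", "auc", "accuracy", "sensitivity", "specificity"]


@dataclass(frozen=True)
class EvaluationReport:
    """Per-fold and fold-averaged classification/forecasting metrics.

    ``per_fold`` has one row per (mode, subset_size, fold); ``aggregate``
    averages the metrics over folds and adds ``auc_pooled``, the AUC of all
    folds' scores pooled into a single ranking.
    """

    per_fold: pd.DataFrame
    aggregate: pd.DataFrame
    ranked_marker_ids: tuple

    def to_csv(self, path) -> None:
        per_fold = self.per_fold.copy()
        per_fold["fold"] = per_fold["fold"].astype(str)
        agg = self.aggregate.copy()
        agg.insert(2, "fold", "mean")
        pd.concat([per_fold, agg], ignore_index=True).to_csv(path, index=False)


def build_trajectory_features(ds: LongitudinalDataset, forecast: ForecastSet | None = None):
    """Per-subject [y(t), y(t+dt), y(t+2dt)] blocks over markers -> (X, labels).

    With ``forecast`` given, third-visit slots come from its predictions
    (forecast mode); otherwise all three visits must be observed (GT mode).
    """
    if forecast is not None:
        if forecast.marker_ids != ds.marker_ids or forecast.subject_ids != ds.subject_ids:
            raise ValueError("forecast does not cover the same subjects/markers as the dataset")
        third = forecast.predicted
    else:
        if ds.n_visits < 3:
            raise ValueError("ground-truth features require complete three-visit trajectories")
        third = ds.values[:, :, 2]
    blocks = np.stack([ds.values[:, :, 0], ds.values[:, :, 1], third], axis=2)
    return blocks.reshape(ds.n_subjects, 3 * ds.n_markers), ds.labels.copy()


def classify_trajectories(train_features, train_labels, test_features, C: float = 1.0):
    """Linear SVM on completed trajectories -> (predicted labels, decision scores).

    Scores are signed margin distances oriented so that larger means more
    progressor-like, suitable for ROC analysis.
    """
    train_labels = np.asarray(train_labels, int)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("trajectory classifier needs both classes in training labels")
    clf = SVC(kernel="linear", C=C)
    clf.fit(train_features, train_labels)
    scores = clf.decision_function(test_features)
    if clf.classes_[1] != 1:  # orient scores toward the progressor class
        scores = -scores
    return clf.predict(test_features), scores


def evaluate_metrics(labels_true, labels_pred, scores, predicted_values=None, observed_values=None) -> dict:
    """One metrics row: MAE (percent of the normalized scale), AUC, accuracy,
    sensitivity (progressor recall) and specificity (stable recall).

    With one-class truth the AUC is undefined and reported as NaN with a
    warning, never fabricated.
    """
    labels_true = np.asarray(labels_true, int)
    labels_pred = np.asarray(labels_pred, int)
    scores = np.asarray(scores, float)

    if predicted_values is None:
        mae_percent = 0.0
    else:
        mae_percent = 100.0 * float(
            np.mean(np.abs(np.asarray(predicted_values, float) - np.asarray(observed_values, float)))
        )

    if len(np.unique(labels_true)) < 2:
        logger.warning("single-class truth: AUC undefined, reported as NaN")
        auc = float("nan")
    else:
        auc = float(roc_auc_score(labels_true, scores))

    pos, neg = labels_true == 1, labels_true == 0
    return {
        "mae_percent": mae_percent,
        "auc": auc,
        "accuracy": float(np.mean(labels_pred == labels_true)),
        "sensitivity": float(np.mean(labels_pred[pos] == 1)) if pos.any() else float("nan"),
        "specificity": float(np.mean(labels_pred[neg] == 0)) if neg.any() else float("nan"),
    }


def run_nested_cv(ds: LongitudinalDataset, config: RunConfig) -> EvaluationReport:
    """Run the full nested cross-validated pipeline over incremental subsets.

    Markers are ranked by baseline t-test (once globally by default, or
    inside each training fold with ``rank_within_fold``); for each subset
    size 1..max_subset and each stratified outer fold, weights are fitted by
    the inner LOO average, test trajectories completed by forecasting, and a
    linear SVM trained on the training fold's observed trajectories scores
    the test fold. Modes: ``forecast``, ``gt`` (observed third visits,
    overriding the forecasting step) or ``both``.
    """
    config.validate()
    if config.dt is not None and abs(ds.dt - config.dt) > 1e-9:
        raise ValueError(f"config dt {config.dt} does not match dataset dt {ds.dt}")
    if ds.n_subjects < 10:
        raise ValueError(f"nested CV needs at least 10 subjects, got {ds.n_subjects}")
    if ds.n_visits < 3:
        raise ValueError("nested CV requires complete three-visit trajectories")
    max_subset = config.max_subset or ds.n_markers
    if not 1 <= max_subset <= ds.n_markers:
        raise ValueError(f"max_subset must be in [1, {ds.n_markers}], got {max_subset}")
    modes = ("forecast", "gt") if config.mode == "both" else (config.mode,)

    work = normalize_dataset(ds) if config.normalization == "pooled" else ds
    ranked = None if config.rank_within_fold else rank_markers(work, config.ttest)

    splitter = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    rows = []
    score_pool: dict = {}
    for fold, (tr_idx, te_idx) in enumerate(splitter.split(np.zeros(ds.n_subjects), work.labels)):
        train = work.select_subjects(tr_idx)
        test = work.select_subjects(te_idx)
        if len(np.unique(train.labels)) < 2 or len(np.unique(test.labels)) < 2:
            raise ValueError(f"outer fold {fold} lost a class; cohort too small or unbalanced")
        if config.normalization == "within_train":
            scales = marker_scales(train)
            train = normalize_dataset(train, scales)
            test = normalize_dataset(test, scales)
        fold_ranked = rank_markers(train, config.ttest) if config.rank_within_fold else ranked
        logger.debug("fold %d: %d train / %d test subjects", fold, train.n_subjects, test.n_subjects)

        for k in range(1, max_subset + 1):
            subset = fold_ranked.marker_ids[:k]
            train_k = train.select_markers(subset)
            test_k = test.select_markers(subset)

            model = fit_weights_loo(train_k)
            if config.base_classifier == "oracle":
                fc = forecast_dataset(test_k, model, base_classes=test_k.labels)
            else:
                base_svm = train_base_group_svm(train_k, C=config.svm_c)
                fc = forecast_dataset(test_k, model, base_svm)

            X_train, y_train = build_trajectory_features(train_k)
            for mode in modes:
                forecast_obj = fc if mode == "forecast" else None
                X_test, y_test = build_trajectory_features(test_k, forecast_obj)
                y_pred, scores = classify_trajectories(X_train, y_train, X_test, C=config.svm_c)
                if mode == "forecast":
                    metrics = evaluate_metrics(y_test, y_pred, scores, fc.predicted, fc.observed)
                else:
                    metrics = evaluate_metrics(y_test, y_pred, scores)
                rows.append({"mode": mode, "subset_size": k, "fold": fold,
                             "n_test": test_k.n_subjects, **metrics})
                pool = score_pool.setdefault((mode, k), ([], []))
                pool[0].append(y_test)
                pool[1].append(scores)

    per_fold = pd.DataFrame(rows)
    aggregate = (
        per_fold.groupby(["mode", "subset_size"], as_index=False)[_METRIC_COLUMNS]
        .mean()
        .sort_values(["mode", "subset_size"], ignore_index=True)
    )
    aggregate["auc_pooled"] = [
        float(roc_auc_score(np.concatenate(score_pool[(m, k)][0]),
                            np.concatenate(score_pool[(m, k)][1])))
        for m, k in zip(aggregate["mode"], aggregate["subset_size"])
    ]
    ranked_ids = ranked.marker_ids if ranked is not None else tuple(work.marker_ids)
    return EvaluationReport(per_fold=per_fold, aggregate=aggregate, ranked_marker_ids=ranked_ids)


def select_best_model(report: EvaluationReport, mode: str = "forecast"):
    """Subset size with the highest fold-averaged AUC (ties -> smallest subset)."""
    agg = report.aggregate[report.aggregate["mode"] == mode]
    if agg.empty:
        raise ValueError(f"report has no rows for mode {mode!r}")
    agg = agg.sort_values("subset_size")
    best = agg.loc[agg["auc"].idxmax()]  # idxmax returns the FIRST maximal row
    return int(best["subset_size"]), best


def plot_report(report: EvaluationReport, path) -> None:
    """Convenience two-panel figure: MAE and AUC versus subset size."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_mae, ax_auc) = plt.subplots(1, 2, figsize=(9, 3.5))
    for mode, group in report.aggregate.groupby("mode"):
        if mode == "forecast":
            ax_mae.plot(group["subset_size"], group["mae_percent"], marker="o", label=mode)
        ax_auc.plot(group["subset_size"], group["auc"], marker="o", label=mode)
    ax_mae.set_xlabel("subset size")
    ax_mae.set_ylabel("forecast MAE (%)")
    ax_auc.set_xlabel("subset size")
    ax_auc.set_ylabel("fold-averaged AUC")
    ax_auc.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
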