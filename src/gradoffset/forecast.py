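"""Third-visit forecasting via the base-group SVM and weighted gradient offset.

A test subject contributes only its first two visits. A linear SVM trained on
visit levels and annual changes suggests the subject's base group
(progressor or stable), which fixes the base gradient alpha_m per marker.
The subject's own deviation from alpha over the observed interval — the
offset vector OS_y — is pushed through the fitted weight matrix to obtain
the multimarker correction beta_m, and the forecast is

    y_m(t + 2 dt) = y_m(t + dt) + (alpha_m + beta_m) * dt
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .cohort import LongitudinalDataset
from .gradients import GradientModel, compute_subject_gradient

__all__ = [
    "ForecastSet",
    "base_group_features",
    "train_base_group_svm",
    "assign_base_gradient",
    "compute_test_offsets",
    "weighted_offset",
    "forecast_value",
    "forecast_dataset",
]

logger = logging.getLogger("gradoffset")


@dataclass(frozen=True)
class ForecastSet:
    """Forecast third-visit values with the quantities that produced them.

    ``predicted[i, m] = prior[i, m] + (alpha[i, m] + beta[i, m]) * dt`` where
    ``prior`` is the second visit. ``observed`` holds true third visits when
    available (NaN otherwise), enabling per-marker MAE.
    """

    subject_ids: tuple
    marker_ids: tuple
    dt: float
    predicted: np.ndarray
    observed: np.ndarray
    base_class: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        n, N = len(self.subject_ids), len(self.marker_ids)
        for name in ("predicted", "observed", "alpha", "beta"):
            arr = np.asarray(getattr(self, name), float)
            object.__setattr__(self, name, arr)
            if arr.shape != (n, N):
                raise ValueError(f"{name} must have shape ({n}, {N}); got {arr.shape}")
        bc = np.asarray(self.base_class, int)
        object.__setattr__(self, "base_class", bc)
        if not np.isin(bc, (0, 1)).all():
            raise ValueError("base_class must be 0 or 1")
        if not np.isfinite(self.predicted).all():
            raise ValueError("predictions must be finite")

    def mae(self, per_marker: bool = False):
        """Mean absolute forecast error on the working (normalized) scale."""
        err = np.abs(self.predicted - self.observed)
        if np.isnan(err).all():
            raise ValueError("no observed third visits available for MAE")
        return np.nanmean(err, axis=0) if per_marker else float(np.nanmean(err))


def base_group_features(ds: LongitudinalDataset) -> np.ndarray:
    """Per-marker [level(t), level(t+dt), annual change] feature blocks, (n, 3N)."""
    grads = compute_subject_gradient(ds.values[:, :, 0], ds.values[:, :, 1], ds.dt)
    blocks = np.stack([ds.values[:, :, 0], ds.values[:, :, 1], grads], axis=2)
    return blocks.reshape(ds.n_subjects, 3 * ds.n_markers)


def train_base_group_svm(train: LongitudinalDataset, marker_ids=None, C: float = 1.0) -> SVC:
    """Linear maximum-margin classifier of base group from two-visit features."""
    if marker_ids is not None:
        train = train.select_markers(marker_ids)
    if len(np.unique(train.labels)) < 2:
        raise ValueError("base-group SVM needs both classes in the training set")
    clf = SVC(kernel="linear", C=C)
    clf.fit(base_group_features(train), train.labels)
    return clf


def assign_base_gradient(subject_features: np.ndarray, classifier, base_gradients: np.ndarray):
    """Predict the subject's base group and return (class, alpha vector)."""
    base_gradients = np.asarray(base_gradients, float)
    features = np.atleast_2d(np.asarray(subject_features, float))
    if features.shape[1] != 3 * base_gradients.shape[1]:
        raise ValueError(
            f"feature length {features.shape[1]} does not match "
            f"{base_gradients.shape[1]} markers (expected 3 features per marker)"
        )
    c = int(classifier.predict(features)[0])
    return c, base_gradients[c].copy()


def compute_test_offsets(y_t, y_tdt, alpha, dt: float) -> np.ndarray:
    """Offset vector OS_y[m] = alpha_m - observed interval gradient of marker m."""
    alpha = np.asarray(alpha, float)
    grad = compute_subject_gradient(y_t, y_tdt, dt)
    if alpha.shape != np.shape(grad):
        raise ValueError(f"alpha shape {alpha.shape} does not match readings {np.shape(grad)}")
    os_y = alpha - grad
    if not np.isfinite(os_y).all():
        raise ValueError("offsets must be finite")
    return os_y


def weighted_offset(mu: np.ndarray, os_y: np.ndarray) -> np.ndarray:
    """Multimarker correction beta_m = mu[:, m] . OS_y (i.e. beta = mu^T OS_y)."""
    mu = np.asarray(mu, float)
    os_y = np.asarray(os_y, float)
    if mu.ndim != 2 or mu.shape[0] != mu.shape[1] or os_y.shape != (mu.shape[0],):
        raise ValueError(f"mu {mu.shape} and offset vector {os_y.shape} are not conformable")
    return mu.T @ os_y


def forecast_value(y_tdt, alpha, beta, dt: float):
    """One-step piecewise-linear forecast y(t+2dt) = y(t+dt) + (alpha+beta)*dt."""
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return np.asarray(y_tdt, float) + (np.asarray(alpha, float) + np.asarray(beta, float)) * dt


def forecast_dataset(
    test: LongitudinalDataset,
    model: GradientModel,
    classifier=None,
    *,
    base_classes=None,
) -> ForecastSet:
    """Complete every test subject's trajectory with a forecast third visit.

    ``classifier`` is the base-group SVM trained on the same marker subset.
    ``base_classes`` (mutually exclusive) bypasses it with explicit class
    assignments — e.g. true labels, to isolate forecasting error from
    base-group misclassification. Observed third visits are copied in when
    the test set has them.
    """
    test = test.select_markers(model.marker_ids)
    if abs(test.dt - model.dt) > 1e-12:
        raise ValueError(f"test dt {test.dt} does not match model dt {model.dt}")
    if (classifier is None) == (base_classes is None):
        raise ValueError("provide exactly one of classifier or base_classes")

    if base_classes is not None:
        base_classes = np.asarray(base_classes, int)
        if base_classes.shape != (test.n_subjects,):
            raise ValueError("base_classes must give one class per test subject")
    else:
        features = base_group_features(test)

    n, N = test.n_subjects, test.n_markers
    predicted = np.empty((n, N))
    alpha = np.empty((n, N))
    beta = np.empty((n, N))
    assigned = np.empty(n, int)
    for i in range(n):
        if base_classes is not None:
            c = int(base_classes[i])
            a = model.base_gradients[c].copy()
        else:
            c, a = assign_base_gradient(features[i], classifier, model.base_gradients)
        os_y = compute_test_offsets(test.values[i, :, 0], test.values[i, :, 1], a, test.dt)
        b = weighted_offset(model.mu, os_y)
        predicted[i] = forecast_value(test.values[i, :, 1], a, b, test.dt)
        assigned[i], alpha[i], beta[i] = c, a, b

    observed = test.values[:, :, 2].copy() if test.n_visits >= 3 else np.full((n, N), np.nan)
    return ForecastSet(
        subject_ids=test.subject_ids,
        marker_ids=test.marker_ids,
        dt=test.dt,
        predicted=predicted,
        observed=observed,
        base_class=assigned,
        alpha=alpha,
        beta=beta,
    )
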