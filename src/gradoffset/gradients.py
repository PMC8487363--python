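"""Gradient offsets and least-squares linear-prediction weights.

The trajectory model is piecewise linear over the two follow-up intervals.
For each class c and marker m, the base gradient delta_m^c is the class-mean
annual change over the first interval. A subject's gradient offset is the
base gradient minus the subject's own interval gradient — its deviation from
typical class progression. Stacking the first-interval offsets of all
training subjects into a matrix A and the second-interval ("future") offsets
of marker m into a column B_m gives the linear system

    A @ mu[:, m] = B_m

whose least-squares solution mu quantifies how deviations on ALL markers in
the current interval propagate into each marker's deviation over the next.
The future offset is oriented as observed-minus-base (the mirror image of
the first-interval offset): the forecast step adds the weighted offset to
the base gradient, so the regression target must be exactly the correction
that addition applies. Weights are averaged over leave-one-out folds of the
training set for stability on small cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import LongitudinalDataset

__all__ = [
    "GradientModel",
    "OffsetSystem",
    "compute_subject_gradient",
    "compute_base_gradients",
    "build_offset_system",
    "solve_weights",
    "fit_weights_loo",
]

logger = logging.getLogger("gradoffset")


@dataclass(frozen=True)
class OffsetSystem:
    """First-interval offsets A and future offsets B for one marker subset.

    Row i = training subject, column m = marker; ``B[:, m]`` is the target
    vector of the linear system for marker m.
    """

    A: np.ndarray
    B: np.ndarray
    subject_ids: tuple
    marker_ids: tuple

    def __post_init__(self):
        A, B = np.asarray(self.A, float), np.asarray(self.B, float)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        if A.ndim != 2 or A.shape != B.shape:
            raise ValueError(f"A and B must share a 2-D shape; got {A.shape} and {B.shape}")
        if A.shape[0] < 1:
            raise ValueError("offset system needs at least one subject")
        if A.shape[1] != len(self.marker_ids):
            raise ValueError("column count must match marker_ids")
        if not (np.isfinite(A).all() and np.isfinite(B).all()):
            raise ValueError("offsets must be finite")


@dataclass(frozen=True)
class GradientModel:
    """Fitted per-class base gradients and linear-prediction weights.

    ``base_gradients[c, m]`` is delta_m^c in normalized units per year
    (row 0 = stables, row 1 = progressors); ``mu[:, m]`` are the weights
    predicting marker m's future offset from all markers' current offsets.
    """

    dt: float
    marker_ids: tuple
    base_gradients: np.ndarray  # (2, N)
    mu: np.ndarray              # (N, N)
    n_loo_folds: int

    def __post_init__(self):
        base = np.asarray(self.base_gradients, float)
        mu = np.asarray(self.mu, float)
        object.__setattr__(self, "base_gradients", base)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "marker_ids", tuple(self.marker_ids))
        N = len(self.marker_ids)
        if base.shape != (2, N):
            raise ValueError(f"base_gradients must be (2, {N}); got {base.shape}")
        if mu.shape != (N, N):
            raise ValueError(f"mu must be ({N}, {N}); got {mu.shape}")
        if not np.isfinite(base).all():
            raise ValueError("base gradients must be finite")
        if not np.isfinite(mu).all():
            raise ValueError("mu must be finite")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")


def compute_subject_gradient(x_t, x_tdt, dt: float):
    """Piecewise gradient (x(t+dt) - x(t)) / dt; accepts scalars or arrays."""
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return (np.asarray(x_tdt, float) - np.asarray(x_t, float)) / dt


def compute_base_gradients(train: LongitudinalDataset) -> np.ndarray:
    """Class-mean first-interval gradients, shape (2, n_markers).

    delta_m^c = mean over class-c subjects of (x(t+dt) - x(t)) / dt.
    """
    grads = compute_subject_gradient(train.values[:, :, 0], train.values[:, :, 1], train.dt)
    out = np.empty((2, train.n_markers))
    for c in (0, 1):
        members = train.labels == c
        if not members.any():
            raise ValueError(f"class {c} has no subjects; cannot compute base gradients")
        out[c] = grads[members].mean(axis=0)
    return out


def build_offset_system(train: LongitudinalDataset, base_gradients: np.ndarray) -> OffsetSystem:
    """Offsets of every training subject relative to its TRUE class's base.

    A[i, m] = delta_m^c(i) - first-interval gradient of subject i;
    B[i, m] = second-interval gradient - delta_m^c(i), oriented so that the
    forecast gradient is base + weighted offset. Training labels are known,
    so the true class selects the base gradient (the classifier-based
    assignment applies only at forecast time).
    """
    if train.n_visits < 3:
        raise ValueError("offset system requires complete three-visit trajectories")
    base_gradients = np.asarray(base_gradients, float)
    if base_gradients.shape != (2, train.n_markers):
        raise ValueError(
            f"base_gradients must be (2, {train.n_markers}); got {base_gradients.shape}"
        )
    grad1 = compute_subject_gradient(train.values[:, :, 0], train.values[:, :, 1], train.dt)
    grad2 = compute_subject_gradient(train.values[:, :, 1], train.values[:, :, 2], train.dt)
    base = base_gradients[train.labels]  # (n, N)
    return OffsetSystem(base - grad1, grad2 - base, train.subject_ids, train.marker_ids)


def solve_weights(system: OffsetSystem) -> np.ndarray:
    """Least-squares weights mu (N x N) from A @ mu[:, m] = B[:, m].

    Uses the minimum-norm solution, which coincides with the normal-equations
    form (A^T A)^-1 A^T B_m whenever A^T A is invertible and survives
    rank-deficient systems (more markers than subjects, collinear markers) —
    those only draw a logged warning.
    """
    mu, _, rank, _ = np.linalg.lstsq(system.A, system.B, rcond=None)
    if rank < system.A.shape[1]:
        logger.warning(
            "offset system is rank-deficient (rank %d < %d markers); "
            "minimum-norm least-squares solution used", rank, system.A.shape[1],
        )
    return mu


def fit_weights_loo(
    train: LongitudinalDataset,
    marker_ids=None,
    *,
    refit_base_per_fold: bool = True,
) -> GradientModel:
    """Fit a GradientModel with leave-one-out-averaged weights.

    Each fold leaves one training subject out, recomputes base gradients on
    the retained subjects (unless ``refit_base_per_fold=False``, which holds
    the full-training-set bases fixed), builds the offset system and solves
    for the weights; the final ``mu`` is the element-wise mean over folds.
    Folds in which a class disappears are skipped with a warning. The
    returned ``base_gradients`` are always computed on the full training set.
    """
    if marker_ids is not None:
        train = train.select_markers(marker_ids)
    if train.n_subjects < 3:
        raise ValueError(f"leave-one-out weight fitting needs >= 3 subjects, got {train.n_subjects}")

    full_base = compute_base_gradients(train)
    mu_sum = np.zeros((train.n_markers, train.n_markers))
    n_folds = 0
    for i in range(train.n_subjects):
        keep = np.arange(train.n_subjects) != i
        retained = train.select_subjects(np.flatnonzero(keep))
        if len(np.unique(retained.labels)) < 2:
            logger.warning("LOO fold %d leaves a single class; fold skipped", i)
            continue
        base = compute_base_gradients(retained) if refit_base_per_fold else full_base
        mu_sum += solve_weights(build_offset_system(retained, base))
        n_folds += 1
    if n_folds == 0:
        raise ValueError("every leave-one-out fold lost a class; cannot fit weights")

    return GradientModel(
        dt=train.dt,
        marker_ids=train.marker_ids,
        base_gradients=full_base,
        mu=mu_sum / n_folds,
        n_loo_folds=n_folds,
    )
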