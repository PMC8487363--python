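"""Trajectory normalization and discriminative marker ranking.

Markers arrive on wildly different scales (cognitive test scores vs. regional
brain volumes in mm^3), so each marker's whole time-domain trajectory is
divided by that marker's maximum over all subjects and visits, preserving
longitudinal shape while mapping positive markers into (0, 1]. Markers are
then ranked by the p-value of a two-sample Student's t-test comparing
baseline readings between progressors and stables, and nested subsets are
formed by adding one marker at a time in rank order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .cohort import LongitudinalDataset

__all__ = ["RankedMarkers", "DegenerateMarkerError", "normalize_dataset", "rank_markers", "build_subsets"]

logger = logging.getLogger("gradoffset")


class DegenerateMarkerError(ValueError):
    """A marker carries no usable signal (e.g. all readings are zero)."""


def marker_scales(ds: LongitudinalDataset) -> np.ndarray:
    """Per-marker normalization divisors: max absolute reading over all
    subjects and visits (equal to the plain maximum for positive markers)."""
    scales = np.abs(ds.values).max(axis=(0, 2))
    zero = np.flatnonzero(scales == 0)
    if zero.size:
        raise DegenerateMarkerError(
            "marker(s) with all-zero readings cannot be normalized: "
            + ", ".join(ds.marker_ids[j] for j in zero)
        )
    return scales


def normalize_dataset(ds: LongitudinalDataset, scales: np.ndarray | None = None) -> LongitudinalDataset:
    """Divide each marker's readings by its maximum (absolute) value.

    Passing precomputed ``scales`` (e.g. from a training fold) applies those
    divisors instead, which is how the leakage-free within-train variant
    normalizes held-out data. Idempotent, and invariant to rescaling any
    marker by a positive constant.
    """
    if scales is None:
        scales = marker_scales(ds)
    else:
        scales = np.asarray(scales, dtype=float)
        if scales.shape != (ds.n_markers,):
            raise ValueError(f"scales must have shape ({ds.n_markers},); got {scales.shape}")
        if (scales <= 0).any() or not np.isfinite(scales).all():
            raise ValueError("scales must be positive and finite")
    return replace(ds, values=ds.values / scales[None, :, None])


def _pooled_t(a: np.ndarray, b: np.ndarray):
    """Classic pooled-variance two-sample t-statistic and its df (columnwise)."""
    n1, n2 = a.shape[0], b.shape[0]
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(axis=0, ddof=1) + (n2 - 1) * b.var(axis=0, ddof=1)) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, df, sp2


@dataclass(frozen=True)
class RankedMarkers:
    """Markers ordered by ascending baseline t-test p-value.

    ``p_values`` and ``t_statistics`` are in the ORIGINAL marker order;
    ``order`` holds original indices sorted by p-value (ties broken by
    original position, stable).
    """

    marker_ids: tuple      # ranked order, best first
    p_values: np.ndarray   # original order
    t_statistics: np.ndarray
    order: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p_values, float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def subsets(self) -> list:
        return build_subsets(self, len(self.marker_ids))


def rank_markers(ds: LongitudinalDataset, method: str = "student") -> RankedMarkers:
    """Rank markers by class-discriminative significance at baseline.

    A two-sample t-test on visit-1 readings (progressors vs. stables) is run
    per marker; smaller p means more discriminative. ``method`` is
    ``"student"`` for the classic pooled-variance test or ``"welch"`` for the
    unequal-variance variant. Markers with zero pooled variance get p = 1 if
    the class means agree and p = 0 otherwise (logged as degenerate).
    """
    if method not in ("student", "welch"):
        raise ValueError(f"method must be 'student' or 'welch', got {method!r}")
    baseline = ds.values[:, :, 0]
    pos, neg = baseline[ds.labels == 1], baseline[ds.labels == 0]
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise ValueError("both classes need at least 2 subjects for the t-test")

    t, p = stats.ttest_ind(pos, neg, equal_var=(method == "student"), axis=0)
    t = np.asarray(t, float).copy()
    p = np.asarray(p, float).copy()

    # zero-variance markers: scipy yields nan; apply the explicit convention
    _, _, sp2 = _pooled_t(pos, neg)
    degenerate = np.flatnonzero(sp2 == 0)
    for j in degenerate:
        equal_means = pos[:, j].mean() == neg[:, j].mean()
        t[j] = 0.0 if equal_means else np.inf
        p[j] = 1.0 if equal_means else 0.0
        logger.warning("marker %s has zero pooled baseline variance; p set to %g by convention",
                       ds.marker_ids[j], p[j])

    order = np.argsort(p, kind="stable")
    return RankedMarkers(
        marker_ids=tuple(ds.marker_ids[j] for j in order),
        p_values=p,
        t_statistics=t,
        order=order,
    )


def build_subsets(ranked: RankedMarkers, max_size: int) -> list:
    """Nested subsets of sizes 1..max_size, growing one rank at a time."""
    total = len(ranked.marker_ids)
    if not 1 <= max_size <= total:
        raise ValueError(f"max_size must be in [1, {total}], got {max_size}")
    return [ranked.marker_ids[:k] for k in range(1, max_size + 1)]
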