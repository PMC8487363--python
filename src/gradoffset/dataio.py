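"""Long-format CSV datasets, JSON model artifacts, and run configuration.

Datasets travel as tidy CSV with one reading per row
(``subject_id,label,marker_id,visit_time,value``): marker counts stay
unbounded and missing visits are representable, mirroring how longitudinal
clinical exports usually look. Fitted models are versioned JSON. All floats
round-trip at full precision so that reruns are bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields

import numpy as np
import pandas as pd
import yaml

from .cohort import LongitudinalDataset
from .gradients import GradientModel

__all__ = [
    "RunConfig",
    "read_long_csv",
    "write_long_csv",
    "read_model",
    "write_model",
    "write_forecast_csv",
]

logger = logging.getLogger("gradoffset")

MODEL_SCHEMA_VERSION = 1
_CSV_COLUMNS = ["subject_id", "label", "marker_id", "visit_time", "value"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated knobs of the full pipeline run.

    ``dt`` (years) is optional and, when given, checked against the dataset.
    ``max_subset`` of None means "use all markers". ``normalization='pooled'``
    scales by each marker's max over the full dataset before the train/test
    split; ``'within_train'`` derives scales from each training fold only.
    ``base_classifier='oracle'`` substitutes true labels for the base-group
    SVM, isolating forecast error from base-group misclassification.
    """

    dt: float | None = None
    folds: int = 5
    max_subset: int | None = None
    seed: int = 0
    mode: str = "both"
    normalization: str = "pooled"
    ttest: str = "student"
    svm_c: float = 1.0
    base_classifier: str = "svm"
    rank_within_fold: bool = False

    def validate(self) -> None:
        if self.dt is not None and not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.folds < 2:
            raise ValueError(f"folds must be >= 2, got {self.folds}")
        if self.max_subset is not None and self.max_subset < 1:
            raise ValueError(f"max_subset must be >= 1, got {self.max_subset}")
        if self.mode not in ("forecast", "gt", "both"):
            raise ValueError(f"mode must be forecast|gt|both, got {self.mode!r}")
        if self.normalization not in ("pooled", "within_train"):
            raise ValueError(f"normalization must be pooled|within_train, got {self.normalization!r}")
        if self.ttest not in ("student", "welch"):
            raise ValueError(f"ttest must be student|welch, got {self.ttest!r}")
        if not self.svm_c > 0:
            raise ValueError(f"svm_c must be positive, got {self.svm_c}")
        if self.base_classifier not in ("svm", "oracle"):
            raise ValueError(f"base_classifier must be svm|oracle, got {self.base_classifier!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**mapping)
        config.validate()
        return config

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# long-format dataset CSV
# ---------------------------------------------------------------------------


def write_long_csv(ds: LongitudinalDataset, path) -> None:
    """Serialize a dataset to tidy CSV, one reading per row."""
    records = []
    times = ds.visit_times
    for i, sid in enumerate(ds.subject_ids):
        for j, mid in enumerate(ds.marker_ids):
            for v in range(ds.n_visits):
                records.append((sid, int(ds.labels[i]), mid, float(times[v]),
                                float(ds.values[i, j, v])))
    # %.17g guarantees bit-exact float round-trips through the CSV
    pd.DataFrame.from_records(records, columns=_CSV_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_long_csv(path, expected_visits: int = 3) -> LongitudinalDataset:
    """Read and validate a tidy-CSV dataset.

    Subjects whose readings do not cover every marker at every one of the
    dataset's equally spaced visit times are excluded with a per-subject
    diagnostic (clinical studies drop subjects with missing designated
    follow-ups the same way). Structural problems — malformed values,
    inconsistent labels, duplicate readings — are hard errors.
    ``expected_visits=2`` accepts forecast-only input (no third visit).
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "marker_id": str},
                     float_precision="round_trip")
    missing_cols = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")

    for col in ("label", "visit_time", "value"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() | ~np.isfinite(
            pd.to_numeric(df[col], errors="coerce")
        )
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"{path}: malformed {col!r} at line {line}")
    df["label"] = df["label"].astype(int)
    if not df["label"].isin((0, 1)).all():
        line = int((~df["label"].isin((0, 1))).idxmax()) + 2
        raise ValueError(f"{path}: label must be 0 or 1 (line {line})")

    dup = df.duplicated(subset=["subject_id", "marker_id", "visit_time"])
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise ValueError(f"{path}: duplicate (subject, marker, visit) reading at line {line}")

    label_counts = df.groupby("subject_id")["label"].nunique()
    inconsistent = label_counts[label_counts > 1]
    if not inconsistent.empty:
        raise ValueError(f"{path}: inconsistent label for subject(s) {list(inconsistent.index)}")

    times = np.sort(df["visit_time"].unique())
    if len(times) != expected_visits:
        raise ValueError(
            f"{path}: expected {expected_visits} distinct visit times, found {len(times)}: {times}"
        )
    gaps = np.diff(times)
    if len(gaps) > 1 and not np.allclose(gaps, gaps[0], rtol=1e-9, atol=1e-12):
        raise ValueError(f"{path}: visit times {times} are not equally spaced")
    dt = float(gaps[0])
    if not dt > 0:
        raise ValueError(f"{path}: non-positive visit spacing {dt}")

    marker_ids = tuple(pd.unique(df["marker_id"]))
    subject_order = list(pd.unique(df["subject_id"]))
    expected_rows = len(marker_ids) * expected_visits

    grid = df.set_index(["subject_id", "marker_id", "visit_time"])["value"]
    kept_ids, labels, blocks, rejected = [], [], [], []
    for sid in subject_order:
        sub = df[df["subject_id"] == sid]
        if len(sub) != expected_rows:
            rejected.append(sid)
            continue
        try:
            block = np.array(
                [[grid[(sid, mid, t)] for t in times] for mid in marker_ids], float
            )
        except KeyError:
            rejected.append(sid)
            continue
        kept_ids.append(sid)
        labels.append(int(sub["label"].iloc[0]))
        blocks.append(block)

    if rejected:
        logger.warning(
            "%s: rejected %d subject(s) lacking readings for every marker at every "
            "designated visit: %s", path, len(rejected), ", ".join(rejected),
        )
    if not kept_ids:
        raise ValueError(f"{path}: no subject has complete readings at the designated visits")

    ds = LongitudinalDataset(tuple(kept_ids), np.array(labels), np.stack(blocks), dt, marker_ids)
    logger.info("%s: loaded %d subjects x %d markers x %d visits (dt=%g y)",
                path, ds.n_subjects, ds.n_markers, ds.n_visits, dt)
    return ds


# ---------------------------------------------------------------------------
# model JSON artifact
# ---------------------------------------------------------------------------


def write_model(model: GradientModel, path) -> None:
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "dt": model.dt,
        "marker_ids": list(model.marker_ids),
        "base_gradients": model.base_gradients.tolist(),
        "mu": model.mu.tolist(),
        "n_loo_folds": model.n_loo_folds,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_model(path) -> GradientModel:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: unsupported model schema version {version!r} "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    for field_name in ("dt", "marker_ids", "base_gradients", "mu", "n_loo_folds"):
        if field_name not in payload:
            raise ValueError(f"{path}: model artifact is missing field {field_name!r}")
    try:
        return GradientModel(
            dt=float(payload["dt"]),
            marker_ids=tuple(payload["marker_ids"]),
            base_gradients=np.array(payload["base_gradients"], float),
            mu=np.array(payload["mu"], float),
            n_loo_folds=int(payload["n_loo_folds"]),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: invalid model artifact: {exc}") from exc


def write_forecast_csv(fc, path) -> None:
    """Forecast table: subject_id, marker_id, predicted, observed, abs_error, base_class."""
    records = []
    for i, sid in enumerate(fc.subject_ids):
        for j, mid in enumerate(fc.marker_ids):
            obs = fc.observed[i, j]
            records.append((
                sid, mid, float(fc.predicted[i, j]),
                float(obs) if np.isfinite(obs) else "",
                float(abs(fc.predicted[i, j] - obs)) if np.isfinite(obs) else "",
                int(fc.base_class[i]),
            ))
    pd.DataFrame.from_records(
        records,
        columns=["subject_id", "marker_id", "predicted", "observed", "abs_error", "base_class"],
    ).to_csv(path, index=False)
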