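"""Cohort preprocessing: image QC, square resizing, clinical cleaning and
encoding, and the stratified train/test split.

QC keeps only patients with every required view present and free of
disqualifying defects (blur, injury, protocol violation); a blurry or
missing static view with a clean dynamic-protocol counterpart is
substituted rather than removed. Clinical cleaning removes anomalous ages
and fills blank questionnaire answers with "not answered". Encoding
one-hot-expands discrete answers and min–max-scales continuous features,
with every data-dependent parameter fitted on the training partition
only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import MinMaxScaler, OneHotEncoder

from .io import NOT_ANSWERED
from .synthetic import (
    CONTINUOUS_FEATURES,
    DISCRETE_FEATURES,
    VIEW_LABELS,
    ClinicalRecord,
    ThermalStudy,
)

REMOVAL_REASONS = ("missing_views", "blurry", "injury", "protocol_violation", "age_anomaly")


@dataclass
class QCReport:
    """Outcome of a QC pass: who was kept, who was removed and why, and
    which static views were substituted by their dynamic counterparts."""

    kept_patient_ids: list[str] = field(default_factory=list)
    removed: dict[str, str] = field(default_factory=dict)
    substitutions: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.kept_patient_ids) & set(self.removed)
        if overlap:
            raise ValueError(f"patients both kept and removed: {sorted(overlap)}")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kept_patient_ids": self.kept_patient_ids,
            "removed": self.removed,
            "substitutions": [
                {"patient_id": pid, "view": view, "change": change}
                for (pid, view), change in self.substitutions.items()
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def qc_filter(studies: list[ThermalStudy],
              required_views: set[str] | tuple[str, ...] = VIEW_LABELS,
              ) -> tuple[list[ThermalStudy], QCReport]:
    """Apply the image QC rules and return (kept studies, report).

    Substitution runs first: a blurry or missing view with a clean
    dynamic-protocol counterpart is replaced and the defect resolved.
    Remaining studies are removed if any required view is missing, or if a
    blur on a required view, an injury, or a protocol violation persists.
    The operation is idempotent: kept studies come back defect-free.
    """
    required = set(required_views)
    if not required or not required <= set(VIEW_LABELS):
        raise ValueError(
            f"required_views must be a non-empty subset of {VIEW_LABELS}, got {sorted(required)}"
        )
    report = QCReport()
    kept: list[ThermalStudy] = []
    for study in studies:
        s = study.copy()
        for defect in ("blurry", "missing_view"):
            if defect not in s.qc_flags:
                continue
            view = s.defect_views.get(defect)
            if view is not None and view in s.dynamic_views:
                s.views[view] = s.dynamic_views.pop(view)
                s.protocol[view] = "dynamic"
                s.qc_flags.discard(defect)
                s.defect_views.pop(defect, None)
                report.substitutions[(s.patient_id, view)] = "static->dynamic"

        reason = None
        if not required <= set(s.views):
            reason = "missing_views"
        elif "blurry" in s.qc_flags and s.defect_views.get("blurry") in required:
            reason = "blurry"
        elif "injury" in s.qc_flags:
            reason = "injury"
        elif "protocol_violation" in s.qc_flags:
            reason = "protocol_violation"

        if reason is None:
            kept.append(s)
            report.kept_patient_ids.append(s.patient_id)
        else:
            report.removed[s.patient_id] = reason
    return kept, report


def resize_square(matrix: np.ndarray, side: int = 640) -> np.ndarray:
    """Bilinear resize of an H x W temperature grid to side x side.

    Uses corner-aligned sampling: output pixel (i, j) samples the input at
    fractional coordinates ``(i * (H-1)/(S-1), j * (W-1)/(S-1))``. A
    non-square input is simply stretched. Output values are convex
    combinations of input values, so the output range stays within the
    input range and a constant image maps to itself.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError(f"input must be at least 2x2, got shape {m.shape}")
    if side < 2:
        raise ValueError(f"output side must be >= 2, got {side}")
    rows = np.linspace(0.0, m.shape[0] - 1.0, side)
    cols = np.linspace(0.0, m.shape[1] - 1.0, side)
    grid = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(m, grid, order=1, mode="nearest")


def clean_clinical(records: list[ClinicalRecord], age_min: float = 1.0,
                   age_max: float = 119.0,
                   menarche_median: float | None = None,
                   ) -> tuple[list[ClinicalRecord], QCReport]:
    """Remove age anomalies, fill blanks, impute missing menarche age.

    Ages outside ``[age_min, age_max]`` (or missing) are anomalies and the
    patient is removed. Blank discrete answers become the literal category
    "not answered". A missing menarche age is imputed with the median of
    the supplied records unless ``menarche_median`` (e.g. fitted on the
    training partition) is given.
    """
    if menarche_median is None:
        observed = [
            r.continuous.get("menarche_age")
            for r in records
            if r.continuous.get("menarche_age") is not None
        ]
        menarche_median = float(np.median(observed)) if observed else 13.0

    report = QCReport()
    cleaned: list[ClinicalRecord] = []
    for record in records:
        age = record.continuous.get("age_at_screening")
        if age is None or not (age_min <= age <= age_max):
            report.removed[record.patient_id] = "age_anomaly"
            continue
        r = record.copy()
        for name, value in r.discrete.items():
            if not value or not value.strip():
                r.discrete[name] = NOT_ANSWERED
        if r.continuous.get("menarche_age") is None:
            r.continuous["menarche_age"] = menarche_median
        cleaned.append(r)
        report.kept_patient_ids.append(r.patient_id)
    return cleaned, report


@dataclass
class EncodedClinical:
    """Design matrix for the clinical network: one-hot discrete blocks plus
    min–max-scaled continuous columns, with 0/1 labels (sick = 1)."""

    feature_names: list[str]
    matrix: np.ndarray
    label_vector: np.ndarray
    patient_ids: list[str]

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


class ClinicalEncoder(TransformerMixin, BaseEstimator):
    """One-hot + min–max encoding fitted on training records only.

    Discrete answers are one-hot encoded over the categories observed in
    the training data; a category unseen at fit time maps to an all-zero
    block. Continuous features are min–max scaled with training-fitted
    bounds (a constant training column maps to 0); applying the fitted
    scaler to test data may produce values outside [0, 1] and must not be
    refitted.
    """

    def __init__(self, discrete_features: tuple[str, ...] = DISCRETE_FEATURES,
                 continuous_features: tuple[str, ...] = CONTINUOUS_FEATURES) -> None:
        self.discrete_features = discrete_features
        self.continuous_features = continuous_features

    def _frame(self, records: list[ClinicalRecord]) -> pd.DataFrame:
        rows = []
        for r in records:
            row: dict[str, object] = {}
            for name in self.discrete_features:
                value = r.discrete.get(name, "")
                row[name] = value if value else NOT_ANSWERED
            for name in self.continuous_features:
                value = r.continuous.get(name)
                if value is None:
                    raise ValueError(
                        f"record {r.patient_id}: continuous feature {name!r} is "
                        "missing; clean the records first"
                    )
                row[name] = float(value)
            rows.append(row)
        return pd.DataFrame(
            rows, columns=[*self.discrete_features, *self.continuous_features]
        )

    def fit(self, records: list[ClinicalRecord], y=None) -> "ClinicalEncoder":
        if not records:
            raise ValueError("cannot fit the clinical encoder on an empty record list")
        df = self._frame(records)
        self.onehot_ = OneHotEncoder(handle_unknown="ignore", sparse_output=False)
        self.onehot_.fit(df[list(self.discrete_features)])
        self.scaler_ = MinMaxScaler(clip=False)
        self.scaler_.fit(df[list(self.continuous_features)].astype(float))
        self.feature_names_ = [
            *self.onehot_.get_feature_names_out(list(self.discrete_features)),
            *self.continuous_features,
        ]
        return self

    def transform(self, records: list[ClinicalRecord]) -> np.ndarray:
        df = self._frame(records)
        onehot = self.onehot_.transform(df[list(self.discrete_features)])
        scaled = self.scaler_.transform(df[list(self.continuous_features)].astype(float))
        return np.hstack([onehot, scaled])

    def encode(self, records: list[ClinicalRecord]) -> EncodedClinical:
        matrix = self.transform(records)
        labels = np.array([1 if r.diagnosis == "sick" else 0 for r in records])
        return EncodedClinical(
            feature_names=list(self.feature_names_),
            matrix=matrix,
            label_vector=labels,
            patient_ids=[r.patient_id for r in records],
        )


def encode_clinical(records: list[ClinicalRecord]) -> EncodedClinical:
    """Fit-and-encode in one step (single-partition use); for a train/test
    flow, fit a :class:`ClinicalEncoder` on the training records and call
    ``encode`` on each partition."""
    return ClinicalEncoder().fit(records).encode(records)


@dataclass
class SplitSpec:
    test_fraction: float = 0.2
    stratify_by_label: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError(f"test_fraction must lie in (0, 1), got {self.test_fraction}")


def stratified_split(n_per_class: dict[str, int],
                     spec: SplitSpec | None = None) -> dict[str, tuple[int, int]]:
    """Per-class (train, test) counts: test = round-half-up of the test
    fraction, train the remainder. 157 healthy / 84 sick at 20% gives
    (126, 31) and (67, 17)."""
    spec = spec or SplitSpec()
    out = {}
    for label, n in n_per_class.items():
        if n < 0:
            raise ValueError(f"count for class {label!r} must be >= 0, got {n}")
        test = int(math.floor(spec.test_fraction * n + 0.5))
        out[label] = (n - test, test)
    return out


def split_assignments(ids_by_class: dict[str, list[str]],
                      spec: SplitSpec | None = None) -> dict[str, str]:
    """Assign each patient to 'train' or 'test' by a seeded permutation
    within class, honouring the round-half-up counts."""
    spec = spec or SplitSpec()
    counts = stratified_split({k: len(v) for k, v in ids_by_class.items()}, spec)
    rng = np.random.default_rng(spec.seed)
    assignment: dict[str, str] = {}
    for label in sorted(ids_by_class):
        ids = list(ids_by_class[label])
        order = rng.permutation(len(ids))
        _, n_test = counts[label]
        test_idx = set(order[:n_test].tolist())
        for i, pid in enumerate(ids):
            assignment[pid] = "test" if i in test_idx else "train"
    return assignment


def write_split_csv(assignment: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(assignment.items()), columns=["patient_id", "partition"]
    ).to_csv(path, index=False)
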