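"""End-to-end synthetic experiments: generate → QC → split → train both
fusion variants → evaluate on a common test partition.

This is the programmatic equivalent of the ``run`` CLI subcommand and the
entry point the evaluation scripts use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import MetricsReport, compare_reports, evaluate_scores
from .pipeline import MultiViewFusionClassifier, TrainConfig
from .preprocessing import (
    ClinicalEncoder,
    SplitSpec,
    clean_clinical,
    qc_filter,
    resize_square,
    split_assignments,
)
from .models import DEFAULT_VIEWS
from .synthetic import SyntheticConfig, cohort_arrays, generate_cohort


@dataclass
class PreparedCohort:
    """Model-ready train/test arrays for one synthetic cohort."""

    X_train: dict
    y_train: np.ndarray
    X_test: dict
    y_test: np.ndarray
    train_ids: list[str]
    test_ids: list[str]
    input_side: int
    views: tuple[str, ...]
    n_removed: int = 0


def prepare_synthetic(config: SyntheticConfig,
                      views: tuple[str, ...] = DEFAULT_VIEWS,
                      split: SplitSpec | None = None,
                      with_clinical: bool = True) -> PreparedCohort:
    """Generate a cohort, apply QC and cleaning, resize to square, encode
    clinical features on the training partition only, and split."""
    split = split or SplitSpec(seed=config.seed)
    side = min(config.image_height, config.image_width)
    studies, records = generate_cohort(config)
    kept, _ = qc_filter(studies, views)
    cleaned, _ = clean_clinical(records)
    clin = {r.patient_id: r for r in cleaned}
    kept = [s for s in kept if s.patient_id in clin]
    n_removed = len(studies) - len(kept)

    resized = []
    for s in kept:
        s = s.copy()
        s.views = {v: resize_square(m, side) for v, m in s.views.items() if v in views}
        resized.append(s)

    by_class: dict[str, list[str]] = {}
    for s in resized:
        by_class.setdefault(s.diagnosis, []).append(s.patient_id)
    assignment = split_assignments(by_class, split)
    train_studies = [s for s in resized if assignment[s.patient_id] == "train"]
    test_studies = [s for s in resized if assignment[s.patient_id] == "test"]

    encoder = None
    if with_clinical:
        encoder = ClinicalEncoder().fit([clin[s.patient_id] for s in train_studies])

    def pack(study_list):
        images, y, ids = cohort_arrays(study_list, views)
        clinical = encoder.transform([clin[p] for p in ids]) if encoder else None
        return {"images": images, "clinical": clinical}, y, ids

    X_train, y_train, train_ids = pack(train_studies)
    X_test, y_test, test_ids = pack(test_studies)
    return PreparedCohort(
        X_train=X_train, y_train=y_train, X_test=X_test, y_test=y_test,
        train_ids=train_ids, test_ids=test_ids, input_side=side, views=views,
        n_removed=n_removed,
    )


@dataclass
class ExperimentResult:
    """Reports for both fusion variants plus per-view test accuracies."""

    report_without_cd: MetricsReport
    report_with_cd: MetricsReport | None
    view_accuracies: dict[str, float]
    pipelines: dict[str, MultiViewFusionClassifier] = field(default_factory=dict)
    y_test: np.ndarray | None = None

    @property
    def accuracy_delta(self) -> float | None:
        if self.report_with_cd is None:
            return None
        return self.report_with_cd.accuracy - self.report_without_cd.accuracy

    def comparison(self):
        if self.report_with_cd is None:
            raise ValueError("no with-clinical report to compare")
        return compare_reports(self.report_without_cd, self.report_with_cd)


def run_experiment(config: SyntheticConfig,
                   views: tuple[str, ...] = DEFAULT_VIEWS,
                   architecture: str = "model1",
                   train_config: TrainConfig | None = None,
                   with_clinical: bool = True,
                   keep_pipelines: bool = False) -> ExperimentResult:
    """Train and evaluate the fusion pipeline with and (optionally)
    without the clinical-data decision on one synthetic cohort."""
    train_config = train_config or TrainConfig(seed=config.seed)
    prepared = prepare_synthetic(config, views=views, with_clinical=with_clinical)

    reports: dict[str, MetricsReport] = {}
    pipelines: dict[str, MultiViewFusionClassifier] = {}
    view_acc: dict[str, float] = {}
    variants = [("without_cd", False)] + ([("with_cd", True)] if with_clinical else [])
    for name, use_clinical in variants:
        pipe = MultiViewFusionClassifier(
            views=views, architecture=architecture, input_side=prepared.input_side,
            use_clinical=use_clinical, train_config=train_config,
            random_state=train_config.seed,
        )
        pipe.fit(prepared.X_train, prepared.y_train)
        reports[name] = evaluate_scores(
            prepared.y_test, pipe.sick_scores(prepared.X_test),
            predicted_labels=pipe.predict(prepared.X_test),
        )
        pipelines[name] = pipe
        if not use_clinical:
            for view, model in pipe.view_models_.items():
                view_acc[view] = float(
                    (model.predict(prepared.X_test["images"][view]) == prepared.y_test).mean()
                )
    return ExperimentResult(
        report_without_cd=reports["without_cd"],
        report_with_cd=reports.get("with_cd"),
        view_accuracies=view_acc,
        pipelines=pipelines if keep_pipelines else {},
        y_test=prepared.y_test,
    )
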