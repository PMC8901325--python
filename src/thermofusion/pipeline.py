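"""Two-stage training of the multi-view late-fusion classifier.

Stage one trains each per-view CNN independently (and the clinical
network when clinical features are used). Stage two freezes those
components, runs them over the training patients to produce fusion
vectors — concatenated per-view probability pairs, optionally ending with
the clinical decision — and trains the final fusion network on the
vectors. Component weights are never touched during fusion training.

The top-level :class:`MultiViewFusionClassifier` is a scikit-learn-style
meta-estimator; its ``X`` is a dict ``{"images": {view: (n, s, s)
array}, "clinical": (n, d) array or None}`` as produced by
:func:`thermofusion.synthetic.cohort_arrays` plus a fitted
:class:`~thermofusion.preprocessing.ClinicalEncoder`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted

from .models import (
    DEFAULT_VIEWS,
    MODEL1_CHANNELS,
    ClinicalNetClassifier,
    FusionClassifier,
    FusionInput,
    ViewCNNClassifier,
    ViewPrediction,
    adjust_channels_for_side,
    assemble_fusion_input,
    clinical_decision,
    model1_spec,
    model2_spec,
)


@dataclass
class TrainConfig:
    """Optimisation settings shared by all three training stages.

    Stochastic gradient descent with learning rate 0.001 and 2-way
    cross-entropy (binary cross-entropy for the clinical net) are the
    defaults; Adam is available but prone to overfitting on cohorts this
    small. ``max_epochs_per_view`` may be a single int or a per-view map.
    """

    optimizer: str = "sgd"
    learning_rate: float = 1e-3
    batch_size: int = 8
    max_epochs_per_view: int | dict[str, int] = 30
    clinical_max_epochs: int = 200
    fusion_max_epochs: int = 300
    early_stop_patience: int = 5
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError(f"learning_rate must be >= 0, got {self.learning_rate}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")

    def epochs_for(self, view: str) -> int:
        if isinstance(self.max_epochs_per_view, dict):
            return self.max_epochs_per_view[view]
        return self.max_epochs_per_view


@dataclass
class TrainedPipeline:
    """Trained components plus per-model loss histories."""

    view_models: dict[str, ViewCNNClassifier]
    fusion_model: FusionClassifier
    clinical_model: ClinicalNetClassifier | None = None
    train_history: dict[str, list[float]] = field(default_factory=dict)
    config: TrainConfig | None = None


def _seed_stream(seed: int, n: int) -> list[int]:
    """Deterministic per-component seeds derived from one run seed."""
    state = np.random.SeedSequence(seed & 0x7FFFFFFF).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


class MultiViewFusionClassifier(ClassifierMixin, BaseEstimator):
    """Late-fusion classifier over multiple thermogram views with an
    optional clinical-data contribution.

    Parameters
    ----------
    views : tuple of str
        Views the pipeline consumes; the default is the three-view setup
        (front, left 90°, right 90°); the full five-view setup is also
        supported.
    architecture : {"model1", "model2"}
        Model 1 shares a 32/64/128 conv stack across views; Model 2 uses
        deeper per-view stacks (50/100/150/200 frontal, 45/90/135/180
        lateral).
    use_clinical : bool
        Append the clinical network's contribution as the final fusion
        element.
    clinical_mode : {"decision", "probability"}
        Append the thresholded 0/1 decision (default) or the raw sigmoid
        probability.
    auto_depth : bool
        Trim trailing conv blocks that would collapse spatially at the
        configured ``input_side`` (needed for Model 2 at small test-scale
        images); the adjustment is recorded in ``depth_adjustments_``.
    """

    def __init__(self, views: tuple[str, ...] = DEFAULT_VIEWS,
                 architecture: str = "model1", input_side: int = 64,
                 use_clinical: bool = True, clinical_mode: str = "decision",
                 threshold: float = 0.5, auto_depth: bool = True,
                 train_config: TrainConfig | None = None,
                 random_state: int = 0) -> None:
        self.views = views
        self.architecture = architecture
        self.input_side = input_side
        self.use_clinical = use_clinical
        self.clinical_mode = clinical_mode
        self.threshold = threshold
        self.auto_depth = auto_depth
        self.train_config = train_config
        self.random_state = random_state

    # -- construction -----------------------------------------------------
    def _spec_channels(self, view: str) -> tuple[int, ...]:
        if self.architecture == "model1":
            channels = MODEL1_CHANNELS
        elif self.architecture == "model2":
            channels = (model2_spec(view, self.input_side).conv_channels)
        else:
            raise ValueError(
                f"architecture must be 'model1' or 'model2', got {self.architecture!r}"
            )
        if self.auto_depth:
            adjusted = adjust_channels_for_side(channels, self.input_side)
            if adjusted != tuple(channels):
                self.depth_adjustments_[view] = {
                    "requested": list(channels), "used": list(adjusted),
                }
            return adjusted
        return tuple(channels)

    def _config(self) -> TrainConfig:
        return self.train_config if self.train_config is not None else TrainConfig(
            seed=self.random_state
        )

    # -- fitting ----------------------------------------------------------
    def fit(self, X: dict, y: np.ndarray) -> "MultiViewFusionClassifier":
        images = X.get("images", {})
        clinical = X.get("clinical")
        missing = [v for v in self.views if v not in images]
        if missing:
            raise ValueError(f"missing required views in training data: {missing}")
        if self.use_clinical and clinical is None:
            raise ValueError(
                "use_clinical=True but no 'clinical' matrix was provided"
            )
        if self.clinical_mode not in ("decision", "probability"):
            raise ValueError(
                f"clinical_mode must be 'decision' or 'probability', got {self.clinical_mode!r}"
            )
        y = np.asarray(y)
        cfg = self._config()
        self.depth_adjustments_: dict[str, dict] = {}
        seeds = _seed_stream(cfg.seed, len(self.views) + 2)
        self.train_history_: dict[str, list[float]] = {}

        self.view_models_: dict[str, ViewCNNClassifier] = {}
        for view, seed in zip(self.views, seeds):
            model = ViewCNNClassifier(
                conv_channels=self._spec_channels(view),
                input_side=self.input_side,
                optimizer=cfg.optimizer,
                learning_rate=cfg.learning_rate,
                batch_size=cfg.batch_size,
                max_epochs=cfg.epochs_for(view),
                early_stop_patience=cfg.early_stop_patience,
                tol=cfg.tol,
                random_state=seed,
            )
            model.fit(images[view], y)
            self.view_models_[view] = model
            self.train_history_[f"view:{view}"] = model.loss_history_

        self.clinical_model_: ClinicalNetClassifier | None = None
        if self.use_clinical:
            self.clinical_model_ = ClinicalNetClassifier(
                threshold=self.threshold,
                optimizer=cfg.optimizer,
                learning_rate=cfg.learning_rate,
                batch_size=cfg.batch_size,
                max_epochs=cfg.clinical_max_epochs,
                early_stop_patience=cfg.early_stop_patience,
                tol=cfg.tol,
                random_state=seeds[len(self.views)],
            )
            self.clinical_model_.fit(clinical, y)
            self.train_history_["clinical"] = self.clinical_model_.loss_history_

        fusion_X = self.fusion_matrix(X)
        self.n_features_fusion_ = fusion_X.shape[1]
        self.fusion_model_ = FusionClassifier(
            input_dim=fusion_X.shape[1],
            optimizer=cfg.optimizer,
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            max_epochs=cfg.fusion_max_epochs,
            early_stop_patience=cfg.early_stop_patience,
            tol=cfg.tol,
            random_state=seeds[len(self.views) + 1],
        )
        self.fusion_model_.fit(fusion_X, y)
        self.train_history_["fusion"] = self.fusion_model_.loss_history_
        self.classes_ = self.fusion_model_.classes_
        return self

    # -- inference --------------------------------------------------------
    def _clinical_values(self, clinical: np.ndarray) -> np.ndarray:
        scores = self.clinical_model_.predict_score(clinical)
        if self.clinical_mode == "decision":
            return np.array([clinical_decision(p, self.threshold) for p in scores],
                            dtype=float)
        return scores

    def fusion_matrix(self, X: dict) -> np.ndarray:
        """Run the frozen components over a cohort and stack the fusion
        vectors row-wise."""
        images = X.get("images", {})
        clinical = X.get("clinical")
        missing = [v for v in self.views if v not in images]
        if missing:
            raise ValueError(f"missing required views: {missing}")
        n = next(iter(images.values())).shape[0]
        view_probs = {v: self.view_models_[v].predict_proba(images[v]) for v in self.views}
        if self.use_clinical:
            if clinical is None:
                raise ValueError(
                    "pipeline was configured with clinical data but none was provided"
                )
            clinical_vals = self._clinical_values(clinical)
        rows = []
        for i in range(n):
            preds = {
                v: ViewPrediction(p_healthy=float(view_probs[v][i, 0]),
                                  p_sick=float(view_probs[v][i, 1]))
                for v in self.views
            }
            extra = float(clinical_vals[i]) if self.use_clinical else None
            rows.append(assemble_fusion_input(preds, extra).values)
        return np.vstack(rows) if rows else np.empty((0, 2 * len(self.views)))

    def predict_proba(self, X: dict) -> np.ndarray:
        check_is_fitted(self, "fusion_model_")
        return self.fusion_model_.predict_proba(self.fusion_matrix(X))

    def predict(self, X: dict) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def predict_detailed(self, X: dict) -> list[dict]:
        """Per-patient audit trail: per-view probability pairs, the
        assembled fusion input, and the final prediction."""
        check_is_fitted(self, "fusion_model_")
        images = X.get("images", {})
        clinical = X.get("clinical")
        fusion_X = self.fusion_matrix(X)
        proba = self.fusion_model_.predict_proba(fusion_X)
        out = []
        for i in range(fusion_X.shape[0]):
            preds = {
                v: ViewPrediction(
                    p_healthy=float(self.view_models_[v].predict_proba(
                        images[v][i:i + 1])[0, 0]),
                    p_sick=float(self.view_models_[v].predict_proba(
                        images[v][i:i + 1])[0, 1]),
                )
                for v in self.views
            }
            extra = (
                float(self._clinical_values(clinical[i:i + 1])[0])
                if self.use_clinical else None
            )
            out.append(
                {
                    "view_predictions": preds,
                    "fusion_input": assemble_fusion_input(preds, extra),
                    "fusion_proba": proba[i],
                    "prediction": self.classes_[int(np.argmax(proba[i]))],
                }
            )
        return out

    def sick_scores(self, X: dict) -> np.ndarray:
        """P(sick) from the fusion head, for ROC / PR curves."""
        return self.predict_proba(X)[:, 1]


# -- thin functional wrappers over the estimators --------------------------

def train_view_model(model: ViewCNNClassifier, X: np.ndarray, y: np.ndarray,
                     config: TrainConfig | None = None,
                     view: str | None = None) -> tuple[ViewCNNClassifier, list[float]]:
    """Fit one per-view CNN under a :class:`TrainConfig`."""
    if config is not None:
        model.set_params(
            optimizer=config.optimizer, learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            max_epochs=config.epochs_for(view) if view else config.max_epochs_per_view
            if isinstance(config.max_epochs_per_view, int) else model.max_epochs,
            early_stop_patience=config.early_stop_patience, tol=config.tol,
            random_state=config.seed,
        )
    model.fit(X, y)
    return model, model.loss_history_


def train_clinical_ann(model: ClinicalNetClassifier, X: np.ndarray, y: np.ndarray,
                       config: TrainConfig | None = None,
                       ) -> tuple[ClinicalNetClassifier, list[float]]:
    if config is not None:
        model.set_params(
            optimizer=config.optimizer, learning_rate=config.learning_rate,
            batch_size=config.batch_size, max_epochs=config.clinical_max_epochs,
            early_stop_patience=config.early_stop_patience, tol=config.tol,
            random_state=config.seed,
        )
    model.fit(X, y)
    return model, model.loss_history_


def train_fusion(view_models: dict[str, ViewCNNClassifier],
                 clinical_model: ClinicalNetClassifier | None,
                 X: dict, y: np.ndarray,
                 config: TrainConfig | None = None,
                 clinical_mode: str = "decision",
                 threshold: float = 0.5) -> TrainedPipeline:
    """Train the fusion head on frozen, already-trained components."""
    views = tuple(view_models)
    images = X.get("images", {})
    missing = [v for v in views if v not in images]
    if missing:
        raise ValueError(f"missing required view data for fusion training: {missing}")
    for view, model in view_models.items():
        if getattr(model, "net_", None) is None:
            raise ValueError(f"view model for {view!r} is not trained")
    cfg = config or TrainConfig()

    shell = MultiViewFusionClassifier(
        views=views, use_clinical=clinical_model is not None,
        clinical_mode=clinical_mode, threshold=threshold,
        input_side=next(iter(view_models.values())).input_side,
        train_config=cfg, random_state=cfg.seed,
    )
    shell.view_models_ = view_models
    shell.clinical_model_ = clinical_model
    fusion_X = shell.fusion_matrix(X)
    fusion = FusionClassifier(
        input_dim=fusion_X.shape[1], optimizer=cfg.optimizer,
        learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
        max_epochs=cfg.fusion_max_epochs,
        early_stop_patience=cfg.early_stop_patience, tol=cfg.tol,
        random_state=cfg.seed,
    )
    fusion.fit(fusion_X, np.asarray(y))
    shell.fusion_model_ = fusion
    shell.classes_ = fusion.classes_
    shell.n_features_fusion_ = fusion_X.shape[1]
    shell.train_history_ = {"fusion": fusion.loss_history_}
    return TrainedPipeline(
        view_models=view_models, fusion_model=fusion, clinical_model=clinical_model,
        train_history={"fusion": fusion.loss_history_}, config=cfg,
    )


def predict(pipeline: MultiViewFusionClassifier, X: dict) -> list[dict]:
    """Audit-friendly prediction for one or more patients."""
    return pipeline.predict_detailed(X)


# -- persistence ------------------------------------------------------------

def save_history_csv(history: dict[str, list[float]], path: str | Path) -> None:
    rows = [
        {"model": name, "epoch": i + 1, "loss": loss}
        for name, series in history.items()
        for i, loss in enumerate(series)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def save_pipeline(pipeline: MultiViewFusionClassifier, out_dir: str | Path) -> None:
    """Persist weights (npz per component) plus a JSON sidecar with the
    estimator parameters."""
    check_is_fitted(pipeline, "fusion_model_")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def dump(net, name):
        np.savez(out_dir / f"{name}.npz",
                 **{f"p{i}": p for i, p in enumerate(net.params)})

    for view, model in pipeline.view_models_.items():
        dump(model.net_, f"view_{view}")
    if pipeline.clinical_model_ is not None:
        dump(pipeline.clinical_model_.net_, "clinical")
    dump(pipeline.fusion_model_.net_, "fusion")
    sidecar = {
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in pipeline.get_params().items()
                   if k != "train_config"},
        "train_config": asdict(pipeline._config()),
        "classes": pipeline.classes_.tolist(),
        "n_features_fusion": int(pipeline.n_features_fusion_),
        "clinical_n_features": (
            int(pipeline.clinical_model_.n_features_in_)
            if pipeline.clinical_model_ is not None else None
        ),
    }
    (out_dir / "pipeline.json").write_text(json.dumps(sidecar, indent=2))


def load_pipeline(out_dir: str | Path) -> MultiViewFusionClassifier:
    out_dir = Path(out_dir)
    sidecar = json.loads((out_dir / "pipeline.json").read_text())
    params = dict(sidecar["params"])
    params["views"] = tuple(params["views"])
    cfg = TrainConfig(**sidecar["train_config"])
    pipe = MultiViewFusionClassifier(train_config=cfg, **params)
    classes = np.asarray(sidecar["classes"])
    cfg_seeds = _seed_stream(cfg.seed, len(pipe.views) + 2)

    def load_into(net, name):
        data = np.load(out_dir / f"{name}.npz")
        for i, p in enumerate(net.params):
            p[...] = data[f"p{i}"]

    pipe.depth_adjustments_ = {}
    pipe.view_models_ = {}
    for view, seed in zip(pipe.views, cfg_seeds):
        model = ViewCNNClassifier(
            conv_channels=pipe._spec_channels(view), input_side=pipe.input_side,
            random_state=seed,
        )
        rng = np.random.default_rng(seed)
        model.net_ = model._build(rng)
        model.classes_ = classes
        load_into(model.net_, f"view_{view}")
        pipe.view_models_[view] = model

    pipe.clinical_model_ = None
    if params.get("use_clinical"):
        clin = ClinicalNetClassifier(threshold=params.get("threshold", 0.5))
        n_in = sidecar["clinical_n_features"]
        rng = np.random.default_rng(0)
        import thermofusion.nn as nnmod
        layers = []
        d = n_in
        for width in clin.hidden_widths:
            layers += [nnmod.Dense(d, width, rng=rng), nnmod.ReLU()]
            d = width
        layers.append(nnmod.Dense(d, 1, rng=rng))
        clin.net_ = nnmod.Network(layers)
        clin.classes_ = classes
        clin.n_features_in_ = n_in
        load_into(clin.net_, "clinical")
        pipe.clinical_model_ = clin

    fusion = FusionClassifier(input_dim=sidecar["n_features_fusion"])
    rng = np.random.default_rng(0)
    import thermofusion.nn as nnmod
    fusion.net_ = nnmod.Network([
        nnmod.Dense(fusion.input_dim, fusion.hidden_width, rng=rng),
        nnmod.ReLU(),
        nnmod.Dense(fusion.hidden_width, 2, rng=rng),
    ])
    fusion.classes_ = classes
    load_into(fusion.net_, "fusion")
    pipe.fusion_model_ = fusion
    pipe.classes_ = classes
    pipe.n_features_fusion_ = sidecar["n_features_fusion"]
    return pipe
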