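"""Two-stage training: per-view convergence, determinism, stage isolation,
oracle fusion and the clinical-effect mechanism on tabular data."""

import numpy as np
import pytest

from thermofusion import (
    ClinicalEncoder,
    ClinicalNetClassifier,
    MultiViewFusionClassifier,
    SyntheticConfig,
    TrainConfig,
    ViewCNNClassifier,
    cohort_arrays,
    generate_clinical,
    generate_cohort,
    train_clinical_ann,
    train_fusion,
    train_view_model,
)

VIEWS = ("front", "left90", "right90")


def _separable_images(n=16, side=16, seed=0):
    """Two classes separated by a bright central blob."""
    rng = np.random.default_rng(seed)
    X = rng.normal(33.0, 0.05, size=(n, side, side))
    y = np.array([0, 1] * (n // 2))
    X[y == 1, 6:10, 6:10] += 3.0
    return X, y


def _encoded_clinical(effect, n_per_class, seed):
    config = SyntheticConfig(clinical_effect=effect, seed=seed)
    rng = np.random.default_rng(seed)
    records = [
        generate_clinical(config, d, rng=rng, patient_id=f"P{i}")
        for i, d in enumerate(["healthy"] * n_per_class + ["sick"] * n_per_class)
    ]
    enc = ClinicalEncoder().fit(records)
    X = enc.transform(records)
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


class TestTrainViewModel:
    def test_loss_decreases_on_separable_data(self):
        X, y = _separable_images()
        model, history = train_view_model(
            ViewCNNClassifier(conv_channels=(4, 8), input_side=16, max_epochs=20,
                              learning_rate=1e-2), X, y)
        assert history[-1] < history[0]

    def test_zero_learning_rate_freezes_loss(self):
        X, y = _separable_images()
        _, history = train_view_model(
            ViewCNNClassifier(conv_channels=(4,), input_side=16, max_epochs=5,
                              learning_rate=0.0, early_stop_patience=100), X, y)
        np.testing.assert_allclose(history, history[0], atol=1e-9)

    def test_same_seed_reproduces_history_and_weights(self):
        X, y = _separable_images()
        runs = []
        for _ in range(2):
            model, history = train_view_model(
                ViewCNNClassifier(conv_channels=(4, 8), input_side=16,
                                  max_epochs=4, random_state=7), X, y)
            runs.append((history, model.net_.copy_params()))
        assert runs[0][0] == runs[1][0]
        for a, b in zip(runs[0][1], runs[1][1]):
            np.testing.assert_array_equal(a, b)

    def test_single_class_data_rejected(self):
        X, _ = _separable_images()
        with pytest.raises(ValueError, match="two classes"):
            ViewCNNClassifier(conv_channels=(4,), input_side=16).fit(X, np.zeros(len(X)))


class TestTrainClinicalANN:
    def test_null_effect_accuracy_near_chance_over_seeds(self):
        correct = total = 0
        for seed in range(5):
            X, y = _encoded_clinical(effect=0.0, n_per_class=60, seed=seed)
            tr = np.r_[0:40, 60:100]
            te = np.r_[40:60, 100:120]
            model, _ = train_clinical_ann(
                ClinicalNetClassifier(max_epochs=80, random_state=seed), X[tr], y[tr])
            correct += (model.predict(X[te]) == y[te]).sum()
            total += len(te)
        # pooled accuracy within 3.3 binomial SDs of 0.5
        assert abs(correct / total - 0.5) < 3.3 * np.sqrt(0.25 / total)

    def test_strong_effect_learned_over_seeds(self):
        accs = []
        for seed in range(5):
            X, y = _encoded_clinical(effect=0.75, n_per_class=60, seed=seed)
            tr = np.r_[0:40, 60:100]
            te = np.r_[40:60, 100:120]
            model, _ = train_clinical_ann(
                ClinicalNetClassifier(max_epochs=300, random_state=seed), X[tr], y[tr])
            accs.append((model.predict(X[te]) == y[te]).mean())
        assert np.mean(accs) > 0.8

    def test_agrees_with_independent_mlp_on_strong_effect(self):
        # cross-check against scikit-learn's MLP on the same design matrix
        from sklearn.neural_network import MLPClassifier

        X, y = _encoded_clinical(effect=0.75, n_per_class=60, seed=1)
        tr = np.r_[0:40, 60:100]
        te = np.r_[40:60, 100:120]
        ours, _ = train_clinical_ann(
            ClinicalNetClassifier(max_epochs=300, random_state=1), X[tr], y[tr])
        ref = MLPClassifier(hidden_layer_sizes=(32,), max_iter=2000,
                            random_state=1).fit(X[tr], y[tr])
        ours_acc = (ours.predict(X[te]) == y[te]).mean()
        ref_acc = (ref.predict(X[te]) == y[te]).mean()
        assert abs(ours_acc - ref_acc) < 0.15

    def test_zero_learning_rate_freezes_loss(self):
        X, y = _encoded_clinical(effect=0.5, n_per_class=10, seed=0)
        _, history = train_clinical_ann(
            ClinicalNetClassifier(max_epochs=5, learning_rate=0.0,
                                  early_stop_patience=100), X, y)
        np.testing.assert_allclose(history, history[0], atol=1e-9)


class _OracleViewModel:
    """Hand-built component that reads the class straight off the image."""

    def __init__(self, input_side=16):
        self.input_side = input_side
        self.net_ = object()  # satisfies the fitted check
        self.classes_ = np.array([0, 1])

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        hot = X[:, 6:10, 6:10].mean(axis=(1, 2)) > X.mean(axis=(1, 2)) + 1.0
        return np.column_stack([1.0 - hot, hot.astype(float)])


class TestTrainFusion:
    def _cohort(self, seed=0, n=24):
        X, y = _separable_images(n=n, side=16, seed=seed)
        return {"images": {v: X for v in VIEWS}}, y

    def test_oracle_components_give_perfect_fusion(self):
        X, y = self._cohort()
        oracle = {v: _OracleViewModel() for v in VIEWS}
        pipeline = train_fusion(oracle, None, X, y,
                                TrainConfig(fusion_max_epochs=400, learning_rate=0.05))
        fused = pipeline.fusion_model
        probs = np.hstack([oracle[v].predict_proba(X["images"][v]) for v in VIEWS])
        # fusion input layout: front, right90, left90
        ordered = np.hstack([
            oracle["front"].predict_proba(X["images"]["front"]),
            oracle["right90"].predict_proba(X["images"]["right90"]),
            oracle["left90"].predict_proba(X["images"]["left90"]),
        ])
        assert (fused.predict(ordered) == y).mean() == 1.0

    def test_fusion_width_without_clinical(self):
        X, y = self._cohort()
        pipeline = train_fusion({v: _OracleViewModel() for v in VIEWS}, None, X, y,
                                TrainConfig(fusion_max_epochs=5))
        assert pipeline.fusion_model.input_dim == 6

    def test_missing_view_rejected(self):
        X, y = self._cohort()
        del X["images"]["front"]
        with pytest.raises(ValueError, match="front"):
            train_fusion({v: _OracleViewModel() for v in VIEWS}, None, X, y)


@pytest.fixture(scope="module")
def fitted_pipeline(small_cohort):
    config, studies, records = small_cohort
    images, y, ids = cohort_arrays(studies, VIEWS)
    clin = {r.patient_id: r for r in records}
    enc = ClinicalEncoder().fit([clin[p] for p in ids])
    X = {"images": images, "clinical": enc.transform([clin[p] for p in ids])}
    pipe = MultiViewFusionClassifier(
        views=VIEWS, input_side=32, use_clinical=True,
        train_config=TrainConfig(seed=5, max_epochs_per_view=5,
                                 clinical_max_epochs=30, fusion_max_epochs=30),
        random_state=5,
    )
    pipe.fit(X, y)
    return pipe, X, y


class TestPipeline:
    def test_fusion_training_leaves_components_frozen(self, small_cohort):
        config, studies, records = small_cohort
        images, y, ids = cohort_arrays(studies, VIEWS)
        X = {"images": images}
        cfg = TrainConfig(seed=2, max_epochs_per_view=3, fusion_max_epochs=10)
        models = {}
        for v in VIEWS:
            m = ViewCNNClassifier(conv_channels=(8, 16), input_side=32,
                                  max_epochs=3, random_state=2)
            m.fit(images[v], y)
            models[v] = m
        before = {v: m.net_.copy_params() for v, m in models.items()}
        train_fusion(models, None, X, y, cfg)
        for v, m in models.items():
            for a, b in zip(before[v], m.net_.copy_params()):
                np.testing.assert_array_equal(a, b)

    def test_fusion_input_width_with_clinical(self, fitted_pipeline):
        pipe, X, y = fitted_pipeline
        assert pipe.n_features_fusion_ == 2 * len(VIEWS) + 1

    def test_predict_is_deterministic(self, fitted_pipeline):
        pipe, X, y = fitted_pipeline
        one = {"images": {v: X["images"][v][:1] for v in VIEWS},
               "clinical": X["clinical"][:1]}
        a = pipe.predict_detailed(one)[0]
        b = pipe.predict_detailed(one)[0]
        np.testing.assert_array_equal(a["fusion_input"].values, b["fusion_input"].values)
        assert a["prediction"] == b["prediction"]

    def test_detailed_prediction_exposes_intermediates(self, fitted_pipeline):
        pipe, X, y = fitted_pipeline
        detail = pipe.predict_detailed(
            {"images": {v: X["images"][v][:1] for v in VIEWS},
             "clinical": X["clinical"][:1]})[0]
        assert set(detail["view_predictions"]) == set(VIEWS)
        assert len(detail["fusion_input"].values) == 7
        assert detail["prediction"] in (0, 1)

    def test_missing_clinical_at_predict_rejected(self, fitted_pipeline):
        pipe, X, y = fitted_pipeline
        with pytest.raises(ValueError, match="clinical"):
            pipe.predict({"images": X["images"]})

    def test_missing_view_at_predict_rejected(self, fitted_pipeline):
        pipe, X, y = fitted_pipeline
        partial = {"images": {v: X["images"][v] for v in VIEWS[:2]},
                   "clinical": X["clinical"]}
        with pytest.raises(ValueError, match="right90"):
            pipe.predict(partial)

    def test_missing_clinical_at_fit_rejected(self, small_cohort):
        _, studies, _ = small_cohort
        images, y, _ = cohort_arrays(studies, VIEWS)
        pipe = MultiViewFusionClassifier(views=VIEWS, input_side=32, use_clinical=True)
        with pytest.raises(ValueError, match="clinical"):
            pipe.fit({"images": images}, y)
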