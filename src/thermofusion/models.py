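"""Per-view CNN classifiers, the clinical network, and fusion assembly.

Two reference architectures are provided. Model 1 uses one stack of
stride-2 convolutions with channel widths 32/64/128 for every view; Model
2 uses 45/90/135/180 for the lateral views and 50/100/150/200 for the
front view. Each conv block is convolution (3x3, stride 2, padding 1) →
ReLU → 2x2 max pooling, followed by a flatten, one hidden dense layer and
a 2-unit softmax output, so every view model emits a probability pair
(P(healthy), P(sick)). The clinical network is a small MLP with a sigmoid
output thresholded at 0.5; its binary decision (or, optionally, the raw
probability) is appended to the concatenated per-view pairs to form the
fusion input — a 10-element tuple for five views, 11 with the clinical
contribution.

All estimators follow the scikit-learn fit/predict contract with seeded,
fully deterministic training.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .synthetic import VIEW_LABELS, VIEW_ORDER

MODEL1_CHANNELS = (32, 64, 128)
MODEL2_LATERAL_CHANNELS = (45, 90, 135, 180)
MODEL2_FRONTAL_CHANNELS = (50, 100, 150, 200)

DEFAULT_VIEWS = ("front", "left90", "right90")


@dataclass
class ViewCNNSpec:
    """Architecture of one per-view CNN."""

    view_label: str
    conv_channels: tuple[int, ...]
    conv_stride: int = 2
    pool_size: tuple[int, int] = (2, 2)
    input_side: int = 640
    kernel_size: int = 3
    hidden_width: int = 64
    output_dim: int = 2  # probability pair (P(healthy), P(sick))

    def __post_init__(self) -> None:
        if self.view_label not in VIEW_LABELS:
            raise ValueError(f"view_label must be one of {VIEW_LABELS}, got {self.view_label!r}")
        if not self.conv_channels:
            raise ValueError("conv_channels must be non-empty")
        if self.output_dim != 2:
            raise ValueError("view models emit a 2-element probability pair")


@dataclass
class ClinicalANNSpec:
    input_dim: int
    hidden_widths: tuple[int, ...] = (32,)
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")


@dataclass
class ViewPrediction:
    """Probability pair for one view; must sum to one."""

    p_healthy: float
    p_sick: float

    def __post_init__(self) -> None:
        for name, p in (("p_healthy", self.p_healthy), ("p_sick", self.p_sick)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if abs(self.p_healthy + self.p_sick - 1.0) > 1e-6:
            raise ValueError(
                f"probabilities must sum to 1, got {self.p_healthy + self.p_sick}"
            )


@dataclass
class FusionInput:
    """Concatenated per-view probability pairs, optionally ending with the
    clinical contribution; ``provenance`` records the layout."""

    values: np.ndarray
    provenance: list[tuple[str, str] | str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.provenance):
            raise ValueError("values and provenance must have equal length")


def trace_spatial(side: int, n_blocks: int, *, kernel: int = 3, stride: int = 2,
                  pad: int = 1, pool: int = 2) -> list[int]:
    """Spatial side after each conv+pool block; raises if it collapses to 0,
    naming the offending block depth."""
    sides = [side]
    s = side
    for depth in range(1, n_blocks + 1):
        s = (s + 2 * pad - kernel) // stride + 1
        s = s // pool
        sides.append(s)
        if s < 1:
            raise ValueError(
                f"input side {side} collapses to 0 at conv block {depth} "
                f"of {n_blocks}; use a larger input or fewer blocks"
            )
    return sides


def adjust_channels_for_side(conv_channels: tuple[int, ...], side: int,
                             ) -> tuple[int, ...]:
    """Trim trailing conv blocks until the spatial trace stays positive."""
    channels = tuple(conv_channels)
    while channels:
        try:
            trace_spatial(side, len(channels))
            return channels
        except ValueError:
            channels = channels[:-1]
    raise ValueError(f"input side {side} is too small for any conv block")


def count_cnn_params(spec: ViewCNNSpec) -> int:
    """Closed-form parameter count for a :class:`ViewCNNSpec`."""
    k = spec.kernel_size
    total, in_ch = 0, 1
    for out_ch in spec.conv_channels:
        total += k * k * in_ch * out_ch + out_ch
        in_ch = out_ch
    final_side = trace_spatial(spec.input_side, len(spec.conv_channels),
                               kernel=k, stride=spec.conv_stride,
                               pool=spec.pool_size[0])[-1]
    flat = in_ch * final_side * final_side
    total += flat * spec.hidden_width + spec.hidden_width
    total += spec.hidden_width * spec.output_dim + spec.output_dim
    return total


class _TrainerMixin:
    """Shared deterministic mini-batch training loop with early stopping."""

    def _train(self, net: nn.Network, X: np.ndarray, y: np.ndarray,
               loss_fn, *, rng: np.random.Generator) -> list[float]:
        opt = nn.make_optimizer(self.optimizer, net.params, net.grads,
                                self.learning_rate)
        history: list[float] = []
        best = np.inf
        stale = 0
        n = X.shape[0]
        for _ in range(self.max_epochs):
            order = rng.permutation(n)
            total_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits = net.forward(X[idx])
                loss, dlogits = loss_fn(logits, y[idx])
                net.backward(dlogits)
                opt.step()
                total_loss += loss * len(idx)
            epoch_loss = total_loss / n
            history.append(epoch_loss)
            if epoch_loss < best - self.tol:
                best = epoch_loss
                stale = 0
            else:
                stale += 1
                if stale >= self.early_stop_patience:
                    break
        return history


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(
            f"training data must contain exactly two classes, got {classes.tolist()}"
        )
    return classes


class ViewCNNClassifier(_TrainerMixin, ClassifierMixin, BaseEstimator):
    """CNN classifier for a single thermogram view.

    Input ``X`` has shape ``(n, side, side)`` (temperatures in °C); each
    image is min–max normalized to [0, 1] before entering the network.
    ``predict_proba`` returns softmax pairs ordered as ``classes_``.
    """

    def __init__(self, conv_channels: tuple[int, ...] = MODEL1_CHANNELS,
                 input_side: int = 64, kernel_size: int = 3, conv_stride: int = 2,
                 pool_size: int = 2, hidden_width: int = 64,
                 optimizer: str = "sgd", learning_rate: float = 1e-3,
                 batch_size: int = 8, max_epochs: int = 30,
                 early_stop_patience: int = 5, tol: float = 1e-4,
                 random_state: int = 0) -> None:
        self.conv_channels = conv_channels
        self.input_side = input_side
        self.kernel_size = kernel_size
        self.conv_stride = conv_stride
        self.pool_size = pool_size
        self.hidden_width = hidden_width
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.tol = tol
        self.random_state = random_state

    def _build(self, rng: np.random.Generator) -> nn.Network:
        trace_spatial(self.input_side, len(self.conv_channels),
                      kernel=self.kernel_size, stride=self.conv_stride,
                      pool=self.pool_size)
        layers: list[nn.Layer] = []
        in_ch = 1
        side = self.input_side
        for out_ch in self.conv_channels:
            conv = nn.Conv2D(in_ch, out_ch, kernel_size=self.kernel_size,
                             stride=self.conv_stride, padding=1, rng=rng)
            pool = nn.MaxPool2D(self.pool_size)
            layers += [conv, nn.ReLU(), pool]
            side = pool.out_spatial(conv.out_spatial(side))
            in_ch = out_ch
        layers.append(nn.Flatten())
        flat = in_ch * side * side
        layers += [nn.Dense(flat, self.hidden_width, rng=rng), nn.ReLU(),
                   nn.Dense(self.hidden_width, 2, rng=rng)]
        return nn.Network(layers)

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != self.input_side or X.shape[2] != self.input_side:
            raise ValueError(
                f"expected images of shape (n, {self.input_side}, {self.input_side}), "
                f"got {X.shape}"
            )
        lo = X.min(axis=(1, 2), keepdims=True)
        hi = X.max(axis=(1, 2), keepdims=True)
        scale = np.where(hi > lo, hi - lo, 1.0)
        return ((X - lo) / scale)[:, None, :, :]  # add channel axis

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ViewCNNClassifier":
        Xp = self._prepare(X)
        y = np.asarray(y)
        self.classes_ = _check_two_classes(y)
        y_idx = np.searchsorted(self.classes_, y)
        rng = np.random.default_rng(self.random_state)
        self.net_ = self._build(rng)
        self.n_params_ = self.net_.n_params()
        self.loss_history_ = self._train(self.net_, Xp, y_idx,
                                         nn.softmax_cross_entropy, rng=rng)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "net_")
        return nn.softmax(self.net_.forward(self._prepare(X)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def view_predictions(self, X: np.ndarray) -> list[ViewPrediction]:
        """Probability pairs in (P(healthy), P(sick)) order; assumes labels
        sort healthy before sick (0/1 or alphabetical strings)."""
        proba = self.predict_proba(X)
        return [ViewPrediction(p_healthy=float(p[0]), p_sick=float(p[1])) for p in proba]


def build_view_cnn(spec: ViewCNNSpec, *, learning_rate: float = 1e-3,
                   optimizer: str = "sgd", batch_size: int = 8,
                   max_epochs: int = 30, random_state: int = 0) -> ViewCNNClassifier:
    """Instantiate (and spatially validate) a view CNN from its spec."""
    clf = ViewCNNClassifier(
        conv_channels=tuple(spec.conv_channels),
        input_side=spec.input_side,
        kernel_size=spec.kernel_size,
        conv_stride=spec.conv_stride,
        pool_size=spec.pool_size[0],
        hidden_width=spec.hidden_width,
        optimizer=optimizer,
        learning_rate=learning_rate,
        batch_size=batch_size,
        max_epochs=max_epochs,
        random_state=random_state,
    )
    trace_spatial(spec.input_side, len(spec.conv_channels),
                  kernel=spec.kernel_size, stride=spec.conv_stride,
                  pool=spec.pool_size[0])
    return clf


def model1_spec(view_label: str, input_side: int = 640) -> ViewCNNSpec:
    """Model 1: identical 32/64/128 conv stack for every view."""
    return ViewCNNSpec(view_label=view_label, conv_channels=MODEL1_CHANNELS,
                       input_side=input_side)


def model2_spec(view_label: str, input_side: int = 640) -> ViewCNNSpec:
    """Model 2: 50/100/150/200 channels for the front view, 45/90/135/180
    for the lateral views."""
    channels = MODEL2_FRONTAL_CHANNELS if view_label == "front" else MODEL2_LATERAL_CHANNELS
    return ViewCNNSpec(view_label=view_label, conv_channels=channels,
                       input_side=input_side)


class ClinicalNetClassifier(_TrainerMixin, ClassifierMixin, BaseEstimator):
    """MLP on the encoded clinical features with a sigmoid output in [0, 1]
    thresholded at 0.5 (ties classify as sick)."""

    def __init__(self, hidden_widths: tuple[int, ...] = (32,), threshold: float = 0.5,
                 optimizer: str = "sgd", learning_rate: float = 1e-3,
                 batch_size: int = 8, max_epochs: int = 200,
                 early_stop_patience: int = 10, tol: float = 1e-4,
                 random_state: int = 0) -> None:
        self.hidden_widths = hidden_widths
        self.threshold = threshold
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.tol = tol
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClinicalNetClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = _check_two_classes(y)
        y01 = np.searchsorted(self.classes_, y).astype(float)
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        layers: list[nn.Layer] = []
        in_dim = X.shape[1]
        for width in self.hidden_widths:
            layers += [nn.Dense(in_dim, width, rng=rng), nn.ReLU()]
            in_dim = width
        layers.append(nn.Dense(in_dim, 1, rng=rng))
        self.net_ = nn.Network(layers)

        def bce(logits, target):
            return nn.binary_cross_entropy(logits[:, 0], target)

        def bce_wrapped(logits, target):
            loss, d = bce(logits, target)
            return loss, d[:, None]

        self.loss_history_ = self._train(self.net_, X, y01, bce_wrapped, rng=rng)
        return self

    def _check_width(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"clinical network expects {self.n_features_in_} features, "
                f"got input of shape {X.shape}"
            )
        return X

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid outputs in [0, 1] (probability of the positive class)."""
        check_is_fitted(self, "net_")
        return nn.sigmoid(self.net_.forward(self._check_width(X))[:, 0])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = self.predict_score(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        decisions = np.array(
            [clinical_decision(p, self.threshold) for p in self.predict_score(X)]
        )
        return self.classes_[decisions]


def build_clinical_ann(spec: ClinicalANNSpec, *, learning_rate: float = 1e-3,
                       optimizer: str = "sgd", random_state: int = 0,
                       ) -> ClinicalNetClassifier:
    return ClinicalNetClassifier(
        hidden_widths=tuple(spec.hidden_widths), threshold=spec.threshold,
        learning_rate=learning_rate, optimizer=optimizer, random_state=random_state,
    )


def clinical_decision(p: float, threshold: float = 0.5) -> int:
    """Threshold rule: below → healthy (0), above → sick (1); the boundary
    case classifies as sick."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    return 0 if p < threshold else 1


def assemble_fusion_input(preds, clinical: float | int | None = None) -> FusionInput:
    """Concatenate per-view probability pairs in the fixed fusion order
    (front, right45, left45, right90, left90), appending the clinical
    contribution last if provided.

    ``preds`` is a mapping view → :class:`ViewPrediction` or an iterable of
    (view, prediction) pairs; duplicate views are rejected.
    """
    if hasattr(preds, "items"):
        items = list(preds.items())
    else:
        items = list(preds)
    seen: dict[str, ViewPrediction] = {}
    for view, pred in items:
        if view not in VIEW_LABELS:
            raise ValueError(f"unknown view label {view!r}")
        if view in seen:
            raise ValueError(f"duplicate view label {view!r}")
        seen[view] = pred
    if not seen:
        raise ValueError("at least one view prediction is required")

    values: list[float] = []
    provenance: list[tuple[str, str] | str] = []
    for view in VIEW_ORDER:
        if view not in seen:
            continue
        pred = seen[view]
        values += [pred.p_healthy, pred.p_sick]
        provenance += [(view, "p_healthy"), (view, "p_sick")]
    if clinical is not None:
        values.append(float(clinical))
        provenance.append("clinical_decision")
    return FusionInput(values=np.asarray(values), provenance=provenance)


def disassemble_fusion_input(fusion: FusionInput
                             ) -> tuple[dict[str, ViewPrediction], float | None]:
    """Invert :func:`assemble_fusion_input` using the recorded provenance."""
    preds: dict[str, dict[str, float]] = {}
    clinical = None
    for value, tag in zip(fusion.values, fusion.provenance):
        if tag == "clinical_decision":
            clinical = float(value)
        else:
            view, component = tag
            preds.setdefault(view, {})[component] = float(value)
    return (
        {view: ViewPrediction(**pair) for view, pair in preds.items()},
        clinical,
    )


class FusionClassifier(_TrainerMixin, ClassifierMixin, BaseEstimator):
    """Final network over assembled fusion vectors (2-way softmax)."""

    def __init__(self, input_dim: int = 10, hidden_width: int = 16,
                 optimizer: str = "sgd", learning_rate: float = 1e-3,
                 batch_size: int = 8, max_epochs: int = 300,
                 early_stop_patience: int = 10, tol: float = 1e-4,
                 random_state: int = 0) -> None:
        self.input_dim = input_dim
        self.hidden_width = hidden_width
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.tol = tol
        self.random_state = random_state

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(
                f"fusion network expects vectors of length {self.input_dim}, "
                f"got input of shape {X.shape}"
            )
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FusionClassifier":
        X = self._check(X)
        y = np.asarray(y)
        self.classes_ = _check_two_classes(y)
        y_idx = np.searchsorted(self.classes_, y)
        rng = np.random.default_rng(self.random_state)
        self.net_ = nn.Network([
            nn.Dense(self.input_dim, self.hidden_width, rng=rng),
            nn.ReLU(),
            nn.Dense(self.hidden_width, 2, rng=rng),
        ])
        self.loss_history_ = self._train(self.net_, X, y_idx,
                                         nn.softmax_cross_entropy, rng=rng)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "net_")
        return nn.softmax(self.net_.forward(self._check(X)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def build_fusion_net(input_dim: int, **kwargs) -> FusionClassifier:
    if input_dim < 2:
        raise ValueError(f"fusion input dimension must be >= 2, got {input_dim}")
    return FusionClassifier(input_dim=input_dim, **kwargs)


def spec_to_dict(spec) -> dict:
    return dataclasses.asdict(spec)
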