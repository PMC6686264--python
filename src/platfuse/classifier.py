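"""Six-layer feed-forward classifier and its raw/feature-selected baselines.

The supervised stage is a fully-connected network with layer widths
x, 1024, 512, 256, 128, 2 (x = input feature width): four hidden layers each
as dense -> batch-norm -> ReLU, and a 2-unit softmax output trained with
categorical cross-entropy on one-hot labels, mini-batch size 32. Batch
normalization regularizes the hidden layers; dropout is deliberately not
combined with it.

Baselines: ``raw`` trains the same network directly on gene expression;
``fs`` first keeps genes whose two-sample Welch t-test p-value against the
endpoint is below a threshold (default 0.05), fitted on training data only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import stats

from . import nn
from .io_data import EndpointLabels, ExpressionMatrix

DEFAULT_HIDDEN_SIZES = (1024, 512, 256, 128)


@dataclass
class ClassifierSpec:
    input_dim: int
    hidden_sizes: tuple[int, ...] = DEFAULT_HIDDEN_SIZES
    output_dim: int = 2
    batch_norm: bool = True
    dropout_rate: float = 0.0
    batch_size: int = 32
    epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        self.hidden_sizes = tuple(int(s) for s in self.hidden_sizes)
        if self.input_dim <= 0 or any(s <= 0 for s in self.hidden_sizes):
            raise ValueError("all layer sizes must be positive")
        if self.output_dim != 2:
            raise ValueError("only binary (2-unit softmax) endpoints are supported")
        if self.batch_norm and self.dropout_rate > 0:
            raise ValueError("dropout must stay off when batch normalization is on")

    @property
    def layer_widths(self) -> list[int]:
        return [self.input_dim, *self.hidden_sizes, self.output_dim]

    def scaled(self, scale: float) -> "ClassifierSpec":
        spec = asdict(self)
        spec["hidden_sizes"] = tuple(max(1, round(s * scale)) for s in self.hidden_sizes)
        return ClassifierSpec(**spec)


@dataclass
class TrainedClassifier:
    spec: ClassifierSpec
    model: nn.Sequential
    loss_trace: list[float] = field(default_factory=list)


@dataclass
class FeatureSelection:
    """t-test screen: columns with p < threshold, fitted on training data."""

    endpoint: str
    p_values: np.ndarray
    selected: np.ndarray
    threshold: float = 0.05


def _build_classifier(spec: ClassifierSpec, rng) -> nn.Sequential:
    layers: list[nn.Layer] = []
    prev = spec.input_dim
    for size in spec.hidden_sizes:
        layers.append(nn.Dense(prev, size, rng))
        if spec.batch_norm:
            layers.append(nn.BatchNorm(size))
        layers.append(nn.Relu())
        if spec.dropout_rate > 0:
            layers.append(nn.Dropout(spec.dropout_rate, rng))
        prev = size
    layers.append(nn.Dense(prev, spec.output_dim, rng))  # logits; softmax in the loss
    return nn.Sequential(layers)


def _validate_training_inputs(features: np.ndarray, labels: EndpointLabels) -> None:
    if features.shape[0] != len(labels.sample_ids):
        raise ValueError("feature rows must align with labels")
    if not np.isfinite(features).all():
        raise ValueError("features contain NaN/Inf")
    if len(np.unique(labels.labels)) < 2:
        raise ValueError(f"endpoint {labels.name!r} has a single class; cannot train")


def train_classifier(features: np.ndarray, labels: EndpointLabels,
                     spec: ClassifierSpec) -> TrainedClassifier:
    """Train the feed-forward classifier with mini-batch Adam.

    Labels are one-hot encoded for the categorical cross-entropy loss; the
    per-epoch mean loss is recorded so training progress is auditable.
    """
    features = np.asarray(features, dtype=float)
    _validate_training_inputs(features, labels)
    if features.shape[1] != spec.input_dim:
        raise ValueError(f"feature width {features.shape[1]} != spec input_dim {spec.input_dim}")
    onehot = np.eye(2)[labels.labels]
    rng = np.random.default_rng(spec.seed)
    model = _build_classifier(spec, rng)
    opt = nn.Adam(model.params(), lr=spec.learning_rate)
    n = features.shape[0]
    trace = []
    for _ in range(spec.epochs):
        total = 0.0
        for batch in nn.iterate_minibatches(n, spec.batch_size, rng):
            logits = model.forward(features[batch], training=True)
            loss, g = nn.softmax_cross_entropy(logits, onehot[batch])
            total += loss * len(batch)
            model.backward(g)
            opt.step(model.grads())
        trace.append(total / n)
    return TrainedClassifier(spec, model, trace)


def predict_proba(clf: TrainedClassifier, features: np.ndarray) -> np.ndarray:
    """n x 2 class probabilities; rows are nonnegative and sum to one."""
    features = np.asarray(features, dtype=float)
    if features.shape[1] != clf.spec.input_dim:
        raise ValueError(
            f"feature width {features.shape[1]} != spec input_dim {clf.spec.input_dim}"
        )
    return nn.softmax(clf.model.forward(features, training=False))


def select_features_ttest(features: np.ndarray, labels: EndpointLabels,
                          threshold: float = 0.05) -> FeatureSelection:
    """Per-column two-sided Welch t-test between the two classes.

    Columns with zero variance in both groups get p = 1 (never selected).
    Must be fitted on training data only; apply the returned column set to
    any later split.
    """
    features = np.asarray(features, dtype=float)
    _validate_training_inputs(features, labels)
    g0 = features[labels.labels == 0]
    g1 = features[labels.labels == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each class needs at least 2 samples for the t-test")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant columns trip scipy's precision warning; they get p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(g0, g1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    return FeatureSelection(labels.name, p, np.flatnonzero(p < threshold), threshold)


def run_baseline(kind: str, x: ExpressionMatrix, labels: EndpointLabels,
                 spec: ClassifierSpec,
                 threshold: float = 0.05) -> tuple[TrainedClassifier, FeatureSelection | None]:
    """Train a baseline on raw gene features.

    ``raw``: all genes enter the classifier. ``fs``: genes pass the t-test
    screen first; the downstream network is identical apart from its input
    width. Returns the selection so the caller can project test data through
    the same (training-derived) column set.
    """
    sub = x.subset_samples(labels.sample_ids)
    if kind == "raw":
        spec = ClassifierSpec(**{**asdict(spec), "input_dim": sub.n_genes})
        return train_classifier(sub.values, labels, spec), None
    if kind == "fs":
        sel = select_features_ttest(sub.values, labels, threshold)
        if len(sel.selected) == 0:
            raise ValueError(
                f"no gene passed p < {threshold} for endpoint {labels.name!r}; "
                "raise the threshold or use the raw baseline"
            )
        spec = ClassifierSpec(**{**asdict(spec), "input_dim": len(sel.selected)})
        return train_classifier(sub.values[:, sel.selected], labels, spec), sel
    raise ValueError(f"unknown baseline kind {kind!r} (expected 'raw' or 'fs')")
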