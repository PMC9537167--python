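"""CNN meta-classifier on prediction arrays, plus an MLP baseline.

The detector consumes ArrayDataset objects (200-slot arrays in one of the
declared 2D/3D shapes) and learns chemical-threat-likeness as a 2-class
softmax problem. 2D shapes are treated as single-channel images; for 3D
shapes the leading axis is the channel axis. The baseline MLP replaces
conv/pool with a dense layer so both nets have the same trainable depth
and training protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cholarray import _nn
from cholarray._nn import (
    ConfigurationError,
    Conv2D,
    Dense,
    Flatten,
    MaxPool2D,
    ReLU,
    Sequential,
    TrainingTrace,
    fit,
)
from cholarray.meta_array import ArrayDataset
from cholarray.metrics import (
    EvalReport,
    confusion_metrics,
    counts_from_predictions,
    evaluate_scores,
    pr_curve_aupr,
)

__all__ = [
    "CNNConfig",
    "build_cnn",
    "build_mlp_baseline",
    "train",
    "evaluate_detector",
    "DetectorReport",
    "dataset_tensors",
    "split_dataset",
]


@dataclass(frozen=True)
class CNNConfig:
    input_shape: tuple[int, ...] = (50, 4)
    conv_filters: int = 32
    kernel: tuple[int, int] = (3, 3)
    pool: tuple[int, int] = (2, 2)
    dense_width: int = 64
    max_epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 0.01
    patience: int = 10
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(self.input_shape)
        if len(shape) not in (2, 3) or any(d <= 0 for d in shape):
            raise ConfigurationError(
                f"input_shape must be a positive 2D or 3D shape, got {shape}"
            )

    @property
    def chw(self) -> tuple[int, int, int]:
        """(channels, height, width) view of the input shape."""
        s = tuple(self.input_shape)
        return (1, *s) if len(s) == 2 else s


def build_cnn(config: CNNConfig) -> Sequential:
    """conv(same, ReLU) -> maxpool -> flatten -> dense(ReLU) -> dense(2).

    Raises ConfigurationError when kernel or pool sizes are incompatible
    with the input shape.
    """
    c, h, w = config.chw
    rng = np.random.default_rng(config.seed)
    ph, pw = config.pool
    if ph > h or pw > w:
        raise ConfigurationError(
            f"pool {config.pool} incompatible with feature map ({h}, {w})"
        )
    oh, ow = h // ph, w // pw
    return Sequential(
        [
            Conv2D(c, config.conv_filters, config.kernel, rng),
            ReLU(),
            MaxPool2D(config.pool),
            Flatten(),
            Dense(oh * ow * config.conv_filters, config.dense_width, rng),
            ReLU(),
            Dense(config.dense_width, 2, rng, scale="xavier"),
        ]
    )


def build_mlp_baseline(config: CNNConfig) -> Sequential:
    """Dense network with the same trainable-layer count as the CNN.

    The conv layer is replaced by a dense layer of the same width as the
    hidden dense layer; pooling has no dense counterpart (it is not
    trainable). Input is the flattened 200-slot vector.
    """
    c, h, w = config.chw
    n_in = c * h * w
    rng = np.random.default_rng(config.seed)
    return Sequential(
        [
            Flatten(),
            Dense(n_in, config.dense_width, rng),
            ReLU(),
            Dense(config.dense_width, config.dense_width, rng),
            ReLU(),
            Dense(config.dense_width, 2, rng, scale="xavier"),
        ]
    )


def dataset_tensors(
    data: ArrayDataset, shape: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """(N, C, H, W) tensor and 0/1 labels (1 = CWA) for a dataset."""
    shape = tuple(shape)
    matrix = data.matrix
    if int(np.prod(shape)) != matrix.shape[1]:
        raise ConfigurationError(
            f"shape {shape} does not hold {matrix.shape[1]} slots"
        )
    X = matrix.reshape(-1, *shape)
    if len(shape) == 2:
        X = X[:, None, :, :]
    return X.astype(float), data.y.astype(int)


def split_dataset(
    data: ArrayDataset, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified index split; returns (first, second) index arrays."""
    rng = np.random.default_rng(seed)
    y = data.y
    first: list[int] = []
    second: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        cut = int(round(fraction * len(idx)))
        first.extend(idx[:cut])
        second.extend(idx[cut:])
    return np.sort(np.asarray(first)), np.sort(np.asarray(second))


def train(
    model: Sequential, data: ArrayDataset, config: CNNConfig
) -> tuple[Sequential, TrainingTrace]:
    """Train on an ArrayDataset with early stopping on validation loss.

    A stratified ``val_fraction`` of the data is held aside to drive the
    early-stopping callback; best weights are restored.
    """
    X, y = dataset_tensors(data, tuple(config.input_shape))
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for training")
    val_idx, fit_idx = split_dataset(data, config.val_fraction, config.seed)
    trace = fit(
        model,
        X[fit_idx],
        y[fit_idx],
        X[val_idx],
        y[val_idx],
        max_epochs=config.max_epochs,
        batch_size=config.batch_size,
        lr=config.learning_rate,
        patience=config.patience,
        seed=config.seed,
    )
    return model, trace


@dataclass
class DetectorReport:
    """Held-out evaluation of the detector: overall + per-class views."""

    overall: EvalReport
    f1_cwa: float | None
    f1_noncwa: float | None
    pr_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def as_dict(self) -> dict:
        d = self.overall.as_dict()
        d["f1_cwa"] = self.f1_cwa
        d["f1_noncwa"] = self.f1_noncwa
        return d


def predict_scores(
    model: Sequential, data: ArrayDataset, shape: tuple[int, ...]
) -> np.ndarray:
    """P(CWA) for every array in the dataset."""
    X, _ = dataset_tensors(data, shape)
    return model.predict_proba(X)[:, 1]


def evaluate_detector(
    model: Sequential, data: ArrayDataset, shape: tuple[int, ...]
) -> DetectorReport:
    """Full held-out report: per-class F1, MCC, ACC, AUPR, PR curve.

    Ranking metrics are undefined (None, flagged) on a single-class set.
    """
    scores = predict_scores(model, data, tuple(shape))
    y = data.y
    overall = evaluate_scores(scores, y)
    pred = (scores >= 0.5).astype(int)
    f1_cwa = overall.f1
    # nonCWA-as-positive view
    neg_counts = counts_from_predictions(1 - y, 1 - pred)
    f1_noncwa = confusion_metrics(neg_counts).f1
    points, _ = pr_curve_aupr(scores, y)
    return DetectorReport(
        overall=overall,
        f1_cwa=f1_cwa,
        f1_noncwa=f1_noncwa,
        pr_points=points,
    )


def batch_loss(model: Sequential, data: ArrayDataset, shape) -> float:
    """Printed-formula loss of the model on a dataset (for invariants)."""
    X, y = dataset_tensors(data, tuple(shape))
    loss, _ = _nn.softmax_ce(model.forward(X), y)
    return loss
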