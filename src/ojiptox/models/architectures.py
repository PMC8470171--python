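"""The three neural classifier architectures and their training defaults.

Layer censuses are fixed by design and asserted in tests:

* dense network (ANN): 4 batch-norm, 6 fully connected, 5 dropout at rate 0.7;
* 1D convolutional net: 4 batch-norm, 3 interspersed conv + max-pool pairs,
  2 fully connected;
* 2D convolutional net: 5 interspersed conv + max-pool pairs, 3 fully
  connected with 2 dropouts in between.

Filter counts, dense widths, kernel sizes and batch size are not pinned by
the census and are exposed as arguments (defaults: 3 / 3x3 kernels, pool 2,
filters doubling from 16, dense widths halving, batch 32).  Training uses
Adam at learning rate 0.001 with Glorot initialization and no validation
split.
"""

from __future__ import annotations

import numpy as np

from .base import FittedModel, ModelSpec
from .nn import (
    BatchNorm,
    Conv1D,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool1D,
    MaxPool2D,
    ReLU,
    Sequential,
)

__all__ = ["build_ann", "build_cnn1d", "build_cnn2d", "train_nn", "default_epochs"]

ANN_DROPOUT = 0.7

# Epochs per (family, task): image nets run 300 epochs on the contaminant
# task and 100 on the concentration task; the dense and 1D nets run 500 on
# both.
DEFAULT_EPOCHS = {
    ("cnn2d", "contaminant"): 300,
    ("cnn2d", "concentration"): 100,
    ("ann", "contaminant"): 500,
    ("ann", "concentration"): 500,
    ("cnn1d", "contaminant"): 500,
    ("cnn1d", "concentration"): 500,
}


def default_epochs(family: str, task_kind: str) -> int:
    try:
        return DEFAULT_EPOCHS[(family, task_kind)]
    except KeyError:
        raise ValueError(f"no epoch default for {family!r} on {task_kind!r} task")


def build_ann(
    input_len: int,
    n_classes: int,
    widths: tuple[int, ...] = (256, 128, 64, 32, 16),
    dropout: float = ANN_DROPOUT,
    seed: int = 0,
) -> Sequential:
    """Dense network: 4x(BN -> Dense -> ReLU -> Dropout), Dense -> ReLU ->
    Dropout, output Dense.  Census: 4 BN / 6 Dense / 5 Dropout."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if len(widths) != 5:
        raise ValueError("ANN takes exactly 5 hidden widths")
    layers = []
    for w in widths[:4]:
        layers += [BatchNorm(), Dense(w), ReLU(), Dropout(dropout)]
    layers += [Dense(widths[4]), ReLU(), Dropout(dropout), Dense(n_classes)]
    model = Sequential(layers)
    model.build((input_len,), seed=seed)
    return model


def build_cnn1d(
    input_len: int,
    n_classes: int,
    filters: tuple[int, int, int] = (16, 32, 64),
    kernel_size: int = 3,
    dense_width: int = 64,
    seed: int = 0,
) -> Sequential:
    """1D conv net: BN, 3x(Conv -> ReLU -> Pool -> BN), Flatten, Dense ->
    ReLU, output Dense.  Census: 4 BN / 3 Conv / 3 MaxPool / 2 Dense."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    layers: list = [BatchNorm()]
    for f in filters:
        layers += [Conv1D(f, kernel_size), ReLU(), MaxPool1D(2), BatchNorm()]
    layers += [Flatten(), Dense(dense_width), ReLU(), Dense(n_classes)]
    model = Sequential(layers)
    model.build((input_len, 1), seed=seed)
    return model


def build_cnn2d(
    image_hw: tuple[int, int],
    n_classes: int,
    filters: tuple[int, int, int, int, int] = (16, 32, 64, 128, 256),
    kernel_size: int = 3,
    dense_widths: tuple[int, int] = (128, 64),
    dropout: float = 0.5,
    seed: int = 0,
) -> Sequential:
    """2D conv net: 5x(Conv -> ReLU -> Pool), Flatten, Dense -> ReLU ->
    Dropout, Dense -> ReLU -> Dropout, output Dense.
    Census: 5 Conv / 5 MaxPool / 3 Dense / 2 Dropout."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    h, w = image_hw
    if h // 2**5 < 1 or w // 2**5 < 1:
        raise ValueError("image too small for five 2x pooling stages")
    layers: list = []
    for f in filters:
        layers += [Conv2D(f, kernel_size), ReLU(), MaxPool2D(2)]
    layers += [
        Flatten(),
        Dense(dense_widths[0]), ReLU(), Dropout(dropout),
        Dense(dense_widths[1]), ReLU(), Dropout(dropout),
        Dense(n_classes),
    ]
    model = Sequential(layers)
    model.build((h, w, 1), seed=seed)
    return model


class _ChannelAdapter:
    """Adds the trailing channel axis the convolutional stacks expect.

    The evaluation harness passes (N, L) series and (N, H, W) image stacks;
    Sequential wants an explicit single channel.
    """

    def __init__(self, model: Sequential) -> None:
        self.model = model

    @staticmethod
    def _expand(X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float)[..., None]

    def predict(self, X):
        return self.model.predict(self._expand(X))

    def score(self, X, y):
        return self.model.score(self._expand(X), y)


def train_nn(
    model: Sequential,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int,
    seed: int = 0,
    batch_size: int = 32,
    lr: float = 0.001,
    family: str = "ann",
) -> FittedModel:
    """Train with softmax cross-entropy; no early stopping, no validation split."""
    X = np.asarray(X, dtype=float)
    convolutional = family in ("cnn1d", "cnn2d")
    model.fit(
        X[..., None] if convolutional else X,
        y, epochs=epochs, batch_size=batch_size, lr=lr, seed=seed,
    )
    est = _ChannelAdapter(model) if convolutional else model
    spec = ModelSpec(
        family=family,
        hyperparameters={"batch_size": batch_size, "lr": lr},
        epochs=epochs,
        seed=seed,
    )
    return FittedModel(spec=spec, estimator=est, train_accuracy=est.score(X, y))
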