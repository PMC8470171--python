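"""Common classifier contract shared by all model families."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

FAMILIES = ("rf", "xgb", "rocket", "ann", "cnn1d", "cnn2d")
NEURAL_FAMILIES = ("ann", "cnn1d", "cnn2d")
REPRESENTATIONS = ("raw", "log", "vt", "minmax", "image_linear", "image_log")


@dataclass
class ModelSpec:
    """Declarative description of a classifier run.

    ``hyperparameters`` is family-specific (e.g. ``n_kernels`` for rocket,
    architecture widths for the neural families); ``epochs`` only applies to
    neural families and defaults per task when None.
    """

    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    epochs: int | None = None
    seed: int = 0
    input_representation: str = "raw"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.input_representation not in REPRESENTATIONS:
            raise ValueError(
                f"unknown representation {self.input_representation!r}"
            )
        if self.epochs is not None and self.epochs <= 0:
            raise ValueError("epochs must be > 0")


@dataclass
class FittedModel:
    """A trained classifier: the spec that produced it plus opaque state.

    ``estimator`` exposes fit/predict; predictions are class labels in the
    label space seen at fit time.
    """

    spec: ModelSpec
    estimator: Any
    train_accuracy: float
    best_params: dict[str, Any] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)


def check_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain at least 2 classes")
    return classes
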