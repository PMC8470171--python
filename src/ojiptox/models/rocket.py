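"""Random-convolution-kernel time-series transform with a ridge classifier.

A large bank of random 1D convolution kernels (random length, centered
normal weights, uniform bias, exponential-scale dilation, random padding) is
applied to every series; each kernel contributes two pooled features — the
proportion of positive values (PPV) of its convolution output and the output
maximum — and a cross-validated L2-regularized linear classifier is trained
on the resulting 2 x n_kernels feature matrix.  The transform is implemented
from scratch here; only the ridge head and feature standardization come from
scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import RidgeClassifierCV
from sklearn.preprocessing import StandardScaler

from .base import check_classes

__all__ = ["RocketKernel", "sample_kernels", "apply_kernel", "rocket_features",
           "RocketClassifier", "fit_rocket"]

KERNEL_LENGTHS = (7, 9, 11)


@dataclass(frozen=True)
class RocketKernel:
    """One random kernel: weights (mean-centered), bias, dilation, padding."""

    weights: np.ndarray
    bias: float
    dilation: int
    padding: int  # zero-padding added at each end (0 for "none")

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or len(w) < 1:
            raise ValueError("weights must be a 1D vector")
        if self.dilation < 1:
            raise ValueError("dilation must be >= 1")
        if self.padding < 0:
            raise ValueError("padding must be >= 0")

    @property
    def length(self) -> int:
        return len(self.weights)

    @property
    def span(self) -> int:
        """Receptive field length: (length - 1) * dilation + 1."""
        return (self.length - 1) * self.dilation + 1


def sample_kernels(n_kernels: int, series_len: int, seed) -> list[RocketKernel]:
    """Draw the kernel bank once; shared across all series.

    Law: length uniform on {7, 9, 11}; weights ~ N(0, 1) then mean-centered;
    bias ~ U(-1, 1); dilation = floor(2^x) with x ~ U(0, log2((L-1)/(l-1)))
    so the receptive field never exceeds the series; padding "same"
    (centered zero-padding) with probability 1/2, else none.
    """
    if n_kernels < 1:
        raise ValueError("n_kernels must be >= 1")
    if series_len < max(KERNEL_LENGTHS):
        raise ValueError(f"series_len must be >= {max(KERNEL_LENGTHS)}")
    rng = np.random.default_rng(seed)
    kernels = []
    for _ in range(n_kernels):
        length = int(rng.choice(KERNEL_LENGTHS))
        weights = rng.standard_normal(length)
        weights = weights - weights.mean()
        bias = float(rng.uniform(-1.0, 1.0))
        max_exp = np.log2((series_len - 1) / (length - 1))
        dilation = int(2 ** rng.uniform(0.0, max_exp))
        padding = ((length - 1) * dilation) // 2 if rng.integers(2) == 1 else 0
        kernels.append(RocketKernel(weights, bias, dilation, padding))
    return kernels


def apply_kernel(series: np.ndarray, kernel: RocketKernel) -> np.ndarray:
    """Dilated convolution (sliding dot product) of one series with one kernel."""
    series = np.asarray(series, dtype=float)
    return _convolve_matrix(series[None, :], kernel)[0]


def _convolve_matrix(X: np.ndarray, kernel: RocketKernel) -> np.ndarray:
    """Convolution outputs for all rows of X; (n_series, n_out)."""
    n, L = X.shape
    if kernel.padding:
        Xp = np.zeros((n, L + 2 * kernel.padding))
        Xp[:, kernel.padding : kernel.padding + L] = X
    else:
        Xp = X
    n_out = Xp.shape[1] - (kernel.length - 1) * kernel.dilation
    if n_out < 1:
        raise ValueError(
            f"series of length {L} shorter than kernel span {kernel.span} "
            "with no padding"
        )
    out = np.full((n, n_out), kernel.bias)
    for j, w in enumerate(kernel.weights):
        out += w * Xp[:, j * kernel.dilation : j * kernel.dilation + n_out]
    return out


def rocket_features(X: np.ndarray, kernels: list[RocketKernel]) -> np.ndarray:
    """Feature matrix of width 2*len(kernels): per kernel (PPV, max)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be (n_series, series_len)")
    feats = np.empty((X.shape[0], 2 * len(kernels)))
    for k, kernel in enumerate(kernels):
        conv = _convolve_matrix(X, kernel)
        feats[:, 2 * k] = (conv > 0).mean(axis=1)
        feats[:, 2 * k + 1] = conv.max(axis=1)
    return feats


class RocketClassifier:
    """fit/predict wrapper: kernel bank + standardized ridge head.

    The ridge regularization strength is selected by internal leave-one-out
    cross-validation over a log grid; feature standardization statistics are
    learned on the training data only.
    """

    def __init__(self, n_kernels: int = 10_000, seed: int = 0,
                 alphas: np.ndarray | None = None) -> None:
        if n_kernels < 1:
            raise ValueError("n_kernels must be >= 1")
        self.n_kernels = n_kernels
        self.seed = seed
        self.alphas = np.logspace(-3, 3, 10) if alphas is None else alphas
        self.kernels_: list[RocketKernel] | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RocketClassifier":
        X = np.asarray(X, dtype=float)
        check_classes(y)
        self.kernels_ = sample_kernels(self.n_kernels, X.shape[1], self.seed)
        F = rocket_features(X, self.kernels_)
        self.scaler_ = StandardScaler().fit(F)
        self.ridge_ = RidgeClassifierCV(alphas=self.alphas)
        self.ridge_.fit(self.scaler_.transform(F), y)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.kernels_ is None:
            raise RuntimeError("fit before transform")
        return rocket_features(np.asarray(X, dtype=float), self.kernels_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.ridge_.predict(self.scaler_.transform(self.transform(X)))

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def fit_rocket(X: np.ndarray, y: np.ndarray, n_kernels: int = 10_000, seed: int = 0):
    """Convenience: fit a RocketClassifier and report training accuracy."""
    from .base import FittedModel, ModelSpec

    clf = RocketClassifier(n_kernels=n_kernels, seed=seed).fit(X, y)
    spec = ModelSpec(family="rocket", hyperparameters={"n_kernels": n_kernels}, seed=seed)
    return FittedModel(spec=spec, estimator=clf, train_accuracy=clf.score(X, y))
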