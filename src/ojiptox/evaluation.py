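"""Experimental protocol: repeated random splits, accuracy summaries, rank tests.

Per task and per classifier family: 30 independent 80/20 train/test splits,
overall and per-class accuracy on each, median and best run summaries, and
pairwise Kruskal-Wallis comparisons of the 30-run accuracy samples at
significance level 0.01.  Splits are stratified by class by default so the
30-sample concentration classes always appear in the test set (an
unstratified mode is selectable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from .imaging import dataset_to_images
from .models.architectures import (
    build_ann,
    build_cnn1d,
    build_cnn2d,
    default_epochs,
    train_nn,
)
from .models.base import FittedModel, ModelSpec
from .models.rocket import RocketClassifier
from .models.trees import grid_search_rf, grid_search_xgb
from .simulate import CurveDataset
from .transforms import minmax_matrix, vt_matrix

__all__ = [
    "TaskDefinition", "RunResult", "ExperimentSummary", "KruskalResult",
    "split", "prepare_inputs", "fit_family", "run_experiment",
    "per_class_accuracy", "kruskal_wallis", "summarize",
    "select_median_model", "select_best_model", "render_reports",
]

ALPHA = 0.01


@dataclass(frozen=True)
class TaskDefinition:
    """Which labels a classifier must predict.

    ``contaminant``: one 13-class problem over the full dataset, dose pooled
    within each EC (controls included, as in the trial design).
    ``concentration``: one subtask per EC; classes are that EC's dose levels,
    30 samples each.  ``include_control`` keeps or drops the 0 µg/L class.
    """

    kind: str  # "contaminant" | "concentration"
    ec_filter: str | None = None
    include_control: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("contaminant", "concentration"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if self.kind == "concentration" and not self.ec_filter:
            raise ValueError("concentration task requires ec_filter")

    def select(self, dataset: CurveDataset) -> tuple[np.ndarray, np.ndarray]:
        """Row indices into the dataset and the class label of each row."""
        if self.kind == "contaminant":
            return np.arange(len(dataset)), dataset.contaminant_labels()
        idx, labels = dataset.concentration_labels(self.ec_filter)
        if not self.include_control:
            keep = labels != 0.0
            idx, labels = idx[keep], labels[keep]
        # dose values become categorical class labels ("0.8", "300"): the
        # classifiers must not read them as a continuous target
        return idx, np.array([f"{c:g}" for c in labels], dtype=object)

    @property
    def default_representation(self) -> str:
        # Absolute fluorescence carries class signal on the contaminant task;
        # the concentration task is normalized per sample (shape only).
        return "raw" if self.kind == "contaminant" else "minmax"


@dataclass
class RunResult:
    run_index: int
    seed: int
    train_accuracy: float
    test_accuracy: float
    per_class: dict
    best_params: dict | None = None

    def __post_init__(self) -> None:
        for a in (self.train_accuracy, self.test_accuracy):
            if not 0.0 <= a <= 1.0:
                raise ValueError("accuracies must be in [0, 1]")


@dataclass(frozen=True)
class KruskalResult:
    statistic: float
    pvalue: float
    significant: bool
    degenerate: bool = False


@dataclass
class ExperimentSummary:
    results: dict[str, list[RunResult]]
    table: pd.DataFrame
    pvalues: pd.DataFrame
    significant: pd.DataFrame
    median_run: dict[str, RunResult] = field(default_factory=dict)
    best_run: dict[str, RunResult] = field(default_factory=dict)


def split(
    labels: np.ndarray,
    test_fraction: float = 0.2,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index partition; deterministic per seed."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples to split")
    idx = np.arange(len(labels))
    train, test = train_test_split(
        idx,
        test_size=test_fraction,
        random_state=seed,
        stratify=labels if stratify else None,
        shuffle=True,
    )
    return np.sort(train), np.sort(test)


def prepare_inputs(
    dataset: CurveDataset,
    task: TaskDefinition,
    representation: str | None = None,
    image_hw: tuple[int, int] = (128, 128),
) -> tuple[np.ndarray, np.ndarray]:
    """The (X, y) pair for a task under a given input representation.

    Image representations are rendered once here and shared across runs.
    """
    idx, y = task.select(dataset)
    sub = dataset.subset(idx)
    representation = representation or task.default_representation
    if representation == "raw":
        X = sub.values.copy()
    elif representation == "log":
        # class effects and noise are multiplicative in fluorescence, so the
        # log scale makes them additive and homoscedastic
        X = np.log(sub.values)
    elif representation == "vt":
        X = vt_matrix(sub.values)
    elif representation == "minmax":
        X = minmax_matrix(sub.values)
    elif representation in ("image_linear", "image_log"):
        scale = "linear" if representation == "image_linear" else "log"
        X = dataset_to_images(sub, axis_scale=scale, height=image_hw[0], width=image_hw[1])
    else:
        raise ValueError(f"unknown representation {representation!r}")
    return X, y


def fit_family(
    spec: ModelSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    run_seed: int,
    task_kind: str = "contaminant",
) -> FittedModel:
    """Fit one classifier family; grid searches are independent per run."""
    hp = spec.hyperparameters
    n_classes = np.unique(y_train).size
    if spec.family == "rf":
        return grid_search_rf(X_train, y_train, seed=run_seed,
                              cv_folds=hp.get("cv_folds", 5))
    if spec.family == "xgb":
        return grid_search_xgb(X_train, y_train, seed=run_seed,
                               cv_folds=hp.get("cv_folds", 5))
    if spec.family == "rocket":
        clf = RocketClassifier(n_kernels=hp.get("n_kernels", 10_000), seed=run_seed)
        clf.fit(X_train, y_train)
        return FittedModel(spec=spec, estimator=clf,
                           train_accuracy=clf.score(X_train, y_train))
    epochs = spec.epochs or default_epochs(spec.family, task_kind)
    if spec.family == "ann":
        model = build_ann(
            X_train.shape[1], n_classes,
            widths=hp.get("widths", (256, 128, 64, 32, 16)),
            dropout=hp.get("dropout", 0.7), seed=run_seed,
        )
    elif spec.family == "cnn1d":
        model = build_cnn1d(
            X_train.shape[1], n_classes,
            filters=hp.get("filters", (16, 32, 64)),
            dense_width=hp.get("dense_width", 64), seed=run_seed,
        )
    elif spec.family == "cnn2d":
        model = build_cnn2d(
            X_train.shape[1:3], n_classes,
            filters=hp.get("filters", (16, 32, 64, 128, 256)),
            dense_widths=hp.get("dense_widths", (128, 64)),
            dropout=hp.get("dropout", 0.5), seed=run_seed,
        )
    else:  # pragma: no cover - ModelSpec already validates
        raise ValueError(spec.family)
    return train_nn(
        model, X_train, y_train, epochs=epochs, seed=run_seed,
        batch_size=hp.get("batch_size", 32), lr=hp.get("lr", 0.001),
        family=spec.family,
    )


def per_class_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Within-class accuracy; classes absent from y_true map to NaN."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/truth length mismatch")
    out = {}
    for cls in np.unique(y_true):
        mask = y_true == cls
        out[cls] = float(np.mean(y_pred[mask] == cls))
    return out


def run_experiment(
    dataset: CurveDataset,
    task: TaskDefinition,
    spec: ModelSpec,
    n_runs: int = 30,
    base_seed: int = 1,
    test_fraction: float = 0.2,
    stratify: bool = True,
    representation: str | None = None,
    image_hw: tuple[int, int] = (128, 128),
) -> list[RunResult]:
    """The repeated-split protocol for one (task, family) pair.

    Run i (1-based) seeds the split, the model, and — for the tree families —
    an independent grid search with base_seed + i.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if representation is None and spec.family == "cnn2d":
        representation = "image_linear"
    X, y = prepare_inputs(dataset, task, representation, image_hw)
    results = []
    for i in range(1, n_runs + 1):
        run_seed = base_seed + i
        try:
            tr, te = split(y, test_fraction, seed=run_seed, stratify=stratify)
            fitted = fit_family(spec, X[tr], y[tr], run_seed, task.kind)
            pred = fitted.predict(X[te])
            results.append(
                RunResult(
                    run_index=i,
                    seed=run_seed,
                    train_accuracy=fitted.train_accuracy,
                    test_accuracy=float(np.mean(pred == y[te])),
                    per_class=per_class_accuracy(y[te], pred),
                    best_params=fitted.best_params,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"run {i} of {spec.family} failed: {exc}") from exc
    return results


def kruskal_wallis(groups: Sequence[np.ndarray], alpha: float = ALPHA) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p-value.

    When every value in every group is identical H is undefined; that case is
    reported as H=0, p=1 with the degenerate flag set.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return KruskalResult(0.0, 1.0, False, degenerate=True)
    h, p = stats.kruskal(*groups)
    return KruskalResult(float(h), float(p), bool(p < alpha))


def _rank_runs(results: list[RunResult]) -> list[RunResult]:
    # stable sort by test accuracy, ties broken by lower run index
    return sorted(results, key=lambda r: (r.test_accuracy, r.run_index))


def select_median_model(results: list[RunResult]) -> RunResult:
    """The run at the lower-middle rank of test accuracy (rank 15 of 30).

    With an even run count the numeric median is a midpoint between two runs;
    the lower of the two middles is returned so a concrete model exists.
    """
    ranked = _rank_runs(results)
    return ranked[(len(ranked) - 1) // 2]


def select_best_model(results: list[RunResult]) -> RunResult:
    ranked = _rank_runs(results)
    return ranked[-1]


def summarize(results: dict[str, list[RunResult]], alpha: float = ALPHA) -> ExperimentSummary:
    """Median/best tables plus pairwise rank-test comparisons of methods."""
    if not results:
        raise ValueError("empty results")
    rows = []
    for method, runs in results.items():
        test = np.array([r.test_accuracy for r in runs])
        train = np.array([r.train_accuracy for r in runs])
        rows.append(
            {
                "method": method,
                "n_runs": len(runs),
                "train_median": float(np.median(train)),
                "test_median": float(np.median(test)),
                "test_best": float(test.max()),
            }
        )
    table = pd.DataFrame(rows).set_index("method")
    methods = list(results)
    pvals = pd.DataFrame(np.nan, index=methods, columns=methods)
    sig = pd.DataFrame(False, index=methods, columns=methods)
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            if len(results[a]) < 2 or len(results[b]) < 2:
                continue
            kw = kruskal_wallis(
                [
                    [r.test_accuracy for r in results[a]],
                    [r.test_accuracy for r in results[b]],
                ],
                alpha=alpha,
            )
            pvals.loc[a, b] = pvals.loc[b, a] = kw.pvalue
            sig.loc[a, b] = sig.loc[b, a] = kw.significant
    summary = ExperimentSummary(
        results=results, table=table, pvalues=pvals, significant=sig
    )
    for method, runs in results.items():
        summary.median_run[method] = select_median_model(runs)
        summary.best_run[method] = select_best_model(runs)
    return summary


def _per_class_frame(summary: ExperimentSummary, use: str) -> pd.DataFrame:
    chosen = summary.median_run if use == "median" else summary.best_run
    rows = []
    for method, run in chosen.items():
        for cls, acc in run.per_class.items():
            rows.append({"method": method, "class": cls, "accuracy": acc})
    return pd.DataFrame(rows)


def render_reports(
    summary: ExperimentSummary,
    outdir,
    use: str = "median",
    title: str = "",
) -> dict[str, str]:
    """Write CSV tables plus heatmap / spider / boxplot figures.

    All numeric content goes to CSV; the figures are illustrations of the
    same numbers.  Returns a name -> path map of everything written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    if not summary.results:
        raise ValueError("empty summary")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    table = summary.table
    table.to_csv(outdir / "summary.csv")
    paths["summary"] = str(outdir / "summary.csv")

    per_class = _per_class_frame(summary, use)
    per_class.to_csv(outdir / "per_class.csv", index=False)
    paths["per_class"] = str(outdir / "per_class.csv")

    summary.pvalues.to_csv(outdir / "pvalues.csv")
    paths["pvalues"] = str(outdir / "pvalues.csv")

    # heatmap: methods x classes
    pivot = per_class.pivot(index="method", columns="class", values="accuracy")
    fig, ax = plt.subplots(figsize=(1 + 0.6 * pivot.shape[1], 1 + 0.5 * pivot.shape[0]))
    im = ax.imshow(pivot.to_numpy(), vmin=0, vmax=1, cmap="viridis", aspect="auto")
    ax.set_xticks(range(pivot.shape[1]), [str(c) for c in pivot.columns], rotation=90)
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    ax.set_title(title or f"per-class accuracy ({use} run)")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(outdir / "heatmap.png", metadata={"Software": None})
    plt.close(fig)
    paths["heatmap"] = str(outdir / "heatmap.png")

    # spider plot: one polygon per method over classes
    classes = list(pivot.columns)
    angles = np.linspace(0, 2 * np.pi, len(classes), endpoint=False)
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(111, polar=True)
    for method in pivot.index:
        vals = pivot.loc[method].to_numpy()
        ax.plot(np.r_[angles, angles[0]], np.r_[vals, vals[0]], label=method)
    ax.set_xticks(angles)
    ax.set_xticklabels([str(c) for c in classes])
    ax.set_ylim(0, 1)
    ax.legend(loc="lower right", fontsize="small")
    ax.set_title(title or f"per-class accuracy ({use} run)")
    fig.savefig(outdir / "spider.png", metadata={"Software": None})
    plt.close(fig)
    paths["spider"] = str(outdir / "spider.png")

    # boxplot of the run distributions
    fig, ax = plt.subplots(figsize=(1 + 0.8 * len(summary.results), 4))
    data = [[r.test_accuracy for r in runs] for runs in summary.results.values()]
    ax.boxplot(data, tick_labels=list(summary.results))
    ax.set_ylabel("test accuracy")
    ax.set_title(title or "accuracy over runs")
    fig.tight_layout()
    fig.savefig(outdir / "boxplot.png", metadata={"Software": None})
    plt.close(fig)
    paths["boxplot"] = str(outdir / "boxplot.png")
    return paths
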