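"""Grid-searched tree ensembles: random forest and gradient-boosted trees.

Each call performs an exhaustive grid search (5-fold stratified
cross-validation on the training split, accuracy criterion, first-in-grid
tie-break) and refits the winning cell on the full training split.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from xgboost import XGBClassifier

from .base import FittedModel, ModelSpec, check_classes

__all__ = ["RF_GRID", "XGB_GRID", "grid_search_rf", "grid_search_xgb"]

RF_GRID = {
    "criterion": ["gini", "entropy"],
    "n_estimators": [5, 10, 15, 20],
    "max_depth": [2, 5, 7, 9],
}  # 2 x 4 x 4 = 32 cells

XGB_GRID = {
    "max_depth": [2, 5, 7, 9],
    "n_estimators": [50, 100, 200],
    "learning_rate": [0.1, 0.01, 0.001],
    "tree_method": ["auto", "exact", "approx", "hist"],
}  # 4 x 3 x 3 x 4 = 144 cells


def _search(estimator, grid: dict, X, y, seed: int, cv_folds: int) -> GridSearchCV:
    check_classes(y)
    n_min = int(np.bincount(np.unique(y, return_inverse=True)[1]).min())
    folds = min(cv_folds, n_min)
    if folds < 2:
        raise ValueError("smallest class has < 2 samples; cannot cross-validate")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(estimator, grid, scoring="accuracy", cv=cv, n_jobs=1)
    search.fit(X, y)
    return search


def grid_search_rf(
    X: np.ndarray, y: np.ndarray, seed: int = 0, cv_folds: int = 5
) -> FittedModel:
    """Exhaustive 32-cell random-forest grid search; deterministic per seed."""
    search = _search(
        RandomForestClassifier(random_state=seed), RF_GRID, X, y, seed, cv_folds
    )
    spec = ModelSpec(family="rf", hyperparameters=dict(search.best_params_), seed=seed)
    return FittedModel(
        spec=spec,
        estimator=search.best_estimator_,
        train_accuracy=float(search.best_estimator_.score(X, y)),
        best_params=dict(search.best_params_),
    )


class _XGBLabelWrapper:
    """XGBClassifier with arbitrary label dtypes (encodes/decodes internally)."""

    def __init__(self, **kwargs) -> None:
        self.model = XGBClassifier(**kwargs)

    def fit(self, X, y):
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self.model.fit(X, y_enc)
        return self

    def predict(self, X):
        return self.classes_[self.model.predict(X)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def grid_search_xgb(
    X: np.ndarray, y: np.ndarray, seed: int = 0, cv_folds: int = 5
) -> FittedModel:
    """Exhaustive 144-cell gradient-boosted-trees grid search."""
    classes, y_enc = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("training data must contain at least 2 classes")
    search = _search(
        XGBClassifier(random_state=seed, n_jobs=1, verbosity=0),
        XGB_GRID,
        X,
        y_enc,
        seed,
        cv_folds,
    )
    best = _XGBLabelWrapper(
        random_state=seed, n_jobs=1, verbosity=0, **search.best_params_
    )
    best.fit(X, np.asarray(y))
    spec = ModelSpec(family="xgb", hyperparameters=dict(search.best_params_), seed=seed)
    return FittedModel(
        spec=spec,
        estimator=best,
        train_accuracy=best.score(X, np.asarray(y)),
        best_params=dict(search.best_params_),
    )
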