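"""Outcome prediction models: gradient boosted trees and L1 linear models.

Both are tuned by 5-fold cross-validation on training rows only, with
folds that never split one intubation event's windows, and use inverse
class-frequency weighting for the binary task.  Gradient boosted trees
accept missing cells natively (the learner routes them to the loss-optimal
side of each split); the L1 models require complete input and refuse
anything else, mirroring the constraint that makes imputation mandatory
for linear learners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier, LGBMRegressor
from sklearn.base import BaseEstimator
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.model_selection import GridSearchCV, GroupKFold, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

TASKS = ("binary", "continuous")
DEFAULT_GBT_GRID = {"learning_rate": [0.05, 0.1], "num_leaves": [15, 31]}
DEFAULT_L1_BINARY_GRID = {"model__C": [0.01, 0.1, 1.0]}
DEFAULT_L1_CONTINUOUS_GRID = {"model__alpha": [0.001, 0.01, 0.1]}


@dataclass
class OutcomeModelSpec:
    learner: str = "gbt"  # "gbt" | "l1"
    task: str = "binary"
    cv_folds: int = 5
    threshold: float = 0.5
    param_grid: dict | None = None
    n_estimators: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learner not in ("gbt", "l1"):
            raise ValueError(f"unknown learner {self.learner!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")


def inverse_frequency_weights(y: np.ndarray) -> np.ndarray:
    """Per-sample weights proportional to 1 / class frequency, normalized
    so every class carries equal total weight."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    per_class = {c: len(y) / (len(classes) * n) for c, n in zip(classes, counts)}
    return np.array([per_class[v] for v in y])


def encode_features(X: pd.DataFrame) -> pd.DataFrame:
    """Categorical columns to integer codes (missing stays NaN); the
    result is an all-float frame both learners accept."""
    out = {}
    for c in X.columns:
        if isinstance(X[c].dtype, pd.CategoricalDtype):
            codes = X[c].cat.codes.to_numpy(dtype=float)
            codes[codes < 0] = np.nan
            out[c] = codes
        else:
            out[c] = X[c].to_numpy(dtype=float)
    return pd.DataFrame(out, index=X.index)


def _cv_splitter(cv_folds: int, groups):
    return GroupKFold(n_splits=cv_folds) if groups is not None else KFold(n_splits=cv_folds)


class _BaseOutcomeModel(BaseEstimator):
    task: str

    def _validate_labels(self, y: np.ndarray) -> None:
        if self.task == "binary" and np.unique(y).size < 2:
            raise ValueError("training labels contain a single class")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of the positive class (binary) or the predicted
        value (continuous)."""
        raise NotImplementedError

    def predict_class(self, X: pd.DataFrame) -> np.ndarray:
        if self.task != "binary":
            raise ValueError("classes are only defined for the binary task")
        return (self.predict(X) >= self.threshold).astype(int)


class GradientBoostedModel(_BaseOutcomeModel):
    """LightGBM with native missing-value support and grouped 5-fold
    CV tuning over a small learning-rate x leaves grid."""

    def __init__(self, task="binary", cv_folds=5, threshold=0.5, param_grid=None,
                 n_estimators=200, seed=0):
        self.task = task
        self.cv_folds = cv_folds
        self.threshold = threshold
        self.param_grid = param_grid
        self.n_estimators = n_estimators
        self.seed = seed

    def fit(self, X: pd.DataFrame, y, groups=None):
        Xe = encode_features(X)
        y = np.asarray(y)
        self._validate_labels(y)
        base_kwargs = dict(
            n_estimators=self.n_estimators,
            random_state=self.seed,
            n_jobs=1,
            verbose=-1,
            min_child_samples=10,
        )
        if self.task == "binary":
            est = LGBMClassifier(**base_kwargs)
            weights = inverse_frequency_weights(y)
            self.class_frequencies_ = dict(zip(*np.unique(y, return_counts=True)))
            scoring = "roc_auc"
        else:
            est = LGBMRegressor(**base_kwargs)
            weights = None
            self.class_frequencies_ = None
            scoring = "neg_mean_squared_error"
        grid = DEFAULT_GBT_GRID if self.param_grid is None else self.param_grid
        if grid:
            search = GridSearchCV(
                est, grid, cv=_cv_splitter(self.cv_folds, groups), scoring=scoring,
                n_jobs=1, refit=True,
            )
            search.fit(Xe, y, groups=groups, sample_weight=weights)
            self.model_ = search.best_estimator_
            self.best_params_ = search.best_params_
        else:
            est.fit(Xe, y, sample_weight=weights)
            self.model_ = est
            self.best_params_ = {}
        self.feature_names_ = list(X.columns)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names_:
            raise ValueError("feature contract mismatch")
        Xe = encode_features(X)
        if self.task == "binary":
            return self.model_.predict_proba(Xe)[:, 1]
        return self.model_.predict(Xe)


class L1LinearModel(_BaseOutcomeModel):
    """L1-penalized logistic regression / LASSO with grouped CV over the
    penalty path.  Requires complete input."""

    def __init__(self, task="binary", cv_folds=5, threshold=0.5, param_grid=None, seed=0):
        self.task = task
        self.cv_folds = cv_folds
        self.threshold = threshold
        self.param_grid = param_grid
        self.seed = seed

    def fit(self, X: pd.DataFrame, y, groups=None):
        Xe = encode_features(X)
        if Xe.isna().to_numpy().any():
            raise ValueError("L1 models cannot accommodate missing values")
        y = np.asarray(y)
        self._validate_labels(y)
        if self.task == "binary":
            model = LogisticRegression(
                solver="liblinear", l1_ratio=1.0, random_state=self.seed, max_iter=500
            )
            grid = DEFAULT_L1_BINARY_GRID if self.param_grid is None else self.param_grid
            weights = inverse_frequency_weights(y)
            fit_params = {"model__sample_weight": weights}
            scoring = "roc_auc"
        else:
            model = Lasso(max_iter=5000)
            grid = DEFAULT_L1_CONTINUOUS_GRID if self.param_grid is None else self.param_grid
            fit_params = {}
            scoring = "neg_mean_squared_error"
        pipe = Pipeline([("scale", StandardScaler()), ("model", model)])
        if grid:
            search = GridSearchCV(
                pipe, grid, cv=_cv_splitter(self.cv_folds, groups), scoring=scoring,
                n_jobs=1, refit=True,
            )
            search.fit(Xe, y, groups=groups, **fit_params)
            self.model_ = search.best_estimator_
            self.best_params_ = search.best_params_
        else:
            pipe.fit(Xe, y, **fit_params)
            self.model_ = pipe
            self.best_params_ = {}
        self.feature_names_ = list(X.columns)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names_:
            raise ValueError("feature contract mismatch")
        Xe = encode_features(X)
        if Xe.isna().to_numpy().any():
            raise ValueError("L1 models cannot accommodate missing values")
        if self.task == "binary":
            return self.model_.predict_proba(Xe)[:, 1]
        return self.model_.predict(Xe)


def fit_outcome_model(spec: OutcomeModelSpec, X: pd.DataFrame, y, groups=None):
    cls = GradientBoostedModel if spec.learner == "gbt" else L1LinearModel
    kwargs = dict(
        task=spec.task, cv_folds=spec.cv_folds, threshold=spec.threshold,
        param_grid=spec.param_grid, seed=spec.seed,
    )
    if spec.learner == "gbt":
        kwargs["n_estimators"] = spec.n_estimators
    return cls(**kwargs).fit(X, y, groups=groups)


def mi_ensemble_predict(models: list, rows_list: list[pd.DataFrame]) -> np.ndarray:
    """Multiple-imputation ensembling: the final score is the arithmetic
    mean of each member model's prediction on its matching completed
    test set."""
    if len(models) != len(rows_list):
        raise ValueError("m mismatch between models and test completions")
    return np.mean([m.predict(rows) for m, rows in zip(models, rows_list)], axis=0)
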