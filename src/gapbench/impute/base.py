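"""Imputer base classes and the multiple-imputation bundle.

All imputers are scikit-learn style estimators: ``fit(X)`` learns state
from training rows only (the outcome is never passed in), ``transform(X)``
returns one completed copy, and ``transform_multi(X)`` returns the ``m``
stochastic completions used for multiple imputation.  Fitted state never
contains test-set information, and applying to a single new row requires
no refitting — the contract needed to transfer an imputation model from
model development to real-time prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

LABEL_COLUMNS = ("success_label", "bp_label")

METHODS = ("mean", "locf", "rf_donor", "bayes_pmm", "lasso_boot", "none")
DETERMINISTIC_METHODS = ("mean", "locf", "none")


@dataclass
class ImputerSpec:
    """Configuration of one missing-data handling strategy."""

    method: str = "mean"
    m: int = 30
    k_donors: int = 5
    n_trees: int = 10
    max_depth: int | None = None
    max_features: str | float = "sqrt"  # per-split feature subsample (mtry)
    chained_iters: int = 5
    max_predictors: int | None = None
    max_fit_rows: int | None = None
    locf_fallback_to_mean: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown imputation method {self.method!r}")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @property
    def effective_m(self) -> int:
        return 1 if self.method in DETERMINISTIC_METHODS else self.m


@dataclass
class ImputedBundle:
    """m completed copies of a table, their average, and provenance of
    which cells were imputed."""

    tables: list[pd.DataFrame]
    average: pd.DataFrame
    imputed_mask: pd.DataFrame
    method: str

    @property
    def m(self) -> int:
        return len(self.tables)


def _categorical_cell_mode(stacked_codes: np.ndarray) -> np.ndarray:
    """Per-cell mode of an (m, n) code array; ties break to the smallest
    code (deterministic)."""
    mode, _ = stats.mode(stacked_codes, axis=0, keepdims=False)
    return mode


def average_imputations(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Cell-wise average of m completed tables: mean for numeric cells,
    per-cell mode for categorical cells."""
    if not tables:
        raise ValueError("need at least one completed table")
    first = tables[0]
    for t in tables[1:]:
        if t.shape != first.shape or list(t.columns) != list(first.columns):
            raise ValueError("inconsistent table shapes in bundle")
    if len(tables) == 1:
        return first.copy()
    out = first.copy()
    for col in first.columns:
        if isinstance(first[col].dtype, pd.CategoricalDtype):
            codes = np.stack([t[col].cat.codes.to_numpy() for t in tables])
            mode_codes = _categorical_cell_mode(codes)
            out[col] = pd.Categorical.from_codes(
                mode_codes, categories=first[col].cat.categories
            )
        else:
            out[col] = np.mean(np.stack([t[col].to_numpy(dtype=float) for t in tables]), axis=0)
    return out


class BaseImputer(BaseEstimator):
    """Common surface of all imputers.  Subclasses implement ``_fit`` and
    ``_transform_once``."""

    method: str = "base"

    def _check_fit_input(self, X: pd.DataFrame) -> pd.DataFrame:
        bad = [c for c in X.columns if c in LABEL_COLUMNS]
        if bad:
            raise ValueError(
                f"outcome columns {bad} must be excluded from imputation models"
            )
        return X

    def fit(self, X: pd.DataFrame, y=None) -> "BaseImputer":
        X = self._check_fit_input(X)
        self.columns_ = list(X.columns)
        self.kinds_ = {
            c: ("categorical" if isinstance(X[c].dtype, pd.CategoricalDtype) else "numeric")
            for c in X.columns
        }
        self._fit(X)
        return self

    def _fit(self, X: pd.DataFrame) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def _check_apply_input(self, X: pd.DataFrame) -> pd.DataFrame:
        if list(X.columns) != self.columns_:
            raise ValueError("column contract mismatch between fit and apply")
        return X

    @property
    def effective_m(self) -> int:
        if self.method in DETERMINISTIC_METHODS:
            return 1
        return getattr(self, "m", 1)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """One completed copy (deterministic given the imputer's seed)."""
        X = self._check_apply_input(X)
        rng = np.random.default_rng(np.random.SeedSequence((getattr(self, "seed", 0), 1)))
        return self._transform_once(X, rng, imp_index=0)

    def transform_multi(self, X: pd.DataFrame, m: int | None = None) -> list[pd.DataFrame]:
        """m stochastic completions (a single table for deterministic
        methods, whatever ``m`` says)."""
        X = self._check_apply_input(X)
        m = self.effective_m if m is None else (1 if self.method in DETERMINISTIC_METHODS else m)
        seeds = np.random.SeedSequence((getattr(self, "seed", 0), 1)).spawn(m)
        return [
            self._transform_once(X, np.random.default_rng(s), imp_index=i)
            for i, s in enumerate(seeds)
        ]

    def impute_bundle(self, X: pd.DataFrame) -> ImputedBundle:
        tables = self.transform_multi(X)
        return ImputedBundle(
            tables=tables,
            average=average_imputations(tables),
            imputed_mask=X.isna(),
            method=self.method,
        )

    def _transform_once(
        self, X: pd.DataFrame, rng: np.random.Generator, imp_index: int
    ) -> pd.DataFrame:  # pragma: no cover - abstract
        raise NotImplementedError

    # -- serialization ----------------------------------------------------
    SERIALIZATION_VERSION = 1

    def save(self, path) -> None:
        joblib.dump({"version": self.SERIALIZATION_VERSION, "imputer": self}, path)

    @classmethod
    def load(cls, path) -> "BaseImputer":
        payload = joblib.load(path)
        if payload.get("version") != cls.SERIALIZATION_VERSION:
            warnings.warn("imputer archive version mismatch")
        return payload["imputer"]


def make_imputer(spec: ImputerSpec) -> BaseImputer:
    """Instantiate the imputer named by a spec."""
    from .chained import BayesianPMMImputer, LassoBootstrapImputer, RandomForestDonorImputer
    from .simple import IdentityImputer, LOCFImputer, MeanModeImputer

    if spec.method == "mean":
        return MeanModeImputer()
    if spec.method == "locf":
        return LOCFImputer(fallback_to_mean=spec.locf_fallback_to_mean)
    if spec.method == "none":
        return IdentityImputer()
    common = dict(
        m=spec.m,
        chained_iters=spec.chained_iters,
        max_predictors=spec.max_predictors,
        max_fit_rows=spec.max_fit_rows,
        seed=spec.seed,
    )
    if spec.method == "rf_donor":
        return RandomForestDonorImputer(
            n_trees=spec.n_trees, max_depth=spec.max_depth,
            max_features=spec.max_features, **common
        )
    if spec.method == "bayes_pmm":
        return BayesianPMMImputer(k_donors=spec.k_donors, **common)
    if spec.method == "lasso_boot":
        return LassoBootstrapImputer(**common)
    raise ValueError(spec.method)


def fit_imputer(spec: ImputerSpec, train: pd.DataFrame) -> BaseImputer:
    """Fit the imputer a spec describes on training rows only."""
    return make_imputer(spec).fit(train)
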