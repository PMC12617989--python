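"""Two-level evaluation: imputation accuracy and prediction performance.

Imputation accuracy is scored only at amputed cells, against the complete
table: per-variable mean squared error after standardizing by the
variable's standard deviation in the complete dataset (numeric cells),
and per-variable classification error (categorical cells).  A dataset's
error is the unweighted mean over variables with at least one amputed
cell.  Prediction performance uses the standard classification /
regression metric set, with balanced accuracy = (sensitivity +
specificity) / 2 as the primary classification metric.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm


def complete_sds(complete: pd.DataFrame, numeric_cols: list[str]) -> pd.Series:
    """Per-variable SDs from the complete dataset — the standardization
    denominators for imputation MSE.  Zero-SD variables are excluded with
    a warning."""
    sds = complete[numeric_cols].astype(float).std(ddof=1)
    zero = sds[~(sds > 0)].index.tolist()
    if zero:
        warnings.warn(f"zero-variance variables excluded from standardized MSE: {zero}")
    return sds[sds > 0]


def imputation_mse(
    complete: pd.DataFrame,
    imputed: pd.DataFrame,
    mask: pd.DataFrame,
    sds: pd.Series,
) -> tuple[float, pd.Series]:
    """Standardized MSE over amputed numeric cells.

    Returns ``(dataset_mse, per_variable)`` where the dataset value is the
    unweighted mean over variables with >= 1 amputed cell.  Cells the
    imputer left unfilled (e.g. LOCF leading gaps) are skipped.
    """
    cols = [c for c in sds.index if c in complete.columns and mask[c].any()]
    if not cols:
        raise ValueError("empty mask: no amputed numeric cells to evaluate")
    per_var = {}
    for c in cols:
        m = mask[c].to_numpy()
        truth = complete[c].to_numpy(dtype=float)[m]
        imp = imputed[c].to_numpy(dtype=float)[m]
        filled = ~np.isnan(imp)
        if not filled.any():
            continue
        err = (imp[filled] - truth[filled]) / sds[c]
        per_var[c] = float(np.mean(err**2))
    per_var = pd.Series(per_var)
    return float(per_var.mean()), per_var


def classification_error(
    complete: pd.DataFrame,
    imputed: pd.DataFrame,
    mask: pd.DataFrame,
    categorical_cols: list[str],
) -> tuple[float, pd.Series]:
    """Fraction of amputed categorical cells imputed to the wrong level,
    per variable, then averaged over variables."""
    cols = [c for c in categorical_cols if c in complete.columns and mask[c].any()]
    if not cols:
        raise ValueError("empty mask: no amputed categorical cells to evaluate")
    per_var = {}
    for c in cols:
        m = mask[c].to_numpy()
        truth = np.asarray(complete[c])[m]
        imp = np.asarray(imputed[c])[m]
        filled = ~pd.isna(imp)
        if not filled.any():
            continue
        per_var[c] = float(np.mean(imp[filled] != truth[filled]))
    per_var = pd.Series(per_var)
    return float(per_var.mean()), per_var


def prediction_metrics(
    y_true, scores, task: str, threshold: float = 0.5
) -> dict[str, float]:
    """Standard outcome-model metric set.

    Binary: balanced accuracy, AUC (absent when only one class is
    present), sensitivity, specificity, PPV, NPV, F1.  Continuous: MSE,
    RMSE, MAE, R^2.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty test labels")
    if task == "continuous":
        mse = float(np.mean((y_true - scores) ** 2))
        return {
            "mse": mse,
            "rmse": float(np.sqrt(mse)),
            "mae": float(np.mean(np.abs(y_true - scores))),
            "r2": float(skm.r2_score(y_true, scores)),
        }
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    ppv = tp / (tp + fp) if (tp + fp) else np.nan
    npv = tn / (tn + fn) if (tn + fn) else np.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else np.nan
    auc = (
        float(skm.roc_auc_score(y_true, scores))
        if np.unique(y_true).size > 1
        else np.nan
    )
    return {
        "balanced_accuracy": (sens + spec) / 2.0,
        "auc": auc,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "f1": f1,
    }


def coefficient_of_variation(values) -> float:
    """Sample-SD / mean; undefined (NaN) when the mean is zero."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean == 0:
        return np.nan
    return float(values.std(ddof=1) / mean)


def variability_and_overfit(report: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-method variability and train-minus-test overfit gaps.

    ``report`` is tidy with columns (outcome, mechanism, level, replicate,
    method, model, partition, metric, value).  The CV is taken across
    imputation methods — per model x outcome x metric — after pooling
    scenarios into per-method means.  The gap is metric(train) -
    metric(test) per dataset.
    """
    test = report[report["partition"] == "test"]
    method_means = (
        test.groupby(["model", "outcome", "metric", "method"])["value"].mean().reset_index()
    )
    cv_rows = []
    for (model, outcome, metric), grp in method_means.groupby(["model", "outcome", "metric"]):
        cv_rows.append(
            {
                "model": model,
                "outcome": outcome,
                "metric": metric,
                "cv": coefficient_of_variation(grp["value"].to_numpy()),
            }
        )
    keys = ["outcome", "mechanism", "level", "replicate", "method", "model", "metric"]
    if "stratum" in report.columns:
        keys.append("stratum")
    wide = report.pivot_table(index=keys, columns="partition", values="value", aggfunc="first")
    gaps = pd.DataFrame()
    if {"train", "test"}.issubset(wide.columns):
        gaps = (wide["train"] - wide["test"]).rename("gap").reset_index()
    return pd.DataFrame(cv_rows), gaps


def ar1_pooled(data: pd.DataFrame) -> pd.Series:
    """Within-event lag-1 Pearson correlation pooled across events, per
    variable (pairs crossing event boundaries are dropped; constant
    variables yield NaN)."""
    data = data.sort_index()
    shifted = data.groupby(level=0).shift(1)
    out = {}
    for c in data.columns:
        x = data[c]
        if isinstance(x.dtype, pd.CategoricalDtype):
            x = x.cat.codes.astype(float).replace(-1, np.nan)
            y = shifted[c]
            y = y.cat.codes.astype(float).replace(-1, np.nan) if isinstance(
                y.dtype, pd.CategoricalDtype
            ) else y.astype(float)
        else:
            x = x.astype(float)
            y = shifted[c].astype(float)
        ok = x.notna() & y.notna()
        if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            out[c] = np.nan
        else:
            out[c] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return pd.Series(out)


def autocorrelation_analysis(
    ar1: pd.Series, per_variable_errors: dict[str, pd.Series]
) -> pd.Series:
    """Pearson r between per-variable AR(1) coefficient and per-variable
    imputation error, for each method."""
    out = {}
    for method, errors in per_variable_errors.items():
        common = ar1.dropna().index.intersection(errors.dropna().index)
        if len(common) < 3:
            out[method] = np.nan
        else:
            out[method] = float(
                stats.pearsonr(ar1[common], errors[common]).statistic
            )
    return pd.Series(out)


def stratify_by_original_missingness(
    complete: pd.DataFrame,
    imputed: pd.DataFrame,
    mask: pd.DataFrame,
    sds: pd.Series,
    original_missing: pd.DataFrame | None,
) -> pd.DataFrame:
    """Standardized MSE reported separately for cells that were missing in
    the original data (and filled to build the synthetic complete table)
    versus cells that were not."""
    if original_missing is None:
        warnings.warn("original-missing flags absent; reporting a single stratum")
        mse, _ = imputation_mse(complete, imputed, mask, sds)
        return pd.DataFrame([{"stratum": "all", "mse": mse}])
    rows = []
    for label, stratum_mask in (
        ("originally_missing", mask & original_missing),
        ("not_originally_missing", mask & ~original_missing),
    ):
        if not stratum_mask.to_numpy().any():
            continue
        mse, _ = imputation_mse(complete, imputed, stratum_mask, sds)
        rows.append({"stratum": label, "mse": mse})
    return pd.DataFrame(rows)
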