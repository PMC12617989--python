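"""Evaluation metrics: standardized MSE, classification error, prediction
metric identities, CV, autocorrelation analysis, stratification."""

import numpy as np
import pandas as pd
import pytest

from gapbench.metrics import (
    ar1_pooled,
    autocorrelation_analysis,
    classification_error,
    coefficient_of_variation,
    complete_sds,
    imputation_mse,
    prediction_metrics,
    stratify_by_original_missingness,
    variability_and_overfit,
)


def _tables(n=100, seed=0, miss_frac=0.4):
    rng = np.random.default_rng(seed)
    complete = pd.DataFrame(
        {"a": rng.normal(0, 2, n), "b": rng.normal(5, 1, n)}
    )
    mask = pd.DataFrame(rng.random((n, 2)) < miss_frac, columns=["a", "b"])
    return complete, mask


def test_perfect_imputation_zero_error():
    complete, mask = _tables()
    sds = complete_sds(complete, ["a", "b"])
    mse, per_var = imputation_mse(complete, complete.copy(), mask, sds)
    assert mse == 0.0
    assert (per_var == 0.0).all()


def test_observed_cells_never_contribute():
    complete, mask = _tables()
    sds = complete_sds(complete, ["a", "b"])
    imputed = complete.copy()
    imputed[~mask] = 999.0  # corrupt only unmasked cells
    mse, _ = imputation_mse(complete, complete.where(mask, imputed), mask, sds)
    assert mse == 0.0


def test_empty_mask_is_an_error():
    complete, mask = _tables()
    sds = complete_sds(complete, ["a", "b"])
    with pytest.raises(ValueError, match="empty mask"):
        imputation_mse(complete, complete, mask & False, sds)


def test_constant_mean_imputation_mse_near_one():
    """Imputing every amputed cell with the variable mean yields a
    standardized MSE near 1 under MCAR."""
    complete, mask = _tables(n=20000, seed=1)
    sds = complete_sds(complete, ["a", "b"])
    imputed = complete.mask(mask)
    imputed = imputed.fillna(complete.mean())
    mse, _ = imputation_mse(complete, imputed, mask, sds)
    assert mse == pytest.approx(1.0, abs=0.05)


def test_zero_variance_variables_excluded_with_warning():
    complete = pd.DataFrame({"a": [1.0, 2.0, 3.0], "z": [5.0, 5.0, 5.0]})
    with pytest.warns(UserWarning, match="zero-variance"):
        sds = complete_sds(complete, ["a", "z"])
    assert list(sds.index) == ["a"]


def test_classification_error_bounds():
    complete = pd.DataFrame({"c": pd.Categorical(["x", "y", "x", "y"])})
    mask = pd.DataFrame({"c": [True, True, True, False]})
    err, _ = classification_error(complete, complete.copy(), mask, ["c"])
    assert err == 0.0
    wrong = pd.DataFrame({"c": pd.Categorical(["y", "x", "y", "y"])})
    err, _ = classification_error(complete, wrong, mask, ["c"])
    assert err == 1.0


def test_binary_metric_identities():
    metrics = prediction_metrics(
        np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0]),
        np.array([0.9, 0.8, 0.7, 0.6, 0.2, 0.7, 0.3, 0.2, 0.1, 0.4]),
        "binary",
    )
    # sens 0.8, spec 0.8 -> balanced accuracy (0.8 + 0.8) / 2
    assert metrics["balanced_accuracy"] == pytest.approx(
        (metrics["sensitivity"] + metrics["specificity"]) / 2
    )
    tp, fp, fn = 4, 1, 1
    assert metrics["f1"] == pytest.approx(2 * tp / (2 * tp + fp + fn))
    assert metrics["balanced_accuracy"] == pytest.approx(0.8)


def test_balanced_accuracy_from_sens_spec():
    y = np.array([1] * 10 + [0] * 10)
    s = np.array([0.9] * 8 + [0.1] * 2 + [0.9] * 4 + [0.1] * 6)
    m = prediction_metrics(y, s, "binary")
    assert m["sensitivity"] == pytest.approx(0.8)
    assert m["specificity"] == pytest.approx(0.6)
    assert m["balanced_accuracy"] == pytest.approx(0.7)


def test_continuous_metric_identities():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    s = np.array([1.5, 2.0, 2.0, 5.0])
    m = prediction_metrics(y, s, "continuous")
    assert m["rmse"] ** 2 == pytest.approx(m["mse"])
    assert m["mae"] == pytest.approx(np.mean(np.abs(y - s)))


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 200)
    s = rng.random(200) + 0.3 * y
    a1 = prediction_metrics(y, s, "binary")["auc"]
    a2 = prediction_metrics(y, np.exp(3 * s), "binary")["auc"]
    assert a1 == pytest.approx(a2)


def test_random_scores_auc_near_half():
    rng = np.random.default_rng(1)
    y = np.array([0, 1] * 500)
    s = rng.random(1000)
    assert prediction_metrics(y, s, "binary")["auc"] == pytest.approx(0.5, abs=0.06)


def test_single_class_auc_absent():
    m = prediction_metrics(np.ones(5), np.linspace(0, 1, 5), "binary")
    assert np.isnan(m["auc"])


def test_coefficient_of_variation():
    assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(np.sqrt(2) / 2)
    assert coefficient_of_variation([2.0, 2.0]) == 0.0
    assert np.isnan(coefficient_of_variation([-1.0, 1.0]))


def test_variability_and_overfit_report():
    rows = []
    for method, val in (("mean", 1.0), ("locf", 3.0)):
        for partition in ("train", "test"):
            rows.append(
                dict(outcome="binary", mechanism="MCAR", level=1.0, replicate=0,
                     method=method, model="gbt", partition=partition,
                     metric="auc", value=val)
            )
    report = pd.DataFrame(rows)
    cv, gaps = variability_and_overfit(report)
    assert cv["cv"].iloc[0] == pytest.approx(np.sqrt(2) / 2)
    assert (gaps["gap"] == 0.0).all()  # train == test -> zero gap


def _ar_series(rho, n=4000, seed=0):
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    for k in range(1, n):
        x[k] = rho * x[k - 1] + np.sqrt(1 - rho**2) * rng.standard_normal()
    idx = pd.MultiIndex.from_tuples([(i // 40, i % 40 + 1) for i in range(n)])
    return pd.DataFrame({"v": x}, index=idx)


@pytest.mark.parametrize("rho", [0.0, 0.9])
def test_ar1_pooled_recovers_coefficient(rho):
    est = ar1_pooled(_ar_series(rho))["v"]
    assert est == pytest.approx(rho, abs=0.05)


def test_ar1_constant_variable_nan():
    df = _ar_series(0.5)
    df["const"] = 1.0
    assert np.isnan(ar1_pooled(df)["const"])


def test_autocorrelation_error_correlation_sign():
    ar1 = pd.Series({"v1": 0.1, "v2": 0.5, "v3": 0.9})
    errors = {"locf": pd.Series({"v1": 1.8, "v2": 1.0, "v3": 0.2})}
    r = autocorrelation_analysis(ar1, errors)
    assert r["locf"] < -0.99


def test_stratified_mse_aggregation_identity():
    """Per-variable pooled MSE equals the cell-count-weighted mean of the
    two strata's per-variable MSEs."""
    complete, mask = _tables(n=500, seed=3)
    rng = np.random.default_rng(4)
    imputed = complete + rng.normal(0, 0.5, complete.shape)
    orig = pd.DataFrame(rng.random(complete.shape) < 0.5, columns=complete.columns)
    sds = complete_sds(complete, ["a", "b"])
    _, pooled = imputation_mse(complete, imputed, mask, sds)
    _, in_strat = imputation_mse(complete, imputed, mask & orig, sds)
    _, out_strat = imputation_mse(complete, imputed, mask & ~orig, sds)
    for v in ["a", "b"]:
        n_in = int((mask & orig)[v].sum())
        n_out = int((mask & ~orig)[v].sum())
        combined = (in_strat[v] * n_in + out_strat[v] * n_out) / (n_in + n_out)
        assert pooled[v] == pytest.approx(combined)
    table = stratify_by_original_missingness(complete, imputed, mask, sds, orig)
    assert set(table["stratum"]) == {"originally_missing", "not_originally_missing"}
    with pytest.warns(UserWarning, match="flags absent"):
        single = stratify_by_original_missingness(complete, imputed, mask, sds, None)
    assert single["stratum"].tolist() == ["all"]
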