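"""Imputers: method semantics, donor membership, transfer contract."""

import numpy as np
import pandas as pd
import pytest

from gapbench.impute import (
    BayesianPMMImputer,
    IdentityImputer,
    ImputerSpec,
    LassoBootstrapImputer,
    LOCFImputer,
    MeanModeImputer,
    RandomForestDonorImputer,
    average_imputations,
    fit_imputer,
    locf_impute,
    make_imputer,
)


def _frame(values: dict, index=None) -> pd.DataFrame:
    df = pd.DataFrame(values, index=index)
    for c in df.columns:
        if df[c].dtype == object:
            df[c] = pd.Categorical(df[c])
    return df


def _mi(event_windows):
    return pd.MultiIndex.from_tuples(event_windows, names=["event_id", "window_index"])


def test_spec_validation():
    with pytest.raises(ValueError):
        ImputerSpec(method="bogus")
    with pytest.raises(ValueError):
        ImputerSpec(m=0)
    assert ImputerSpec(method="mean", m=30).effective_m == 1
    assert ImputerSpec(method="bayes_pmm", m=30).effective_m == 30


def test_mean_mode_imputation():
    train = _frame({"x": [2.0, 4.0], "c": ["A", "A", "B"][:2]})
    test = _frame({"x": [np.nan, 1.0], "c": [None, "A"]})
    test["c"] = pd.Categorical(test["c"], categories=["A", "B"])
    imp = MeanModeImputer().fit(train)
    out = imp.transform(test)
    assert out["x"].iloc[0] == 3.0  # training mean of {2, 4}
    assert out["c"].iloc[0] == "A"  # training mode
    assert out["x"].iloc[1] == 1.0  # observed untouched


def test_mode_of_train_counts():
    train = _frame({"c": ["A", "A", "B"]})
    imp = MeanModeImputer().fit(train)
    assert imp.fill_values_["c"] == "A"


def test_identity_imputer_passthrough():
    X = _frame({"x": [1.0, np.nan]})
    imp = IdentityImputer().fit(X)
    out = imp.transform(X)
    pd.testing.assert_frame_equal(out, X)


def test_locf_series_semantics():
    assert locf_impute(pd.Series([5.0, np.nan, np.nan])).tolist() == [5.0, 5.0, 5.0]
    out = locf_impute(pd.Series([np.nan, 7.0]))
    assert np.isnan(out.iloc[0]) and out.iloc[1] == 7.0
    complete = pd.Series([1.0, 2.0])
    pd.testing.assert_series_equal(locf_impute(complete), complete)


def test_locf_never_crosses_events_or_uses_future():
    X = pd.DataFrame(
        {"x": [1.0, np.nan, np.nan, np.nan, 9.0, np.nan]},
        index=_mi([(0, 1), (0, 2), (0, 3), (1, 1), (1, 2), (1, 3)]),
    )
    imp = LOCFImputer().fit(X)
    out = imp.transform(X)
    assert out["x"].loc[0].tolist() == [1.0, 1.0, 1.0]
    assert np.isnan(out["x"].loc[(1, 1)])  # no prior value; future never used
    assert out["x"].loc[(1, 3)] == 9.0


def test_locf_mean_fallback_for_complete_models():
    X = pd.DataFrame(
        {"x": [np.nan, 4.0, 2.0]}, index=_mi([(0, 1), (0, 2), (1, 1)])
    )
    imp = LOCFImputer(fallback_to_mean=True).fit(X)
    out = imp.transform(X)
    assert out["x"].loc[(0, 1)] == pytest.approx(3.0)


def test_fit_refuses_outcome_columns():
    X = pd.DataFrame({"x": [1.0], "success_label": [1]})
    with pytest.raises(ValueError, match="outcome"):
        MeanModeImputer().fit(X)


def test_average_imputations_numeric_and_categorical():
    t1 = _frame({"x": [1.0], "c": ["A"]})
    t2 = _frame({"x": [3.0], "c": ["A"]})
    t3 = _frame({"x": [2.0], "c": ["B"]})
    for t in (t1, t2, t3):
        t["c"] = pd.Categorical(t["c"], categories=["A", "B"])
    avg = average_imputations([t1, t2, t3])
    assert avg["x"].iloc[0] == 2.0
    assert avg["c"].iloc[0] == "A"  # mode of {A, A, B}
    same = average_imputations([t1, t1])
    assert same["x"].iloc[0] == 1.0
    with pytest.raises(ValueError):
        average_imputations([t1, _frame({"x": [1.0]})])


def _chained_fixture(seed=0, n=300):
    """Training matrix with correlated numeric columns, one categorical,
    and ~25% missingness."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    df = pd.DataFrame(
        {
            "a": 10 + 2 * z + rng.normal(0, 0.5, n),
            "b": -5 + 3 * z + rng.normal(0, 0.5, n),
            "d": rng.normal(0, 1, n),
        },
        index=_mi([(i // 10, i % 10 + 1) for i in range(n)]),
    )
    df["c"] = pd.Categorical(
        np.where(z > 0, "hi", np.where(z > -1, "mid", "lo")),
        categories=["lo", "mid", "hi"],
    )
    miss = rng.random((n, 4)) < 0.25
    df = df.mask(pd.DataFrame(miss, index=df.index, columns=df.columns))
    for c in ("a", "b", "d"):
        df[c] = df[c].astype(float)
    return df


@pytest.mark.parametrize("cls", [RandomForestDonorImputer, BayesianPMMImputer])
def test_donor_methods_return_observed_training_values(cls):
    """Donor-based imputations are always members of the variable's
    observed training value set (checked over >= 1000 draws)."""
    train = _chained_fixture(seed=1)
    test = _chained_fixture(seed=2, n=160)
    imp = cls(m=10, chained_iters=3, seed=3).fit(train)
    observed = {c: set(train[c].dropna()) for c in ["a", "b", "d"]}
    draws = 0
    for t in imp.transform_multi(test):
        for c in ["a", "b", "d"]:
            filled = t[c][test[c].isna()]
            assert filled.notna().all()
            assert set(filled).issubset(observed[c])
            draws += len(filled)
    assert draws >= 1000


def test_pmm_within_observed_range():
    train = _chained_fixture(seed=4)
    test = _chained_fixture(seed=5, n=100)
    imp = BayesianPMMImputer(m=5, chained_iters=3, seed=6).fit(train)
    for t in imp.transform_multi(test):
        for c in ["a", "b", "d"]:
            assert t[c].min() >= train[c].min()
            assert t[c].max() <= train[c].max()


def test_pmm_exact_linear_selects_nearest_donor():
    """On noiseless linear data with a single donor to choose (k=1), PMM
    returns the donor whose prediction is nearest — the brute-force
    nearest-neighbour oracle."""
    n = 60
    x = np.linspace(0, 1, n)
    train = pd.DataFrame({"x": x, "y": 2.0 * x}, index=_mi([(0, i + 1) for i in range(n)]))
    train.loc[train.index[5], "y"] = np.nan  # one missing cell to trigger fitting
    imp = BayesianPMMImputer(m=1, k_donors=1, chained_iters=1, seed=0).fit(train)
    test = pd.DataFrame({"x": [0.52], "y": [np.nan]}, index=_mi([(9, 1)]))
    out = imp.transform(test)
    y_obs = train["y"].dropna()
    x_obs = train.loc[y_obs.index, "x"]
    oracle = y_obs.iloc[(x_obs - 0.52).abs().to_numpy().argmin()]
    # posterior noise is tiny on noiseless data: nearest or next-nearest donor
    assert abs(out["y"].iloc[0] - oracle) <= 2 * (2.0 / (n - 1)) + 1e-6


def test_lasso_heavy_penalty_collapses_to_intercept():
    """With a dominating penalty the linear draws are training mean plus
    residual noise."""
    train = _chained_fixture(seed=7)
    imp = LassoBootstrapImputer(m=20, alpha=1e6, chained_iters=2, seed=8).fit(train)
    test = _chained_fixture(seed=9, n=200)
    draws = np.concatenate(
        [t["a"][test["a"].isna()].to_numpy() for t in imp.transform_multi(test)]
    )
    assert np.mean(draws) == pytest.approx(train["a"].mean(), abs=0.2)
    sd = train["a"].std()
    assert np.std(draws) == pytest.approx(sd, rel=0.25)


def test_lasso_multiclass_levels_valid():
    train = _chained_fixture(seed=10)
    imp = LassoBootstrapImputer(m=5, chained_iters=2, seed=11).fit(train)
    test = _chained_fixture(seed=12, n=100)
    for t in imp.transform_multi(test):
        assert set(t["c"].dropna()).issubset({"lo", "mid", "hi"})
        assert t["c"].notna().all()


def test_fitted_state_is_train_only_and_deterministic():
    """Refitting on the same training data yields byte-identical state and
    identical imputations of new rows, regardless of what the test rows
    contain."""
    train = _chained_fixture(seed=13)
    test_a = _chained_fixture(seed=14, n=80)
    imp1 = BayesianPMMImputer(m=3, chained_iters=2, seed=5).fit(train)
    imp2 = BayesianPMMImputer(m=3, chained_iters=2, seed=5).fit(train)
    for j, st1 in imp1.models_.items():
        np.testing.assert_array_equal(st1["beta"], imp2.models_[j]["beta"])
        np.testing.assert_array_equal(st1["y_obs"], imp2.models_[j]["y_obs"])
    out1 = imp1.transform_multi(test_a)
    out2 = imp2.transform_multi(test_a)
    for a, b in zip(out1, out2):
        pd.testing.assert_frame_equal(a, b)


def test_single_row_application():
    train = _chained_fixture(seed=15)
    imp = RandomForestDonorImputer(m=2, chained_iters=2, seed=16).fit(train)
    row = _chained_fixture(seed=17, n=30).iloc[[0]]
    row.loc[:, "a"] = np.nan
    out = imp.transform(row)
    assert out["a"].notna().all()
    vals = imp.draw_for_variable("a", row)
    assert vals.shape == (1,)
    assert vals[0] in set(train["a"].dropna())


def test_mean_imputation_shrinks_variance():
    train = _chained_fixture(seed=18)
    imp = MeanModeImputer().fit(train)
    out = imp.transform(train)
    assert out["a"].var() < train["a"].dropna().var()


def test_averaging_reduces_expected_squared_error():
    """The average of m imputations has lower squared error against the
    truth than single imputations, on average (ensembling)."""
    rng = np.random.default_rng(19)
    n = 400
    z = rng.standard_normal(n)
    truth = pd.DataFrame(
        {"a": 2 * z, "b": z + rng.normal(0, 0.3, n)},
        index=_mi([(i // 20, i % 20 + 1) for i in range(n)]),
    )
    gappy = truth.copy()
    miss = rng.random(n) < 0.3
    gappy.loc[miss, "a"] = np.nan
    imp = BayesianPMMImputer(m=10, chained_iters=2, seed=20).fit(gappy)
    tables = imp.transform_multi(gappy)
    avg = average_imputations(tables)
    err_avg = np.mean((avg.loc[miss, "a"] - truth.loc[miss, "a"]) ** 2)
    err_single = np.mean(
        [np.mean((t.loc[miss, "a"] - truth.loc[miss, "a"]) ** 2) for t in tables]
    )
    assert err_avg < err_single


def test_make_imputer_dispatch():
    for method in ("mean", "locf", "none", "rf_donor", "bayes_pmm", "lasso_boot"):
        imp = make_imputer(ImputerSpec(method=method))
        assert imp.method == method


def test_no_missing_is_identity_for_every_method():
    X = _chained_fixture(seed=21).dropna()
    for method in ("mean", "locf", "none", "rf_donor", "bayes_pmm", "lasso_boot"):
        imp = fit_imputer(ImputerSpec(method=method, m=2, chained_iters=1, seed=0), X)
        out = imp.transform(X)
        pd.testing.assert_frame_equal(out, X, check_categorical=False)
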