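"""Windowing: collapse semantics, eligibility, lag construction, labels."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_window_table, tiny_census
from gapbench.census import default_census
from gapbench.cohort import RawObservationTable
from gapbench.windows import (
    WindowSpec,
    assign_labels,
    build_lagged_matrix,
    collapse_to_windows,
    filter_eligible_events,
    propagate_mask_to_lagged,
)


def _raw(obs_rows, events_rows):
    obs = pd.DataFrame(obs_rows, columns=["event_id", "timestamp", "variable", "value"])
    obs["patient_id"] = obs["event_id"]
    obs["timestamp"] = pd.to_datetime(obs["timestamp"])
    ev = pd.DataFrame(
        events_rows,
        columns=["patient_id", "event_id", "intubation_time", "extubation_time", "success"],
    )
    for c in ("intubation_time", "extubation_time"):
        ev[c] = pd.to_datetime(ev[c])
    ev["duration_hours"] = (
        ev["extubation_time"] - ev["intubation_time"]
    ).dt.total_seconds() / 3600.0
    return RawObservationTable(observations=obs, events=ev)


def test_first_eligible_window_ends_12h_after_intubation():
    """A patient intubated at 17:27 on 5/6/2018: the first modeling
    window (index 3) ends at 05:27 on 5/7/2018."""
    raw = _raw(
        [(0, "2018-05-07 05:00", "pulse", 120.0)],
        [(0, 0, "2018-05-06 17:27", "2018-05-08 08:45", 1)],
    )
    spec = WindowSpec()
    wt = collapse_to_windows(raw, tiny_census(), spec)
    intub = raw.events.loc[0, "intubation_time"]
    first_eligible = wt.data.index[wt.eligible][0]
    assert first_eligible == (0, 3)
    assert intub + pd.Timedelta(hours=3 * spec.width_hours) == pd.Timestamp(
        "2018-05-07 05:27"
    )
    assert spec.first_model_window_end_hours == 12.0
    # the 05:00 observation falls inside window 3 (01:27, 05:27]
    assert wt.data.loc[(0, 3), "pulse"] == 120.0


def test_collapse_mean_mode_and_missing():
    raw = _raw(
        [
            (0, "2020-01-01 01:00", "pulse", 120.0),
            (0, "2020-01-01 02:00", "pulse", 124.0),
            (0, "2020-01-01 01:00", "secretions", "small"),
            (0, "2020-01-01 02:00", "secretions", "large"),
            (0, "2020-01-01 03:00", "secretions", "large"),
            (0, "2020-01-01 05:00", "secretions", "none"),
            (0, "2020-01-01 06:00", "secretions", "small"),
        ],
        [(0, 0, "2020-01-01 00:00", "2020-01-02 04:00", 1)],
    )
    wt = collapse_to_windows(raw, tiny_census(), WindowSpec())
    assert wt.data.loc[(0, 1), "pulse"] == pytest.approx(122.0)  # mean of 120, 124
    assert pd.isna(wt.data.loc[(0, 2), "pulse"])  # no in-window observation
    assert wt.data.loc[(0, 1), "secretions"] == "large"  # mode
    # tie in window 2 between none and small -> most recent (small) wins
    assert wt.data.loc[(0, 2), "secretions"] == "small"


def test_half_open_window_boundaries():
    raw = _raw(
        [
            (0, "2020-01-01 04:00:00", "pulse", 100.0),  # boundary -> window 1
            (0, "2020-01-01 04:00:01", "lactate", 2.0),  # just past -> window 2
        ],
        [(0, 0, "2020-01-01 00:00", "2020-01-02 04:00", 1)],
    )
    wt = collapse_to_windows(raw, tiny_census(), WindowSpec())
    assert wt.data.loc[(0, 1), "pulse"] == 100.0
    assert pd.isna(wt.data.loc[(0, 2), "pulse"])
    assert wt.data.loc[(0, 2), "lactate"] == 2.0


def test_out_of_range_observations_dropped_with_warning():
    raw = _raw(
        [
            (0, "2019-12-31 23:00", "pulse", 99.0),  # before intubation
            (0, "2020-01-03 00:00", "pulse", 98.0),  # after extubation
            (0, "2020-01-01 01:00", "pulse", 100.0),
        ],
        [(0, 0, "2020-01-01 00:00", "2020-01-02 04:00", 1)],
    )
    with pytest.warns(UserWarning, match="dropped 2"):
        wt = collapse_to_windows(raw, tiny_census(), WindowSpec())
    assert wt.n_dropped_observations == 2
    assert wt.data.loc[(0, 1), "pulse"] == 100.0


def test_collapse_idempotent_on_windowed_data():
    """Collapsing data that already has one observation per window
    reproduces the same table."""
    rng = np.random.default_rng(3)
    values = rng.normal(80, 5, size=8)
    obs = [
        (0, pd.Timestamp("2020-01-01") + pd.Timedelta(hours=4 * k + 2), "pulse", v)
        for k, v in enumerate(values)
    ]
    raw = _raw(obs, [(0, 0, "2020-01-01 00:00", "2020-01-02 08:00", 1)])
    wt1 = collapse_to_windows(raw, tiny_census(), WindowSpec())
    obs2 = [
        (0, pd.Timestamp("2020-01-01") + pd.Timedelta(hours=4 * k + 2), "pulse", v)
        for k, v in enumerate(wt1.data["pulse"].to_numpy())
    ]
    raw2 = _raw(obs2, [(0, 0, "2020-01-01 00:00", "2020-01-02 08:00", 1)])
    wt2 = collapse_to_windows(raw2, tiny_census(), WindowSpec())
    pd.testing.assert_frame_equal(wt1.data, wt2.data)


def test_eligibility_duration_and_age_rules():
    ev = pd.DataFrame(
        {
            "patient_id": [0, 1, 2, 3],
            "event_id": [0, 1, 2, 3],
            "duration_hours": [20.0, 24.5, 48.0, 24.0],
            "age_years": [5.0, 5.0, 19.0, 5.0],
            "intubation_time": pd.Timestamp("2020-01-01"),
        }
    )
    kept = filter_eligible_events(ev, WindowSpec())
    # 20 h excluded, 24.5 h retained, 19-year-old excluded, exactly 24 h excluded
    assert kept["event_id"].tolist() == [1]
    empty = filter_eligible_events(ev.iloc[0:0], WindowSpec())
    assert empty.empty


def test_wide_matrix_has_265_features_under_default_census():
    census = default_census()
    rng = np.random.default_rng(0)
    idx = pd.MultiIndex.from_product([[0], range(1, 8)])
    data = pd.DataFrame(
        {v.name: rng.normal(size=7) for v in census.variables}, index=idx
    )
    for v in census.variables:
        if v.kind == "categorical":
            data[v.name] = pd.Categorical(
                [v.levels[0]] * 7, categories=list(v.levels)
            )
    wt = make_window_table(data, census=census)
    lm = build_lagged_matrix(wt)
    assert lm.X.shape[1] == 265
    lm0 = build_lagged_matrix(wt, WindowSpec(n_lags=0))
    assert lm0.X.shape[1] == 99


def test_lag_columns_take_prior_window_values():
    idx = pd.MultiIndex.from_product([[0], [1, 2, 3, 4]])
    data = pd.DataFrame(
        {
            "age_years": 4.0,
            "pulse": [10.0, 20.0, 30.0, 40.0],
            "lactate": [1.0, 2.0, 3.0, 4.0],
            "ett_size": 5.0,
            "secretions": "none",
            "cough": 0.0,
        },
        index=idx,
    )
    wt = make_window_table(data)
    lm = build_lagged_matrix(wt)
    assert list(lm.X.index) == [(0, 3), (0, 4)]
    assert lm.X.loc[(0, 3), "pulse"] == 30.0
    assert lm.X.loc[(0, 3), "pulse_lag1"] == 20.0
    assert lm.X.loc[(0, 3), "pulse_lag2"] == 10.0
    # an event shorter than n_lags+1 windows contributes no rows
    short = make_window_table(data.iloc[:2])
    assert build_lagged_matrix(short).X.empty


def test_labels_terminal_outcome_and_leads():
    idx = pd.MultiIndex.from_product([[0], range(1, 7)])
    data = pd.DataFrame(
        {
            "age_years": 4.0,
            "pulse": 1.0,
            "lactate": 1.0,
            "ett_size": 5.0,
            "secretions": "none",
            "cough": 0.0,
            "sbp_percentile": [50.0, 55.0, 60.0, 65.0, 70.0, 75.0],
        },
        index=idx,
    )
    wt = make_window_table(data)
    wt.events["success"] = 1
    out = assign_labels(wt)
    # event has 6 windows (24 h): window 3's horizon (window 6) reaches the
    # end -> terminal outcome; windows 1-2 horizons are pre-extubation -> 0
    assert out.labels.loc[(0, 3), "success_label"] == 1
    assert out.labels.loc[(0, 2), "success_label"] == 0
    # failure event: terminal label 0 everywhere at/past the horizon
    wt.events["success"] = 0
    out_f = assign_labels(wt)
    assert out_f.labels["success_label"].sum() == 0
    # continuous label is the blood-pressure percentile one window later
    assert out.labels.loc[(0, 3), "bp_label"] == 65.0
    assert np.isnan(out.labels.loc[(0, 6), "bp_label"])


def test_mask_propagation_matches_shifted_base_mask(small_prep):
    _, prep = small_prep
    wt = prep.window_table
    mask = pd.DataFrame(False, index=wt.data.index, columns=wt.data.columns)
    eid = wt.data.index.get_level_values(0)[0]
    mask.loc[(eid, 2), "sbp_percentile"] = True
    wide = propagate_mask_to_lagged(mask, wt)
    assert bool(wide.loc[(eid, 3), "sbp_percentile_lag1"])
    assert bool(wide.loc[(eid, 4), "sbp_percentile_lag2"])
    assert not wide.loc[(eid, 3), "sbp_percentile"]
    # mask is confined to the amputed base cells and their lag copies
    assert int(wide.to_numpy().sum()) == 2
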