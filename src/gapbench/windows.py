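"""Collapse raw observations into 4-hour windows and build the wide matrix.

Windows are indexed 1-based from intubation; window ``k`` covers the
half-open interval ``(intubation + 4(k-1) h, intubation + 4k h]``.  The
first ``n_lags`` windows exist only to supply lagged features and are not
eligible modeling rows, so the first modeling window ends
``width * (n_lags + 1)`` hours after intubation (12 h by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .census import CATEGORICAL, VariableCensus

DAYS_30 = 30.0 / 365.25


@dataclass(frozen=True)
class WindowSpec:
    width_hours: float = 4.0
    min_duration_hours: float = 24.0
    n_lags: int = 2
    binary_label_lead: int = 3  # windows (12 h)
    continuous_label_lead: int = 1  # windows (4 h)

    @property
    def first_model_window_end_hours(self) -> float:
        return self.width_hours * (self.n_lags + 1)

    def __post_init__(self) -> None:
        if self.binary_label_lead < 1 or self.continuous_label_lead < 1:
            raise ValueError("label leads must be >= 1 window")


@dataclass
class WindowTable:
    """Windowed table: one row per (event, window), one column per variable."""

    data: pd.DataFrame  # MultiIndex (event_id, window_index)
    census: VariableCensus
    spec: WindowSpec
    events: pd.DataFrame
    eligible: pd.Series = None
    partial: pd.Series = None
    labels: pd.DataFrame | None = None
    n_dropped_observations: int = 0

    def __post_init__(self) -> None:
        if self.eligible is None:
            widx = self.data.index.get_level_values("window_index")
            self.eligible = pd.Series(widx >= self.spec.n_lags + 1, index=self.data.index)
        if self.partial is None:
            self.partial = pd.Series(False, index=self.data.index)

    def copy(self) -> "WindowTable":
        return WindowTable(
            data=self.data.copy(),
            census=self.census,
            spec=self.spec,
            events=self.events.copy(),
            eligible=self.eligible.copy(),
            partial=self.partial.copy(),
            labels=None if self.labels is None else self.labels.copy(),
            n_dropped_observations=self.n_dropped_observations,
        )

    def missing_cell_count(self) -> int:
        return int(self.data.isna().to_numpy().sum())


def filter_eligible_events(events: pd.DataFrame, spec: WindowSpec) -> pd.DataFrame:
    """Keep events intubated for more than ``min_duration_hours`` and, when
    ages are present, aged more than 30 days and under 18 years."""
    if events.empty:
        return events.copy()
    keep = events["duration_hours"] > spec.min_duration_hours
    if "age_years" in events.columns:
        keep &= (events["age_years"] > DAYS_30) & (events["age_years"] < 18.0)
    return events.loc[keep].reset_index(drop=True)


def _collapse_categorical(obs: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mode with ties broken toward the most recent observation."""
    obs = obs.sort_values("timestamp", kind="stable").reset_index(drop=True)
    obs["order"] = np.arange(len(obs))
    g = (
        obs.groupby(["event_id", "window_index", "variable", "value"], sort=False)
        .agg(n=("order", "size"), last=("order", "max"))
        .reset_index()
        .sort_values(["n", "last"], kind="stable")
    )
    winners = g.drop_duplicates(["event_id", "window_index", "variable"], keep="last")
    return winners[["event_id", "window_index", "variable", "value"]]


def collapse_to_windows(raw, census: VariableCensus, spec: WindowSpec) -> WindowTable:
    """Collapse raw observations: mean for numeric/binary cells, mode for
    categorical cells; a cell is missing iff no in-window observation.

    Static variables are broadcast to every window of their event.
    Observations outside ``(intubation, extubation]`` are dropped (counted).
    """
    events = raw.events.reset_index(drop=True)
    obs = raw.observations.merge(
        events[["event_id", "intubation_time", "extubation_time", "duration_hours"]],
        on="event_id",
        how="inner",
    )
    rel_h = (
        (obs["timestamp"] - obs["intubation_time"]).dt.total_seconds().to_numpy() / 3600.0
    )
    in_range = (rel_h > 0) & (obs["timestamp"] <= obs["extubation_time"])
    n_dropped = int((~in_range).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} observations outside the intubation period")
    obs = obs.loc[in_range].copy()
    obs["window_index"] = np.ceil(rel_h[in_range] / spec.width_hours).astype(int)

    n_windows = np.ceil(events["duration_hours"].to_numpy() / spec.width_hours).astype(int)
    full_index = pd.MultiIndex.from_tuples(
        [
            (eid, k)
            for eid, K in zip(events["event_id"], n_windows)
            for k in range(1, int(K) + 1)
        ],
        names=["event_id", "window_index"],
    )

    kinds = census.kinds()
    is_cat = obs["variable"].map(kinds).eq(CATEGORICAL)
    frames = []
    num = obs.loc[~is_cat].copy()
    if not num.empty:
        num["value"] = pd.to_numeric(num["value"])
        wide_num = num.pivot_table(
            index=["event_id", "window_index"],
            columns="variable",
            values="value",
            aggfunc="mean",
        )
        frames.append(wide_num)
    cat = obs.loc[is_cat, ["event_id", "window_index", "variable", "value", "timestamp"]]
    if not cat.empty:
        winners = _collapse_categorical(cat)
        wide_cat = winners.pivot(
            index=["event_id", "window_index"], columns="variable", values="value"
        )
        frames.append(wide_cat)

    wide = pd.concat(frames, axis=1) if frames else pd.DataFrame(index=full_index)
    wide = wide.reindex(index=full_index, columns=census.names)
    for v in census.variables:
        if v.kind == CATEGORICAL:
            wide[v.name] = pd.Categorical(wide[v.name], categories=list(v.levels))

    static_cols = [v.name for v in census.statics]
    if static_cols:
        grouped = wide[static_cols].groupby(level="event_id", group_keys=False)
        wide[static_cols] = grouped.apply(lambda g: g.ffill().bfill())

    # partial flag: last window of an event extends past extubation
    last_flags = {}
    for eid, K, dur in zip(events["event_id"], n_windows, events["duration_hours"]):
        last_flags[(eid, int(K))] = bool(K * spec.width_hours > dur + 1e-9)
    partial = pd.Series(
        [last_flags.get(ix, False) for ix in full_index], index=full_index
    )

    return WindowTable(
        data=wide,
        census=census,
        spec=spec,
        events=events,
        eligible=None,
        partial=partial,
        n_dropped_observations=n_dropped,
    )


def assign_labels(wt: WindowTable, events: pd.DataFrame | None = None, spec: WindowSpec | None = None) -> WindowTable:
    """Attach outcome labels to each window row.

    Binary label at window ``k`` is the extubation-success status evaluated
    at the end of window ``k + binary_label_lead``: if the event has
    terminated by then, the event's terminal binary outcome; otherwise 0
    (still intubated, hence not successfully extubated at that horizon).
    The continuous label is the blood-pressure percentile of window
    ``k + continuous_label_lead`` (absent past the last window).
    """
    events = wt.events if events is None else events
    spec = wt.spec if spec is None else spec
    if "success" not in events.columns:
        raise ValueError("event table lacks outcome information")
    ev = events.set_index("event_id")
    eid = wt.data.index.get_level_values("event_id")
    widx = wt.data.index.get_level_values("window_index").to_numpy()
    duration = ev.loc[eid, "duration_hours"].to_numpy()
    success = ev.loc[eid, "success"].to_numpy()

    horizon_h = (widx + spec.binary_label_lead) * spec.width_hours
    terminated = duration <= horizon_h + 1e-9
    success_label = np.where(terminated, success, 0).astype(int)

    bp = wt.data["sbp_percentile"] if "sbp_percentile" in wt.data.columns else None
    if bp is not None:
        bp_lead = bp.groupby(level="event_id").shift(-spec.continuous_label_lead)
        bp_label = bp_lead.to_numpy(dtype=float)
    else:
        bp_label = np.full(len(wt.data), np.nan)

    out = wt.copy()
    out.labels = pd.DataFrame(
        {"success_label": success_label, "bp_label": bp_label}, index=wt.data.index
    )
    return out


@dataclass
class LaggedMatrix:
    """Wide modeling matrix: statics once, each time-varying variable with
    its current value and ``n_lags`` lagged copies as distinct columns."""

    X: pd.DataFrame  # index (event_id, window_index), eligible rows only
    labels: pd.DataFrame | None
    col_meta: pd.DataFrame  # index: column; fields base, lag, kind, static

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


def build_lagged_matrix(wt: WindowTable, spec: WindowSpec | None = None) -> LaggedMatrix:
    """Build the wide matrix (265 features under the default census).

    Lagged cells inherit the base window's value — and hence its
    missingness — exactly.  Only rows with ``window_index >= n_lags + 1``
    are kept; events shorter than ``n_lags + 1`` windows contribute none.
    """
    spec = wt.spec if spec is None else spec
    data = wt.data.sort_index()
    tv = [v.name for v in wt.census.time_varying]
    statics = [v.name for v in wt.census.statics]

    pieces = [data[statics], data[tv]]
    meta_rows = [
        {"column": c, "base": c, "lag": 0, "kind": wt.census.kind_of(c), "static": True}
        for c in statics
    ] + [
        {"column": c, "base": c, "lag": 0, "kind": wt.census.kind_of(c), "static": False}
        for c in tv
    ]
    for lag in range(1, spec.n_lags + 1):
        shifted = data[tv].groupby(level="event_id").shift(lag)
        shifted.columns = [f"{c}_lag{lag}" for c in tv]
        pieces.append(shifted)
        meta_rows += [
            {
                "column": f"{c}_lag{lag}",
                "base": c,
                "lag": lag,
                "kind": wt.census.kind_of(c),
                "static": False,
            }
            for c in tv
        ]
    X = pd.concat(pieces, axis=1)
    keep = X.index.get_level_values("window_index") >= spec.n_lags + 1
    X = X.loc[keep]
    labels = None
    if wt.labels is not None:
        labels = wt.labels.loc[keep].copy()
    col_meta = pd.DataFrame(meta_rows).set_index("column")
    return LaggedMatrix(X=X, labels=labels, col_meta=col_meta)


def propagate_mask_to_lagged(mask: pd.DataFrame, wt: WindowTable, spec: WindowSpec | None = None) -> pd.DataFrame:
    """Map a window-level boolean mask onto the lagged wide matrix: each
    lagged column inherits exactly the base variable's mask shifted by its
    lag (amputation precedes lag construction)."""
    spec = wt.spec if spec is None else spec
    mask = mask.sort_index()
    tv = [v.name for v in wt.census.time_varying]
    statics = [v.name for v in wt.census.statics]
    pieces = [mask[statics], mask[tv]]
    for lag in range(1, spec.n_lags + 1):
        shifted = mask[tv].groupby(level="event_id").shift(lag, fill_value=False)
        shifted.columns = [f"{c}_lag{lag}" for c in tv]
        pieces.append(shifted)
    wide = pd.concat(pieces, axis=1).astype(bool)
    keep = wide.index.get_level_values("window_index") >= spec.n_lags + 1
    return wide.loc[keep]
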