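"""Synthetic PICU-like cohort generation.

Emulates the structure of an intensive-care EHR extract around intubation
events: a long raw-observation table (patient, event, timestamp, variable,
value), an event table with intubation/extubation times, and outcome
labels.  The generative model is a stand-in — no joint distribution of the
real variables is claimed — but it reproduces the structural features the
downstream experiment depends on:

* per-event latent severity following a stationary AR(1) process on the
  4-hour window grid, on which every time-varying variable loads linearly
  (cross-variable correlation);
* per-variable lag-1 autocorrelation targeted to a configurable coefficient
  rho (binary and categorical variables are thresholded / binned latent
  Gaussians, keeping autocorrelation meaningful for all kinds);
* intubation durations log-normal with parameters solved from the target
  median and IQR (defaults 4.4 and (2.2, 8.5) days);
* a binary extubation-success outcome from a logistic model on late-window
  severity, with the intercept solved by bisection to hit a target
  prevalence (default 76.1%);
* a continuous systolic-blood-pressure-percentile series emitted directly
  as a time-varying variable (the percentile reference computation itself
  is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .census import BINARY, CATEGORICAL, NUMERIC, VariableCensus, default_census

HOURS_PER_DAY = 24.0
_Q75 = norm.ppf(0.75)  # 0.6745

#: split of non-success outcome categories, proportional to a PICU census
#: (reintubation within 48 h, death, tracheostomy, transfer, ETT change)
FAILURE_CATEGORIES = ("failure", "death", "tracheostomy", "transfer", "ett_change")
FAILURE_CATEGORY_WEIGHTS = (100, 96, 36, 25, 34)


def lognormal_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    """Solve (mu, sigma) of a log-normal from its median and (q25, q75).

    mu = log(median); sigma from the IQR ratio, since
    q75/q25 = exp(2 * 0.6745 * sigma) for a log-normal.
    """
    if median <= 0 or iqr[0] <= 0 or iqr[1] <= iqr[0]:
        raise ValueError("need positive median and q25 < q75")
    mu = float(np.log(median))
    sigma = float(np.log(iqr[1] / iqr[0]) / (2.0 * _Q75))
    return mu, sigma


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator."""

    n_patients: int = 886
    reintubation_prob: float = 0.377  # extra events per patient -> ~1220 events
    duration_median_days: float = 4.4
    duration_iqr_days: tuple[float, float] = (2.2, 8.5)
    min_duration_hours: float = 6.0  # floor; eligibility filtering happens later
    census: VariableCensus = field(default_factory=default_census)
    ar1_range: tuple[float, float] = (0.2, 0.95)
    latent_loading_range: tuple[float, float] = (0.2, 0.6)
    severity_ar1: float = 0.9
    noise_sd: float = 0.05  # measurement noise on the latent z scale
    outcome_slope: float = -1.2  # logistic slope on late-window mean severity
    target_success: float = 0.761
    bp_center: float = 50.0  # sbp percentile = center + scale * z, clipped
    bp_scale: float = 20.0
    age_median_years: float = 4.3
    age_iqr_years: tuple[float, float] = (1.0, 12.1)
    female_prob: float = 0.457
    window_hours: float = 4.0
    study_start: str = "2013-01-01"
    study_end: str = "2023-03-31"
    original_missingness: tuple[str, float] | None = None  # (mechanism, proportion)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        lo, hi = self.ar1_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("ar1_range must lie in [0, 1)")
        if not (0.0 < self.target_success < 1.0):
            raise ValueError("target_success must be in (0, 1)")
        if not (0.0 <= self.reintubation_prob < 1.0):
            raise ValueError("reintubation_prob must be in [0, 1)")


@dataclass
class RawObservationTable:
    """Long-format raw observations plus the event table."""

    observations: pd.DataFrame  # patient_id, event_id, timestamp, variable, value
    events: pd.DataFrame  # patient_id, event_id, intubation_time, extubation_time,
    #                       duration_hours, age_years, outcome_category, success

    def write(self, obs_path, events_path) -> None:
        self.observations.to_csv(obs_path, index=False)
        self.events.to_csv(events_path, index=False)

    @classmethod
    def read(cls, obs_path, events_path) -> "RawObservationTable":
        obs = pd.read_csv(obs_path, parse_dates=["timestamp"])
        ev = pd.read_csv(events_path, parse_dates=["intubation_time", "extubation_time"])
        return cls(obs, ev)


def calibrate_outcome_intercept(
    coefs, target_prevalence: float, severity: np.ndarray | None = None
) -> float:
    """Solve the logistic intercept so that mean(expit(b0 + X @ coefs)) hits
    the target prevalence, by bisection (Brent) on b0.

    ``severity`` is the sample of linear-predictor covariates (1-D for a
    single slope).  With all-zero slopes this reduces to logit(target).
    """
    if not (0.0 < target_prevalence < 1.0):
        raise ValueError("target prevalence must be in (0, 1)")
    coefs = np.atleast_1d(np.asarray(coefs, dtype=float))
    if severity is None:
        severity = np.zeros((1, coefs.size))
    sev = np.asarray(severity, dtype=float)
    if sev.ndim == 1:
        sev = sev[:, None]
    scores = sev @ coefs

    def prevalence_gap(b0: float) -> float:
        return float(np.mean(expit(b0 + scores))) - target_prevalence

    lo, hi = -40.0, 40.0
    if prevalence_gap(lo) > 0 or prevalence_gap(hi) < 0:
        raise ValueError("target prevalence unattainable given coefficient scale")
    if np.allclose(scores, 0.0):
        return float(logit(target_prevalence))
    return float(brentq(prevalence_gap, lo, hi, xtol=1e-10))


def _ar1_path(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) path with unit marginal variance."""
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov_sd = np.sqrt(1.0 - rho * rho)
    eps = rng.standard_normal(n)
    for k in range(1, n):
        x[k] = rho * x[k - 1] + innov_sd * eps[k]
    return x


def _ar1_matrix(n: int, rhos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """(n, len(rhos)) matrix of independent stationary AR(1) columns."""
    m = rhos.size
    x = np.empty((n, m))
    x[0] = rng.standard_normal(m)
    innov_sd = np.sqrt(1.0 - rhos * rhos)
    eps = rng.standard_normal((n, m))
    for k in range(1, n):
        x[k] = rhos * x[k - 1] + innov_sd * eps[k]
    return x


@dataclass
class _VariableParams:
    """Per-variable draw of the generative parameters (seed-determined)."""

    rho: np.ndarray  # target lag-1 autocorrelation, time-varying vars
    rho_noise: np.ndarray  # AR(1) coefficient of the idiosyncratic part
    loading: np.ndarray  # loading on the latent severity process
    mu: np.ndarray  # location of numeric variables
    sigma: np.ndarray  # scale of numeric variables
    binary_threshold: np.ndarray  # z threshold for binary vars (NaN otherwise)
    cutpoints: dict[str, np.ndarray]  # z cutpoints for categorical vars


def _draw_variable_params(cfg: GeneratorConfig, rng: np.random.Generator) -> _VariableParams:
    tv = cfg.census.time_varying
    n = len(tv)
    rho = rng.uniform(*cfg.ar1_range, size=n)
    loading = rng.uniform(*cfg.latent_loading_range, size=n)
    # choose the idiosyncratic AR(1) coefficient so the variable's marginal
    # lag-1 autocorrelation matches rho despite the severity component
    lam2 = loading * loading
    rho_noise = np.clip((rho - lam2 * cfg.severity_ar1) / (1.0 - lam2), 0.0, 0.99)
    mu = rng.uniform(10.0, 120.0, size=n)
    sigma = rng.uniform(1.0, 15.0, size=n)
    thr = np.full(n, np.nan)
    cutpoints: dict[str, np.ndarray] = {}
    for i, v in enumerate(tv):
        if v.name == "sbp_percentile":
            mu[i], sigma[i] = cfg.bp_center, cfg.bp_scale
        if v.kind == BINARY:
            thr[i] = norm.ppf(1.0 - rng.uniform(0.15, 0.85))
        elif v.kind == CATEGORICAL:
            # random level proportions -> z cutpoints
            props = rng.dirichlet(np.full(len(v.levels), 4.0))
            cutpoints[v.name] = norm.ppf(np.cumsum(props)[:-1])
    return _VariableParams(rho, rho_noise, loading, mu, sigma, thr, cutpoints)


def _simulate_event_table(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    mu_d, sigma_d = lognormal_params(cfg.duration_median_days, cfg.duration_iqr_days)
    mu_a, sigma_a = lognormal_params(cfg.age_median_years, cfg.age_iqr_years)
    start = pd.Timestamp(cfg.study_start)
    end = pd.Timestamp(cfg.study_end)
    span_h = (end - start).total_seconds() / 3600.0

    rows = []
    event_id = 0
    for pid in range(cfg.n_patients):
        age = float(np.clip(np.exp(rng.normal(mu_a, sigma_a)), 30.0 / 365.0, 17.9))
        female = int(rng.random() < cfg.female_prob)
        n_events = 1 + int(rng.random() < cfg.reintubation_prob)
        t = start + pd.Timedelta(hours=float(rng.uniform(0.0, span_h)))
        for _ in range(n_events):
            dur_h = max(
                cfg.min_duration_hours,
                float(np.exp(rng.normal(mu_d, sigma_d)) * HOURS_PER_DAY),
            )
            rows.append(
                {
                    "patient_id": pid,
                    "event_id": event_id,
                    "intubation_time": t,
                    "extubation_time": t + pd.Timedelta(hours=dur_h),
                    "duration_hours": dur_h,
                    "age_years": age,
                    "sex_female": female,
                }
            )
            event_id += 1
            gap_h = float(rng.uniform(72.0, 24.0 * 90))
            t = t + pd.Timedelta(hours=dur_h + gap_h)
    return pd.DataFrame(rows)


def simulate_events_and_outcomes(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Event table with calibrated outcomes plus per-event severity paths.

    This is the fast path shared by :func:`generate_cohort`: it simulates
    the event skeleton (durations, latent severity on the window grid) and
    draws the binary outcome from the calibrated logistic model, without
    materialising per-variable raw observations.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    events = _simulate_event_table(cfg, rng)
    n_windows = np.ceil(events["duration_hours"].to_numpy() / cfg.window_hours).astype(int)
    severities = [_ar1_path(max(k, 1), cfg.severity_ar1, rng) for k in n_windows]
    late_sev = np.array([s[-3:].mean() for s in severities])

    intercept = calibrate_outcome_intercept(
        [cfg.outcome_slope], cfg.target_success, severity=late_sev
    )
    p_success = expit(intercept + cfg.outcome_slope * late_sev)
    success = (rng.random(len(events)) < p_success).astype(int)

    cat_w = np.asarray(FAILURE_CATEGORY_WEIGHTS, float)
    cat_w /= cat_w.sum()
    categories = np.where(success == 1, "success", "").astype(object)
    n_fail = int((success == 0).sum())
    if n_fail:
        categories[success == 0] = rng.choice(FAILURE_CATEGORIES, size=n_fail, p=cat_w)
    events = events.assign(
        n_windows=n_windows, success=success, outcome_category=categories
    )
    return events, severities


def _static_values(
    cfg: GeneratorConfig,
    events: pd.DataFrame,
    severities: list[np.ndarray],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One row per event with every static census variable's value."""
    n = len(events)
    mean_sev = np.array([s.mean() for s in severities])
    out = {"event_id": events["event_id"].to_numpy()}
    for v in cfg.census.statics:
        if v.name == "age_years":
            out[v.name] = events["age_years"].to_numpy()
        elif v.name == "sex_female":
            out[v.name] = events["sex_female"].to_numpy().astype(float)
        elif v.name == "race_ethnicity" or (v.kind == CATEGORICAL):
            if v.name == "race_ethnicity":
                probs = np.array([117, 67, 340, 88, 229], float)
                probs /= probs.sum()
            else:
                probs = np.full(len(v.levels), 1.0 / len(v.levels))
            out[v.name] = rng.choice(list(v.levels), size=n, p=probs)
        elif v.formula == "ett_from_age":
            out[v.name] = events["age_years"].to_numpy() / 4.0 + 4.0 + rng.normal(
                0.0, 0.1, size=n
            )
        elif v.kind == BINARY:
            out[v.name] = (rng.random(n) < 0.3).astype(float)
        else:  # numeric admission measure, correlated with mean severity
            lam = rng.uniform(*cfg.latent_loading_range)
            z = lam * mean_sev + np.sqrt(1 - lam * lam) * rng.standard_normal(n)
            out[v.name] = rng.uniform(10, 120) + rng.uniform(1, 15) * z
    return pd.DataFrame(out)


def generate_cohort(cfg: GeneratorConfig) -> RawObservationTable:
    """Generate the full raw-observation cohort, deterministic given seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    events, severities = simulate_events_and_outcomes(cfg, rng)
    params = _draw_variable_params(cfg, rng)
    statics = _static_values(cfg, events, severities, rng)

    tv = cfg.census.time_varying
    tv_names = np.array([v.name for v in tv])
    tv_kinds = [v.kind for v in tv]
    cadences = np.array([v.cadence_hours for v in tv], dtype=float)

    obs_event, obs_var, obs_time_h, obs_value = [], [], [], []

    for row, sev in zip(events.itertuples(index=False), severities):
        K = int(row.n_windows)
        dur = float(row.duration_hours)
        noise = _ar1_matrix(K, params.rho_noise, rng)
        lam = params.loading
        z = lam * sev[:, None] + np.sqrt(1.0 - lam * lam) * noise  # (K, n_tv)
        for j, v in enumerate(tv):
            c = cadences[j]
            n_obs = int(dur // c)
            if n_obs == 0:
                n_obs = 1
            t = (np.arange(n_obs) + rng.uniform(0.05, 0.95, size=n_obs)) * c
            t = t[t <= dur]
            if t.size == 0:
                t = np.array([min(dur, 0.5 * c)])
            k_idx = np.minimum(np.ceil(t / cfg.window_hours).astype(int), K) - 1
            zz = z[k_idx, j] + cfg.noise_sd * rng.standard_normal(t.size)
            if tv_kinds[j] == NUMERIC:
                vals = params.mu[j] + params.sigma[j] * zz
                if v.name == "sbp_percentile":
                    vals = np.clip(vals, 1.0, 99.0)
            elif tv_kinds[j] == BINARY:
                vals = (zz > params.binary_threshold[j]).astype(float)
            else:
                codes = np.searchsorted(params.cutpoints[v.name], zz)
                vals = np.asarray(v.levels, dtype=object)[codes]
            obs_event.append(np.full(t.size, row.event_id))
            obs_var.append(np.full(t.size, v.name, dtype=object))
            obs_time_h.append(t)
            obs_value.append(np.asarray(vals, dtype=object))

    # statics: a single recording shortly after intubation
    static_cols = [v.name for v in cfg.census.statics]
    for row in statics.itertuples(index=False):
        vals = [getattr(row, c) for c in static_cols]
        obs_event.append(np.full(len(static_cols), row.event_id))
        obs_var.append(np.array(static_cols, dtype=object))
        obs_time_h.append(np.full(len(static_cols), 0.25))
        obs_value.append(np.array(vals, dtype=object))

    ev_indexed = events.set_index("event_id")
    eid = np.concatenate(obs_event)
    hours = np.concatenate(obs_time_h)
    intub = ev_indexed.loc[eid, "intubation_time"].to_numpy()
    timestamps = pd.to_datetime(intub) + pd.to_timedelta(hours, unit="h")
    observations = pd.DataFrame(
        {
            "patient_id": ev_indexed.loc[eid, "patient_id"].to_numpy(),
            "event_id": eid,
            "timestamp": timestamps,
            "variable": np.concatenate(obs_var),
            "value": np.concatenate(obs_value),
        }
    ).sort_values(["event_id", "timestamp"], kind="stable", ignore_index=True)

    return RawObservationTable(observations=observations, events=events.copy())


def induce_original_missingness(window_table, cfg: GeneratorConfig, seed: int | None = None):
    """Apply "original mode" missingness to a complete windowed table.

    Returns ``(gappy WindowTable, original_missing_flags)`` where the flags
    are a boolean frame aligned to the table's variable columns.  The gap
    pattern is produced by the amputation module at the configured
    mechanism and proportion (default MCAR at 0.182).
    """
    from .ampute import MissingnessScenario, ampute

    mechanism, proportion = cfg.original_missingness or ("MCAR", 0.182)
    if not (0.0 <= proportion < 1.0):
        raise ValueError("original missingness proportion must be in [0, 1)")
    if proportion == 0.0:
        flags = pd.DataFrame(
            False, index=window_table.data.index, columns=window_table.data.columns
        )
        return window_table, flags
    scenario = MissingnessScenario(
        mechanism=mechanism,
        level=1.0,
        base_cell_proportion=proportion,
        seed=cfg.seed if seed is None else seed,
    )
    gappy, mask = ampute(window_table, scenario)
    return gappy, mask.mask
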