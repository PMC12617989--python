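"""Drive the full factorial experiment: mechanism x level x replicate x
method x model x outcome, from a single config, with derived seeds and a
tidy evaluation report.

The seed scheme derives a child seed for every (outcome, scenario,
replicate, method) cell from the master seed, so any single cell is
reproducible in isolation and a rerun with the same master seed yields an
identical report.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ampute import LEVELS, MECHANISMS, MissingnessScenario, ampute
from .census import CATEGORICAL, VariableCensus, default_census, small_census
from .cohort import GeneratorConfig, generate_cohort, induce_original_missingness
from .complete import build_complete_table
from .impute import (
    DETERMINISTIC_METHODS,
    METHODS,
    ImputerSpec,
    LOCFImputer,
    MeanModeImputer,
    average_imputations,
    fit_imputer,
)
from .metrics import (
    classification_error,
    complete_sds,
    imputation_mse,
    prediction_metrics,
)
from .models import GradientBoostedModel, L1LinearModel, mi_ensemble_predict
from .windows import (
    WindowSpec,
    build_lagged_matrix,
    collapse_to_windows,
    filter_eligible_events,
    propagate_mask_to_lagged,
)


def child_seed(master: int, *keys) -> int:
    """Deterministic child seed below 2^31 from a master seed and a key
    path (counter-based; any experiment cell is reproducible alone)."""
    ints = [zlib.crc32(str(k).encode()) for k in keys]
    ss = np.random.SeedSequence([int(master)] + ints)
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class ExperimentConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    window_spec: WindowSpec = field(default_factory=WindowSpec)
    mechanisms: tuple = MECHANISMS
    levels: tuple = LEVELS
    replicates: int = 20
    base_proportion: float = 0.182
    methods: tuple = METHODS
    m: int = 30
    k_donors: int = 5
    n_trees: int = 10
    chained_iters: int = 5
    max_predictors: int | None = None
    max_fit_rows: int | None = None
    outcomes: tuple = ("binary", "continuous")
    models: tuple = ("gbt", "l1")
    mi_variant: bool = True
    two_stage: bool = True
    train_fraction: float = 0.75
    gbt_param_grid: dict | None = None
    l1_param_grid: dict | None = None
    gbt_n_estimators: int = 200
    cv_folds: int = 5
    out_dir: str | None = None
    master_seed: int = 0

    @property
    def n_scenarios(self) -> int:
        return len(self.mechanisms) * len(self.levels)


def desk_config(seed: int = 0) -> ExperimentConfig:
    """Desk-scale preset: a reduced census and cohort, 5 replicates,
    m=10 — small enough for a laptop CI run."""
    return ExperimentConfig(
        generator=GeneratorConfig(
            n_patients=60, reintubation_prob=0.3, census=small_census(10), seed=seed
        ),
        replicates=5,
        m=10,
        max_predictors=20,
        max_fit_rows=800,
        mi_variant=False,
        gbt_param_grid={"learning_rate": [0.05, 0.1], "num_leaves": [15]},
        gbt_n_estimators=100,
        master_seed=seed,
    )


def paper_config(seed: int = 0) -> ExperimentConfig:
    """Full-scale preset mirroring the study conditions: 886 patients,
    99-variable census, 20 replicates, 30 imputations."""
    return ExperimentConfig(
        generator=GeneratorConfig(seed=seed),
        max_predictors=30,
        master_seed=seed,
    )


def config_to_yaml(cfg: ExperimentConfig, path) -> None:
    d = asdict(cfg)
    d["generator"]["census"] = cfg.generator.census.to_records()
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_from_yaml(path) -> ExperimentConfig:
    d = yaml.safe_load(Path(path).read_text())
    gen = d.pop("generator", {})
    census_records = gen.pop("census", None)
    census = (
        VariableCensus.from_records(census_records)
        if census_records
        else default_census()
    )
    for tup_key in ("duration_iqr_days", "age_iqr_years", "ar1_range", "latent_loading_range"):
        if tup_key in gen and gen[tup_key] is not None:
            gen[tup_key] = tuple(gen[tup_key])
    generator = GeneratorConfig(census=census, **gen)
    wspec = WindowSpec(**d.pop("window_spec", {}))
    for tup_key in ("mechanisms", "levels", "methods", "outcomes", "models"):
        if tup_key in d and d[tup_key] is not None:
            d[tup_key] = tuple(d[tup_key])
    return ExperimentConfig(generator=generator, window_spec=wspec, **d)


def enumerate_scenarios(cfg: ExperimentConfig) -> list[tuple[str, float]]:
    """Deterministically ordered mechanism x level cross product."""
    if not cfg.mechanisms or not cfg.levels:
        raise ValueError("mechanism and level lists must be nonempty")
    return [(m, lvl) for m in cfg.mechanisms for lvl in cfg.levels]


def chronological_split(
    events: pd.DataFrame, train_fraction: float = 0.75
) -> tuple[list, list]:
    """Chronological 75/25 split by intubation date with patient
    exclusivity: earlier events train; a patient straddling the boundary
    follows their earliest event's partition."""
    if len(events) < 2:
        raise ValueError("need at least 2 events to split")
    ordered = events.sort_values("intubation_time", kind="stable")
    n_train = int(round(len(ordered) * train_fraction))
    n_train = min(max(n_train, 1), len(ordered) - 1)
    train_mask = np.zeros(len(ordered), dtype=bool)
    train_mask[:n_train] = True
    partition = pd.Series(train_mask, index=ordered["event_id"].to_numpy())
    first_partition = {}
    for eid, pid in zip(ordered["event_id"], ordered["patient_id"]):
        first_partition.setdefault(pid, partition[eid])
    resolved = np.array(
        [first_partition[pid] for pid in ordered["patient_id"]], dtype=bool
    )
    train_ids = ordered["event_id"].to_numpy()[resolved].tolist()
    test_ids = ordered["event_id"].to_numpy()[~resolved].tolist()
    return train_ids, test_ids


@dataclass
class PreparedData:
    """Complete ground-truth dataset plus the fixed train/test partition."""

    window_table: "WindowTable"  # complete, labelled
    lagged: "LaggedMatrix"
    original_missing: pd.DataFrame | None  # window-level flags
    original_missing_wide: pd.DataFrame | None
    events: pd.DataFrame
    train_ids: list
    test_ids: list
    sds: pd.Series
    numeric_wide: list[str]
    categorical_wide: list[str]


def prepare_complete_dataset(cfg: ExperimentConfig) -> PreparedData:
    from .windows import assign_labels

    raw = generate_cohort(cfg.generator)
    events = filter_eligible_events(raw.events, cfg.window_spec)
    raw.observations = raw.observations[
        raw.observations["event_id"].isin(events["event_id"])
    ]
    raw.events = events
    wt = collapse_to_windows(raw, cfg.generator.census, cfg.window_spec)

    # structural gaps (windows with no observation) are completed first so
    # the original-missingness stage starts from a complete table
    structural = wt.data.isna()
    wt = build_complete_table(
        wt, seed=child_seed(cfg.master_seed, "structural")
    ).table

    orig_flags = None
    if cfg.two_stage:
        wt, orig_flags = induce_original_missingness(
            wt, cfg.generator, seed=child_seed(cfg.master_seed, "original")
        )
        orig_flags = orig_flags | structural  # empty windows count as original gaps
        wt = build_complete_table(
            wt, seed=child_seed(cfg.master_seed, "complete")
        ).table
    wt = assign_labels(wt, events, cfg.window_spec)
    lagged = build_lagged_matrix(wt, cfg.window_spec)

    col_meta = lagged.col_meta
    numeric_wide = col_meta.index[col_meta["kind"] != CATEGORICAL].tolist()
    categorical_wide = col_meta.index[col_meta["kind"] == CATEGORICAL].tolist()
    sds = complete_sds(lagged.X, numeric_wide)
    train_ids, test_ids = chronological_split(events, cfg.train_fraction)

    orig_wide = None
    if orig_flags is not None:
        orig_wide = propagate_mask_to_lagged(orig_flags, wt, cfg.window_spec)
    return PreparedData(
        window_table=wt,
        lagged=lagged,
        original_missing=orig_flags,
        original_missing_wide=orig_wide,
        events=events,
        train_ids=train_ids,
        test_ids=test_ids,
        sds=sds,
        numeric_wide=numeric_wide,
        categorical_wide=categorical_wide,
    )


def _rows_for(X: pd.DataFrame, event_ids) -> pd.DataFrame:
    return X[X.index.get_level_values("event_id").isin(set(event_ids))]


def impute_dataset(
    method: str,
    cfg: ExperimentConfig,
    amputed_wt,
    lag_amp,
    train_ids,
    test_ids,
    seed: int,
):
    """Apply one handling method: returns (tables_train, tables_test,
    fitted imputer or None).  LOCF runs on the base window series and the
    lags are rebuilt, guaranteeing temporal consistency; the passthrough
    method returns the gappy matrix unchanged."""
    X = lag_amp.X
    Xtr, Xte = _rows_for(X, train_ids), _rows_for(X, test_ids)
    if method == "none":
        return [Xtr], [Xte], None
    if method == "locf":
        imputer = LOCFImputer().fit(Xtr)
        filled = amputed_wt.copy()
        filled.data = (
            amputed_wt.data.sort_index().groupby(level="event_id", group_keys=False).ffill()
        )
        lag_filled = build_lagged_matrix(filled, cfg.window_spec)
        Xf = lag_filled.X
        return [_rows_for(Xf, train_ids)], [_rows_for(Xf, test_ids)], imputer
    spec = ImputerSpec(
        method=method,
        m=cfg.m,
        k_donors=cfg.k_donors,
        n_trees=cfg.n_trees,
        chained_iters=cfg.chained_iters,
        max_predictors=cfg.max_predictors,
        max_fit_rows=cfg.max_fit_rows,
        seed=seed,
    )
    imputer = fit_imputer(spec, Xtr)
    return imputer.transform_multi(Xtr), imputer.transform_multi(Xte), imputer


def _complete_for_l1(tables: list[pd.DataFrame], fallback: MeanModeImputer) -> pd.DataFrame:
    avg = average_imputations(tables)
    if avg.isna().to_numpy().any():
        avg = fallback._transform_once(avg, None, 0)
    return avg


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run the full grid and return the tidy evaluation report.

    With ``cfg.out_dir`` set, per-(outcome, scenario, replicate) chunks
    are written as CSV and already-present chunks are skipped, making the
    run resumable.
    """
    prep = prepare_complete_dataset(cfg)
    Xc = prep.lagged.X
    labels = prep.lagged.labels
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    all_rows: list[dict] = []
    scenarios = enumerate_scenarios(cfg)
    for outcome in cfg.outcomes:
        y_all = labels["success_label"] if outcome == "binary" else labels["bp_label"]
        outcome_for_score = (
            prep.window_table.labels["success_label"]
            if outcome == "binary"
            else prep.window_table.labels["bp_label"].fillna(
                prep.window_table.labels["bp_label"].mean()
            )
        )
        for si, (mech, level) in enumerate(scenarios):
            for rep in range(cfg.replicates):
                chunk_path = (
                    out_dir / f"{outcome}_{mech}_{level}_{rep}.csv" if out_dir else None
                )
                if chunk_path is not None and chunk_path.exists():
                    all_rows.extend(pd.read_csv(chunk_path).to_dict("records"))
                    continue
                rows = _run_cell(
                    cfg, prep, Xc, y_all, outcome, outcome_for_score, mech, level, rep
                )
                if chunk_path is not None:
                    pd.DataFrame(rows).to_csv(chunk_path, index=False)
                all_rows.extend(rows)
    report = pd.DataFrame(all_rows)
    if out_dir:
        report.to_csv(out_dir / "report.csv", index=False)
    return report


def _run_cell(cfg, prep, Xc, y_all, outcome, outcome_for_score, mech, level, rep):
    base = dict(outcome=outcome, mechanism=mech, level=level, replicate=rep,
                stratum="")
    seed = child_seed(cfg.master_seed, outcome, mech, level, rep)
    scenario = MissingnessScenario(
        mechanism=mech, level=level, base_cell_proportion=cfg.base_proportion, seed=seed
    )
    amputed_wt, mmask = ampute(prep.window_table, scenario, outcome=outcome_for_score)
    lag_amp = build_lagged_matrix(amputed_wt, cfg.window_spec)
    mask_wide = propagate_mask_to_lagged(mmask.mask, amputed_wt, cfg.window_spec)

    task = "binary" if outcome == "binary" else "continuous"
    model_rows_ok = y_all.notna()
    rows: list[dict] = []
    rows.append({**base, "method": "", "variant": "", "model": "",
                 "partition": "", "metric": "achieved_cell_proportion",
                 "value": mmask.achieved_cell_proportion})

    for method in cfg.methods:
        mseed = child_seed(cfg.master_seed, outcome, mech, level, rep, method)
        tables_tr, tables_te, _ = impute_dataset(
            method, cfg, amputed_wt, lag_amp, prep.train_ids, prep.test_ids, mseed
        )
        avg_tr = average_imputations(tables_tr)
        avg_te = average_imputations(tables_te)

        # --- level 1: imputation accuracy --------------------------------
        if method != "none":
            for partition, avg, ids in (
                ("test", avg_te, prep.test_ids),
                ("train", avg_tr, prep.train_ids),
            ):
                sub_mask = _rows_for(mask_wide, ids)
                sub_complete = _rows_for(Xc, ids)
                try:
                    mse, _ = imputation_mse(sub_complete, avg, sub_mask, prep.sds)
                    rows.append({**base, "method": method, "variant": "averaged",
                                 "model": "", "partition": partition,
                                 "metric": "imputation_mse", "value": mse})
                except ValueError:
                    pass
                if prep.original_missing_wide is not None:
                    flags = _rows_for(prep.original_missing_wide, ids)
                    for label, strat_mask in (
                        ("originally_missing", sub_mask & flags),
                        ("not_originally_missing", sub_mask & ~flags),
                    ):
                        try:
                            smse, _ = imputation_mse(
                                sub_complete, avg, strat_mask, prep.sds
                            )
                        except ValueError:
                            continue
                        rows.append({**base, "stratum": label, "method": method,
                                     "variant": "averaged", "model": "",
                                     "partition": partition,
                                     "metric": "imputation_mse", "value": smse})
                if prep.categorical_wide:
                    try:
                        cerr, _ = classification_error(
                            sub_complete, avg, sub_mask, prep.categorical_wide
                        )
                        rows.append({**base, "method": method, "variant": "averaged",
                                     "model": "", "partition": partition,
                                     "metric": "classification_error", "value": cerr})
                    except ValueError:
                        pass

        # --- level 2: outcome-model performance ---------------------------
        tr_ok = _rows_for(pd.DataFrame(index=Xc.index).assign(ok=model_rows_ok), prep.train_ids)["ok"]
        te_ok = _rows_for(pd.DataFrame(index=Xc.index).assign(ok=model_rows_ok), prep.test_ids)["ok"]
        y_tr = _rows_for(y_all.to_frame("y"), prep.train_ids)["y"][tr_ok]
        y_te = _rows_for(y_all.to_frame("y"), prep.test_ids)["y"][te_ok]
        groups_tr = y_tr.index.get_level_values("event_id")
        fallback = MeanModeImputer().fit(avg_tr)

        for model_name in cfg.models:
            mod_seed = child_seed(cfg.master_seed, outcome, mech, level, rep, method, model_name)
            if model_name == "gbt":
                model = GradientBoostedModel(
                    task=task, cv_folds=cfg.cv_folds, param_grid=cfg.gbt_param_grid,
                    n_estimators=cfg.gbt_n_estimators, seed=mod_seed,
                )
                Xin_tr, Xin_te = avg_tr[tr_ok], avg_te[te_ok]
            else:
                if method == "none":
                    continue  # linear models cannot accommodate missing values
                model = L1LinearModel(
                    task=task, cv_folds=cfg.cv_folds, param_grid=cfg.l1_param_grid,
                    seed=mod_seed,
                )
                Xin_tr = _complete_for_l1([avg_tr], fallback)[tr_ok]
                Xin_te = _complete_for_l1([avg_te], fallback)[te_ok]
            try:
                model.fit(Xin_tr, y_tr.to_numpy(), groups=groups_tr)
            except ValueError as exc:
                warnings.warn(f"{model_name} fit failed for {method}: {exc}")
                continue
            for partition, Xin, y in (("test", Xin_te, y_te), ("train", Xin_tr, y_tr)):
                for metric, value in prediction_metrics(
                    y.to_numpy(), model.predict(Xin), task
                ).items():
                    rows.append({**base, "method": method, "variant": "averaged",
                                 "model": model_name, "partition": partition,
                                 "metric": metric, "value": value})

            # multiple-imputation variant: m models, averaged predictions
            if (
                cfg.mi_variant
                and method not in DETERMINISTIC_METHODS
                and method != "none"
                and len(tables_tr) > 1
                and model_name == "gbt"
            ):
                members = []
                for i, t in enumerate(tables_tr):
                    mm = GradientBoostedModel(
                        task=task, cv_folds=cfg.cv_folds, param_grid=cfg.gbt_param_grid,
                        n_estimators=cfg.gbt_n_estimators, seed=child_seed(mod_seed, i),
                    )
                    mm.fit(t[tr_ok], y_tr.to_numpy(), groups=groups_tr)
                    members.append(mm)
                for partition, tabs, y in (
                    ("test", [t[te_ok] for t in tables_te], y_te),
                    ("train", [t[tr_ok] for t in tables_tr], y_tr),
                ):
                    scores = mi_ensemble_predict(members, tabs)
                    for metric, value in prediction_metrics(y.to_numpy(), scores, task).items():
                        rows.append({**base, "method": method, "variant": "mi",
                                     "model": model_name, "partition": partition,
                                     "metric": metric, "value": value})
    return rows
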