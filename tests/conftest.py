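import numpy as np
import pandas as pd
import pytest

from gapbench.census import Variable, VariableCensus, small_census
from gapbench.cohort import GeneratorConfig
from gapbench.experiment import ExperimentConfig, desk_config, prepare_complete_dataset
from gapbench.windows import WindowSpec, WindowTable


def tiny_census() -> VariableCensus:
    return VariableCensus(
        [
            Variable("age_years", "numeric", static=True, amputable=False),
            Variable("pulse", "numeric", group=1, cadence_hours=1),
            Variable("lactate", "numeric", group=2, cadence_hours=4),
            Variable(
                "ett_size", "numeric", static=True, group=3, formula="ett_from_age"
            ),
            Variable(
                "secretions",
                "categorical",
                group=4,
                levels=("none", "small", "large"),
            ),
            Variable("cough", "binary", group=5, cadence_hours=2),
        ]
    )


def make_window_table(
    data: pd.DataFrame,
    census: VariableCensus | None = None,
    events: pd.DataFrame | None = None,
    spec: WindowSpec | None = None,
) -> WindowTable:
    """Assemble a WindowTable from a hand-built (event, window)-indexed
    frame, coercing categorical dtypes from the census."""
    census = census or tiny_census()
    spec = spec or WindowSpec()
    data = data.copy()
    data.index = data.index.set_names(["event_id", "window_index"])
    for v in census.variables:
        if v.kind == "categorical" and v.name in data.columns:
            data[v.name] = pd.Categorical(data[v.name], categories=list(v.levels))
    if events is None:
        eids = data.index.get_level_values("event_id").unique()
        sizes = data.groupby(level="event_id").size()
        events = pd.DataFrame(
            {
                "patient_id": range(len(eids)),
                "event_id": eids,
                "intubation_time": pd.Timestamp("2020-01-01"),
                "duration_hours": [sizes[e] * spec.width_hours for e in eids],
                "success": 1,
            }
        )
        events["extubation_time"] = events["intubation_time"] + pd.to_timedelta(
            events["duration_hours"], unit="h"
        )
    return WindowTable(data=data, census=census, spec=spec, events=events)


@pytest.fixture(scope="session")
def small_prep():
    """A complete desk-scale dataset shared across tests: ~40 events,
    10 time-varying variables, two-stage completion."""
    cfg = desk_config(seed=11)
    cfg.generator = GeneratorConfig(
        n_patients=30, reintubation_prob=0.3, census=small_census(8), seed=11
    )
    return cfg, prepare_complete_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
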