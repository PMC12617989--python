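"""Variable census: the catalogue of cohort variables and their roles.

The census describes every column of the windowed table: its measurement
kind (numeric, binary, categorical), whether it is static within an
intubation event, whether the amputer may remove it, and which of the five
missingness-pattern groups it belongs to.  The default census mirrors the
structure of a PICU extubation-readiness extract: 99 variables, 83 of them
time-varying, so that a wide matrix with two lags carries 265 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NUMERIC = "numeric"
BINARY = "binary"
CATEGORICAL = "categorical"
KINDS = (NUMERIC, BINARY, CATEGORICAL)


@dataclass(frozen=True)
class Variable:
    """One census record.

    Parameters
    ----------
    name : column name in the windowed table.
    kind : ``numeric``, ``binary`` or ``categorical``.
    static : constant within an intubation event.
    amputable : whether the amputer may remove this variable's cells.
    group : missingness-pattern group (1..5); ``None`` means never amputed.
    levels : level labels for categorical variables.
    select_all_block : id of a "select all that apply" indicator block, if
        this variable is one indicator of such a block.
    cadence_hours : raw-observation sampling interval used by the generator.
    formula : id of a deterministic completion rule (e.g. ETT size from age).
    """

    name: str
    kind: str
    static: bool = False
    amputable: bool = True
    group: int | None = None
    levels: tuple[str, ...] = ()
    select_all_block: str | None = None
    cadence_hours: int = 4
    formula: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == CATEGORICAL and len(self.levels) < 2:
            raise ValueError(f"categorical variable {self.name} needs >=2 levels")
        if self.amputable and self.group is None:
            raise ValueError(f"amputable variable {self.name} needs a group")
        if not self.amputable and self.group is not None:
            raise ValueError(f"non-amputable variable {self.name} must have group=None")


@dataclass
class VariableCensus:
    """Ordered collection of :class:`Variable` records."""

    variables: list[Variable] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in census")

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self):
        return iter(self.variables)

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def time_varying(self) -> list[Variable]:
        return [v for v in self.variables if not v.static]

    @property
    def statics(self) -> list[Variable]:
        return [v for v in self.variables if v.static]

    @property
    def amputable(self) -> list[Variable]:
        return [v for v in self.variables if v.amputable]

    @property
    def amputable_names(self) -> list[str]:
        return [v.name for v in self.variables if v.amputable]

    def kind_of(self, name: str) -> str:
        return self[name].kind

    def kinds(self) -> dict[str, str]:
        return {v.name: v.kind for v in self.variables}

    def groups(self) -> dict[int, list[str]]:
        """Pattern groups: group id -> amputable variable names."""
        out: dict[int, list[str]] = {}
        for v in self.variables:
            if v.group is not None:
                out.setdefault(v.group, []).append(v.name)
        return out

    def n_wide_features(self, n_lags: int = 2) -> int:
        """Feature count of the wide matrix with ``n_lags`` lags."""
        return len(self.statics) + len(self.time_varying) * (n_lags + 1)

    def to_records(self) -> list[dict]:
        return [
            {
                "name": v.name,
                "kind": v.kind,
                "static": v.static,
                "amputable": v.amputable,
                "group": v.group,
                "levels": list(v.levels),
                "select_all_block": v.select_all_block,
                "cadence_hours": v.cadence_hours,
                "formula": v.formula,
            }
            for v in self.variables
        ]

    @classmethod
    def from_records(cls, records: list[dict]) -> "VariableCensus":
        return cls(
            [
                Variable(
                    name=r["name"],
                    kind=r["kind"],
                    static=bool(r.get("static", False)),
                    amputable=bool(r.get("amputable", True)),
                    group=r.get("group"),
                    levels=tuple(r.get("levels") or ()),
                    select_all_block=r.get("select_all_block"),
                    cadence_hours=int(r.get("cadence_hours", 4)),
                    formula=r.get("formula"),
                )
                for r in records
            ]
        )


def _grouped(i: int) -> int:
    return (i % 5) + 1


def default_census() -> VariableCensus:
    """The full 99-variable census (83 time-varying; 265 wide features).

    Variable content is schematic — realistic names, but no clinical units
    or reference ranges.  Groups 1..5 partition the amputable variables;
    a respiratory-pattern "select all that apply" indicator block sits in
    group 4.  Age, sex and race are never missing.
    """
    vars: list[Variable] = []
    # --- statics (16): 3 never-missing + 13 amputable admission measures
    vars.append(Variable("age_years", NUMERIC, static=True, amputable=False))
    vars.append(Variable("sex_female", BINARY, static=True, amputable=False))
    vars.append(
        Variable(
            "race_ethnicity",
            CATEGORICAL,
            static=True,
            amputable=False,
            levels=("asian", "black", "latinx", "other", "white"),
        )
    )
    static_numeric = [
        "weight_kg",
        "height_cm",
        "admission_albumin",
        "admission_creatinine",
        "admission_hemoglobin",
        "admission_platelets",
        "admission_bicarbonate",
        "admission_glucose",
        "admission_calcium",
        "admission_bilirubin",
        "baseline_risk_score",
    ]
    for i, name in enumerate(static_numeric):
        vars.append(Variable(name, NUMERIC, static=True, group=_grouped(i)))
    vars.append(Variable("chronic_ventilation", BINARY, static=True, group=_grouped(11)))
    vars.append(
        Variable(
            "ett_size",
            NUMERIC,
            static=True,
            group=_grouped(12),
            formula="ett_from_age",
        )
    )

    # --- time-varying (83): 69 numeric (incl. sbp percentile), 8 binary,
    #     6 categorical
    tv_numeric = [
        "sbp_percentile",
        "pulse",
        "resp_rate",
        "spo2",
        "temperature",
        "map_mmhg",
        "peep",
        "pip",
        "fio2",
        "tidal_volume_kg",
        "minute_ventilation",
        "vent_rate_set",
        "pressure_support",
        "etco2",
        "ph",
        "pco2",
        "pao2",
        "base_excess",
        "lactate",
        "wbc_count",
        "hemoglobin",
        "platelet_count",
        "sodium",
        "potassium",
        "chloride",
        "bun",
        "creatinine",
        "glucose",
        "calcium_ionized",
        "fluid_balance_12h_kg",
        "urine_output_kg",
        "sedative_dose_kg",
        "opioid_morphine_equiv",
        "vasopressor_dose",
        "gcs_total",
        "comfort_score",
    ]
    tv_numeric += [f"lab_panel_{i:02d}" for i in range(16)]
    tv_numeric += [f"vent_param_{i:02d}" for i in range(9)]
    tv_numeric += [f"vitals_aux_{i:02d}" for i in range(8)]
    assert len(tv_numeric) == 69
    for i, name in enumerate(tv_numeric):
        vars.append(
            Variable(name, NUMERIC, group=_grouped(i), cadence_hours=1 + (i % 4))
        )

    tv_binary_free = ["cough_present", "gag_present", "sedated", "on_vasopressor"]
    for i, name in enumerate(tv_binary_free):
        vars.append(Variable(name, BINARY, group=_grouped(i + 1), cadence_hours=2 + (i % 3)))
    resp_block = ["resp_tachypneic", "resp_retractions", "resp_grunting", "resp_apneic"]
    for name in resp_block:
        # "select all that apply" indicator block lives together in group 4
        vars.append(
            Variable(name, BINARY, group=4, select_all_block="resp_pattern", cadence_hours=4)
        )

    tv_categorical = [
        ("secretion_amount", ("none", "scant", "small", "moderate", "large", "copious")),
        ("state_behavioral_scale", ("-3", "-2", "-1", "0", "1")),
        ("glasgow_eye", ("1", "2", "3", "4")),
        ("motor_response_ue", ("1", "2", "3", "4", "5", "6")),
        ("pupil_response", ("brisk", "sluggish", "fixed")),
        ("breath_sounds", ("clear", "coarse", "diminished", "absent")),
    ]
    for i, (name, levels) in enumerate(tv_categorical):
        vars.append(Variable(name, CATEGORICAL, group=_grouped(i), levels=levels, cadence_hours=4))

    census = VariableCensus(vars)
    assert len(census) == 99, len(census)
    assert len(census.time_varying) == 83
    assert census.n_wide_features(2) == 265
    return census


def small_census(n_numeric_tv: int = 10, seed_spread: bool = True) -> VariableCensus:
    """A reduced census for desk-scale experiments and tests.

    ``n_numeric_tv`` numeric time-varying variables plus one binary and one
    categorical time-varying variable, two never-missing statics and one
    amputable static.  Groups 1..5 are assigned round-robin.
    """
    vars: list[Variable] = [
        Variable("age_years", NUMERIC, static=True, amputable=False),
        Variable("sex_female", BINARY, static=True, amputable=False),
        Variable("weight_kg", NUMERIC, static=True, group=1),
        Variable("sbp_percentile", NUMERIC, group=2, cadence_hours=2),
    ]
    for i in range(n_numeric_tv - 1):
        vars.append(
            Variable(f"num_{i:02d}", NUMERIC, group=_grouped(i), cadence_hours=1 + (i % 4))
        )
    vars.append(Variable("flag_a", BINARY, group=3, cadence_hours=2))
    vars.append(
        Variable("scale_a", CATEGORICAL, group=4, levels=("low", "mid", "high"), cadence_hours=4)
    )
    return VariableCensus(vars)
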