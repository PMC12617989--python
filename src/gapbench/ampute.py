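"""Mechanism-controlled amputation: induce missingness in a complete table.

Five mechanisms are supported.  Under MCAR every row has the same
missingness probability.  Under MAR and the three MNAR grades, each
pattern (one per variable group) scores every row with a weighted sum of
standardized variable values — the weight ratio of variables left observed
to variables being amputed encodes the mechanism strength (MAR 1:0,
weak MNAR 2:1, moderate MNAR 1:1, strong MNAR 0:1) — and the outcome
enters the score with unit weight.  Scores are mapped to per-row
probabilities by a shifted logistic whose offset is solved by bisection so
the expected cell-wise missing proportion over the whole table equals
``level x base_cell_proportion``.

Each pattern draws independently per row, so a row may be hit by several
patterns; this makes any cell-wise proportion up to the amputable fraction
of the table attainable (a single-pattern-per-row assignment would cap it
at one fifth under the default five-group partition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .census import VariableCensus
from .windows import WindowTable

MECHANISMS = ("MCAR", "MAR", "MNAR_weak", "MNAR_moderate", "MNAR_strong")
LEVELS = (0.5, 1.0, 2.0)

#: (weight on observed variables, weight on to-be-amputed variables)
_WEIGHT_POLICY = {
    "MCAR": (0.0, 0.0),
    "MAR": (1.0, 0.0),
    "MNAR_weak": (2.0, 1.0),
    "MNAR_moderate": (1.0, 1.0),
    "MNAR_strong": (0.0, 1.0),
}


@dataclass
class MissingnessScenario:
    mechanism: str
    level: float = 1.0
    base_cell_proportion: float = 0.182
    include_outcome: bool | None = None  # default: outcome included unless MCAR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not (0.0 <= self.level * self.base_cell_proportion < 1.0):
            raise ValueError("cell-wise target proportion must be in [0, 1)")

    @property
    def cell_target(self) -> float:
        return self.level * self.base_cell_proportion

    @property
    def outcome_in_score(self) -> bool:
        if self.include_outcome is None:
            return self.mechanism != "MCAR"
        return self.include_outcome


@dataclass
class MissingnessMask:
    """Boolean mask aligned to the base window table (True = amputed)."""

    mask: pd.DataFrame
    achieved_cell_proportion: float
    pattern_hits: pd.DataFrame  # rows x pattern-group ids
    scenario: MissingnessScenario

    def to_sparse_frame(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.mask.to_numpy())
        return pd.DataFrame(
            {
                "event_id": self.mask.index.get_level_values(0)[rows],
                "window_index": self.mask.index.get_level_values(1)[rows],
                "variable": self.mask.columns[cols],
            }
        )


def build_patterns(census: VariableCensus) -> dict[int, list[str]]:
    """One missingness pattern per variable group: the pattern's amputed
    set is exactly that group's amputable variables."""
    groups = census.groups()
    for g, names in groups.items():
        if not names:
            raise ValueError(f"pattern group {g} is empty")
    return dict(sorted(groups.items()))


def _zscore_frame(data: pd.DataFrame, census: VariableCensus) -> pd.DataFrame:
    """Column z-scores using the table's mean/SD; categorical columns are
    scored on their integer level codes.  Zero-variance columns score 0
    (their weight is effectively dropped)."""
    z = pd.DataFrame(index=data.index)
    for c in data.columns:
        col = data[c]
        if isinstance(col.dtype, pd.CategoricalDtype):
            col = col.cat.codes.astype(float)
        else:
            col = col.astype(float)
        sd = col.std()
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"zero-variance variable {c}; its weight is dropped")
            z[c] = 0.0
        else:
            z[c] = (col - col.mean()) / sd
    return z


def weighted_sum_scores(
    z: pd.DataFrame,
    amputed_cols: list[str],
    mechanism: str,
    outcome_z: pd.Series | None = None,
) -> np.ndarray:
    """Per-row weighted-sum score for one pattern under a mechanism."""
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    w_obs, w_amp = _WEIGHT_POLICY[mechanism]
    scores = np.zeros(len(z))
    amputed = set(amputed_cols)
    for c in z.columns:
        w = w_amp if c in amputed else w_obs
        if w:
            scores = scores + w * z[c].to_numpy()
    if outcome_z is not None and mechanism != "MCAR":
        scores = scores + outcome_z.to_numpy()
    return scores


def calibrate_probability(scores: np.ndarray, target_row_prob: float) -> np.ndarray:
    """Per-row missingness probabilities: logistic(score + c) with the
    offset c solved by bisection so that mean(p) equals the target.
    Constant scores reduce to a uniform Bernoulli probability."""
    if not (0.0 <= target_row_prob < 1.0):
        raise ValueError("target row probability must be in [0, 1)")
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if target_row_prob == 0.0:
        return np.zeros_like(scores)
    sd = scores.std()
    if sd == 0:
        return np.full_like(scores, target_row_prob)
    z = (scores - scores.mean()) / sd

    def gap(c: float) -> float:
        return float(np.mean(expit(z + c))) - target_row_prob

    c = brentq(gap, -60.0, 60.0, xtol=1e-9)
    return expit(z + c)


def ampute(
    wt: WindowTable,
    scenario: MissingnessScenario,
    outcome: pd.Series | None = None,
) -> tuple[WindowTable, MissingnessMask]:
    """Produce one amputed copy of a complete window table.

    ``outcome`` is the per-row outcome allowed to influence missingness
    under MAR/MNAR; when absent, the table's binary success label is used
    if available.  Deterministic given ``scenario.seed``.
    """
    data = wt.data
    if data.isna().to_numpy().any():
        raise ValueError("amputation requires a complete table")
    census = wt.census
    patterns = build_patterns(census)
    n_rows, n_cols = data.shape
    total_pattern_cells = sum(len(v) for v in patterns.values())

    # uniform per-pattern row probability that yields the target cell-wise
    # proportion over all table cells in expectation
    target = scenario.cell_target
    q = target * n_cols / total_pattern_cells
    if q > 1.0:
        raise ValueError(
            f"cell proportion {target:.3f} unattainable: patterns cover too few "
            f"cells (max {total_pattern_cells / n_cols:.3f})"
        )

    if outcome is None and wt.labels is not None:
        outcome = wt.labels["success_label"]
    outcome_z = None
    if outcome is not None and scenario.outcome_in_score:
        o = pd.Series(outcome, index=data.index).astype(float)
        sd = o.std()
        outcome_z = (o - o.mean()) / sd if sd > 0 else o * 0.0

    z = _zscore_frame(data, census)
    rng = np.random.default_rng(scenario.seed)
    mask = pd.DataFrame(False, index=data.index, columns=data.columns)
    hits = pd.DataFrame(False, index=data.index, columns=list(patterns))
    for g, amputed_cols in patterns.items():
        scores = weighted_sum_scores(z, amputed_cols, scenario.mechanism, outcome_z)
        probs = calibrate_probability(scores, q)
        hit = rng.random(n_rows) < probs
        hits[g] = hit
        mask.loc[hit, amputed_cols] = True

    amputed = wt.copy()
    masked = amputed.data.mask(mask)
    for c in data.columns:  # preserve categorical dtypes
        if isinstance(data[c].dtype, pd.CategoricalDtype):
            masked[c] = pd.Categorical(
                masked[c], categories=data[c].cat.categories
            )
    amputed.data = masked
    achieved = float(mask.to_numpy().sum()) / (n_rows * n_cols)
    return amputed, MissingnessMask(
        mask=mask,
        achieved_cell_proportion=achieved,
        pattern_hits=hits,
        scenario=scenario,
    )
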