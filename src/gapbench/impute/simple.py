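"""Deterministic imputers: mean/mode, last observation carried forward,
and the explicit no-imputation passthrough."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .base import BaseImputer


def locf_impute(series: pd.Series) -> pd.Series:
    """Carry the most recent prior observed value forward, indefinitely.

    Leading gaps remain missing (data stay missing if no prior measurement
    exists); future values are never used.
    """
    return series.ffill()


class MeanModeImputer(BaseImputer):
    """Unconditional training mean (numeric/binary) or mode (categorical)."""

    method = "mean"

    def _fit(self, X: pd.DataFrame) -> None:
        self.fill_values_ = {}
        for c in X.columns:
            col = X[c]
            if self.kinds_[c] == "categorical":
                modes = col.mode(dropna=True)
                self.fill_values_[c] = None if modes.empty else modes.iloc[0]
            else:
                self.fill_values_[c] = float(col.mean())

    def _transform_once(self, X, rng, imp_index):
        out = X.copy()
        for c, v in self.fill_values_.items():
            if v is not None and not (isinstance(v, float) and np.isnan(v)):
                out[c] = out[c].fillna(v)
        return out


class LOCFImputer(BaseImputer):
    """Last observation carried forward within each event's window series.

    Expects a (event_id, window_index) MultiIndex so that carrying forward
    never crosses events.  With ``fallback_to_mean`` remaining leading gaps
    take the training mean/mode (for outcome models that require complete
    input); otherwise they stay missing for natively-capable models.
    """

    method = "locf"

    def __init__(self, fallback_to_mean: bool = False):
        self.fallback_to_mean = fallback_to_mean

    def _fit(self, X: pd.DataFrame) -> None:
        self.fill_values_ = {}
        if self.fallback_to_mean:
            for c in X.columns:
                if self.kinds_[c] == "categorical":
                    modes = X[c].mode(dropna=True)
                    self.fill_values_[c] = None if modes.empty else modes.iloc[0]
                else:
                    self.fill_values_[c] = float(X[c].mean())

    def _transform_once(self, X, rng, imp_index):
        if isinstance(X.index, pd.MultiIndex):
            out = X.sort_index().groupby(level=0, group_keys=False).ffill()
            out = out.reindex(X.index)
        else:
            out = X.ffill()
        if self.fallback_to_mean:
            for c, v in self.fill_values_.items():
                if v is not None and not (isinstance(v, float) and np.isnan(v)):
                    out[c] = out[c].fillna(v)
        return out


class IdentityImputer(BaseImputer):
    """No imputation: missing cells flow through to the outcome model's
    native missing-value handling."""

    method = "none"

    def _fit(self, X: pd.DataFrame) -> None:
        pass

    def _transform_once(self, X, rng, imp_index):
        return X.copy()
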