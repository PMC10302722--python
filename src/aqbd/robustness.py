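"""Plackett-Burman robustness models and system-suitability ranges.

Robustness testing perturbs every method parameter over a deliberately
narrow range around the working point and fits a main-effects model on a
two-level Plackett-Burman design.  Effects are estimated as
mean(high) - mean(low); their error is judged either against the
apparent "effects" of unassigned dummy columns (which estimate pure
noise) or against the regression residual.  The observed response ranges
then become the System Suitability Test acceptance intervals, widened
where the fitted models predict values beyond what was observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._ols import ols
from .design import DesignMatrix

__all__ = [
    "PlackettBurmanLinear",
    "PBLinearResults",
    "SuitabilityRange",
    "suitability_ranges",
]


class PlackettBurmanLinear:
    """Main-effects model on a two-level (+-1) design.

    ``n_real`` marks how many leading design columns carry real factors;
    the remaining columns are treated as dummy (noise) columns.  By
    default every column whose factor name starts with ``"dummy"`` is a
    dummy.
    """

    def __init__(self, endog, design: DesignMatrix, n_real: int | None = None):
        y = np.asarray(endog, float).ravel()
        if len(y) != len(design):
            raise ValueError("response length must match the number of runs")
        coded = design.coded
        if not np.all(np.isin(coded, (-1.0, 1.0))):
            raise ValueError("robustness design must be two-level (+-1)")
        if np.any(coded.sum(axis=0) != 0):
            raise ValueError("unbalanced columns: +1 and -1 must appear "
                             "equally often in every column")
        self.design = design
        self.endog = y
        if n_real is None:
            n_real = sum(
                not f.name.startswith("dummy") for f in design.factors
            )
        self.n_real = n_real

    def fit(self, alpha: float = 0.05, error: str = "auto") -> "PBLinearResults":
        """Estimate effects and flag significance.

        ``error``: ``"dummy"`` uses the dummy-column effects as the noise
        yardstick, ``"residual"`` the regression residual, ``"auto"``
        prefers dummy columns when at least two are available.
        """
        coded = self.design.coded
        n, k = coded.shape
        effects = np.array(
            [self.endog[coded[:, j] > 0].mean()
             - self.endog[coded[:, j] < 0].mean() for j in range(k)]
        )
        n_dummy = k - self.n_real
        if error == "auto":
            error = "dummy" if n_dummy >= 2 else "residual"
        if error == "dummy":
            if n_dummy < 2:
                raise ValueError("need >= 2 dummy columns for dummy-based error")
            dummy_eff = effects[self.n_real:]
            se = float(np.sqrt(np.mean(dummy_eff**2)))
            df = n_dummy
        elif error == "residual":
            X = np.column_stack([np.ones(n), coded[:, : self.n_real]])
            f = ols(X, self.endog)
            if f.df_resid <= 0:
                raise ValueError("saturated design: no residual df; "
                                 "use dummy columns")
            # effect = 2 * regression coefficient; var scales accordingly
            se = float(2.0 * np.sqrt(f.s2 / n))
            df = f.df_resid
        else:
            raise ValueError("error must be 'auto', 'dummy' or 'residual'")
        return PBLinearResults(self, effects, se, df, alpha, error)


@dataclass
class PBLinearResults:
    model: PlackettBurmanLinear
    effects: np.ndarray
    se_effect: float
    df: int
    alpha: float
    error_source: str

    @property
    def coefficients(self) -> np.ndarray:
        """Regression-scale coefficients: exactly effects / 2."""
        return self.effects / 2.0

    def table(self) -> pd.DataFrame:
        names = [f.name for f in self.model.design.factors]
        if self.se_effect > 0:
            t = self.effects / self.se_effect
            p = 2 * stats.t.sf(np.abs(t), self.df)
        else:
            t = np.where(self.effects == 0, 0.0, np.inf)
            p = np.where(self.effects == 0, 1.0, 0.0)
        df = pd.DataFrame(
            {"effect": self.effects, "se": self.se_effect, "t": t, "p": p,
             "significant": p < self.alpha,
             "dummy": [i >= self.model.n_real for i in range(len(names))]},
            index=names,
        )
        return df

    def significant_factors(self) -> list[str]:
        tab = self.table()
        return list(tab.index[tab.significant & ~tab.dummy])

    def summary(self) -> str:
        return (
            f"Plackett-Burman main-effects model "
            f"({self.model.n_real} factors, "
            f"{len(self.effects) - self.model.n_real} dummy columns, "
            f"error from {self.error_source})\n"
            + self.table().round(4).to_string()
        )


@dataclass
class SuitabilityRange:
    """System-suitability acceptance interval for one CMA."""

    response: str
    low: float
    high: float
    widened: bool = False
    reason: str = ""

    def contains(self, value) -> np.ndarray:
        v = np.asarray(value, float)
        return (v >= self.low) & (v <= self.high)


def suitability_ranges(
    responses: pd.DataFrame,
    model_predictions: dict[str, float] | None = None,
    widen_low: bool = False,
) -> list[SuitabilityRange]:
    """Observed [min, max] per response, widened to cover model predictions.

    When a fitted model predicts values beyond the observed maximum (the
    plate-count case), the upper limit is raised to the prediction and the
    range is flagged as widened; widening the lower limit is off by
    default.
    """
    out = []
    preds = model_predictions or {}
    for name in responses.columns:
        vals = responses[name].dropna().to_numpy(float)
        if len(vals) < 2:
            raise ValueError(
                f"response {name!r}: need >= 2 observed values for a range"
            )
        low, high = float(vals.min()), float(vals.max())
        widened, reason = False, ""
        if name in preds:
            p = float(preds[name])
            if p > high:
                high, widened = p, True
                reason = ("interval widened upward to include the "
                          "model-predicted value")
            elif widen_low and p < low:
                low, widened = p, True
                reason = ("interval widened downward to include the "
                          "model-predicted value")
        out.append(SuitabilityRange(name, low, high, widened, reason))
    return out
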