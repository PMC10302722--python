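"""Free-Wilson screening models for three-level designs.

The screening phase relates each Critical Method Attribute to seven
method parameters studied at three levels each, through an additive
(main-effects) Free-Wilson model: a constant plus, per factor, one
deviation coefficient for each of the first two levels; the third-level
coefficient is implied by the sum-to-zero constraint.  The fit supports
the two displays used to read a screen: per-level effect bars
("which level of each parameter is best") and level-change contrasts
("is moving between two levels a significant change").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._ols import OLSFit, ols
from .design import DesignMatrix

__all__ = ["FreeWilson", "FreeWilsonResults", "free_wilson_matrix"]


def _levels(design: DesignMatrix) -> np.ndarray:
    """Coded -1/0/+1 three-level design -> integer levels 1/2/3."""
    lv = np.rint(design.coded).astype(int) + 2
    for j, f in enumerate(design.factors):
        observed = np.unique(lv[:, j])
        if not np.array_equal(observed, [1, 2, 3]):
            raise ValueError(
                f"factor {f.name!r} must be observed at exactly 3 levels; "
                f"got levels {observed.tolist()}"
            )
    return lv


def free_wilson_matrix(design: DesignMatrix) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero (deviation) model matrix for a three-level design.

    One intercept column plus two indicator-contrast columns per factor;
    a run at level 1 contributes (1, 0), level 2 -> (0, 1) and level 3
    closes the constraint with (-1, -1).
    """
    lv = _levels(design)
    n, k = lv.shape
    cols = [np.ones(n)]
    names = ["intercept"]
    for j, f in enumerate(design.factors):
        c1 = np.where(lv[:, j] == 1, 1.0, np.where(lv[:, j] == 3, -1.0, 0.0))
        c2 = np.where(lv[:, j] == 2, 1.0, np.where(lv[:, j] == 3, -1.0, 0.0))
        cols += [c1, c2]
        names += [f"{f.name}[1]", f"{f.name}[2]"]
    return np.column_stack(cols), names


#: level-change contrasts displayed in a graphic analysis of effects,
#: as (from_level, to_level): estimate = effect(to) - effect(from)
_CONTRASTS = ((2, 1), (3, 2), (3, 1))


class FreeWilson:
    """Additive per-level effects model on a three-level screening design."""

    def __init__(self, endog, design: DesignMatrix):
        y = np.asarray(endog, float).ravel()
        if len(y) != len(design):
            raise ValueError("response length must match the number of runs")
        if np.any(~np.isfinite(y)):
            raise ValueError("screening responses must not contain missing values")
        self.design = design
        self.endog = y
        self.exog, self.exog_names = free_wilson_matrix(design)

    def fit(self) -> "FreeWilsonResults":
        return FreeWilsonResults(self, ols(self.exog, self.endog))


class FreeWilsonResults:
    """Fitted Free-Wilson screening model."""

    def __init__(self, model: FreeWilson, fit: OLSFit):
        self.model = model
        self._fit = fit
        self.params = fit.params
        self.bse = fit.bse
        self.df_resid = fit.df_resid
        self.residual_sd = float(np.sqrt(fit.s2)) if fit.df_resid > 0 else np.nan
        self.rsquared = fit.rsquared

    # -- whole-model ANOVA -------------------------------------------------
    @property
    def anova(self) -> dict:
        """F test of the full model against the intercept-only model.

        ``computable`` is False for degenerate data (zero residual or zero
        model sum of squares), in which case F and p are NaN.
        """
        f = self._fit
        df_model = len(self.params) - 1
        ssr = f.sst - f.sse
        if f.df_resid <= 0 or f.sse <= 0 or f.sst <= 0:
            return {"F": np.nan, "df_model": df_model,
                    "df_resid": f.df_resid, "p": np.nan, "computable": False}
        F = (ssr / df_model) / (f.sse / f.df_resid)
        p = float(stats.f.sf(F, df_model, f.df_resid))
        return {"F": float(F), "df_model": df_model,
                "df_resid": f.df_resid, "p": p, "computable": True}

    # -- per-level quantities ----------------------------------------------
    def level_coefficients(self) -> pd.DataFrame:
        """Per-factor deviation coefficients for levels 1..3 (rows sum to 0)."""
        rows = {}
        for j, fac in enumerate(self.model.design.factors):
            a1, a2 = self.params[1 + 2 * j], self.params[2 + 2 * j]
            rows[fac.name] = [a1, a2, -a1 - a2]
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["level_1", "level_2", "level_3"]
        )

    def level_effects(self) -> pd.DataFrame:
        """Predicted response at each level of each factor (others averaged
        out): intercept + level coefficient.  This is the bar-plot display."""
        return self.level_coefficients() + self.params[0]

    def predict(self, design: DesignMatrix | None = None) -> np.ndarray:
        if design is None:
            return self._fit.fitted
        X, _ = free_wilson_matrix(design)
        return X @ self.params

    # -- level-change significance -----------------------------------------
    def _contrast_vector(self, j: int, frm: int, to: int) -> np.ndarray:
        """c such that c'beta = effect(level to) - effect(level frm)."""
        c = np.zeros(len(self.params))
        for level, sign in ((to, 1.0), (frm, -1.0)):
            if level == 1:
                c[1 + 2 * j] += sign
            elif level == 2:
                c[2 + 2 * j] += sign
            else:  # level 3 coefficient is -(a1 + a2)
                c[1 + 2 * j] -= sign
                c[2 + 2 * j] -= sign
        return c

    def pure_error(self) -> tuple[float, int]:
        """Replicate-based error variance from duplicated design rows."""
        coded = self.model.design.coded
        y = self.model.endog
        _, inverse = np.unique(coded, axis=0, return_inverse=True)
        ss, df = 0.0, 0
        for g in np.unique(inverse):
            yy = y[inverse == g]
            if len(yy) > 1:
                ss += float(np.sum((yy - yy.mean()) ** 2))
                df += len(yy) - 1
        return ss, df

    def level_contrasts(
        self, alpha: float = 0.05, error: str = "residual"
    ) -> pd.DataFrame:
        """t tests for the level transitions 2->1, 3->2 and 3->1 per factor.

        ``error`` selects the variance estimate: ``"residual"`` (mean square
        of the fit, the default) or ``"pure"`` (replicate-based).
        """
        if error == "residual":
            s2, df = self._fit.s2, self._fit.df_resid
        elif error == "pure":
            ss, df = self.pure_error()
            if df == 0:
                raise ValueError("no replicated runs: pure error unavailable")
            s2 = ss / df
        else:
            raise ValueError("error must be 'residual' or 'pure'")
        if df <= 0:
            raise ValueError(
                "no residual degrees of freedom and no replicate error"
            )
        rows = []
        for j, fac in enumerate(self.model.design.factors):
            for frm, to in _CONTRASTS:
                c = self._contrast_vector(j, frm, to)
                est = float(c @ self.params)
                se = float(np.sqrt(c @ self._fit.cov_unscaled @ c * s2))
                if se > 0:
                    t = est / se
                    p = float(2 * stats.t.sf(abs(t), df))
                else:
                    t, p = (0.0, 1.0) if est == 0 else (np.inf, 0.0)
                rows.append(
                    {"factor": fac.name, "from_level": frm, "to_level": to,
                     "estimate": est, "se": se, "t": t, "p": p,
                     "significant": p < alpha}
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        an = self.anova
        lines = [
            "Free-Wilson screening model",
            f"  runs: {len(self.model.endog)}   parameters: {len(self.params)}",
            f"  residual sd: {self.residual_sd:.4g} (df={self.df_resid})",
            f"  R2: {self.rsquared:.4f}",
            (f"  ANOVA: F({an['df_model']},{an['df_resid']}) = {an['F']:.2f}, "
             f"p = {an['p']:.4f}" if an["computable"]
             else "  ANOVA: not computable"),
            "",
            "  per-level effects (intercept + level coefficient):",
        ]
        lines.append(self.level_effects().round(4).to_string())
        return "\n".join(lines)
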