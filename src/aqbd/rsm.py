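"""Quadratic response-surface models on central composite designs.

A full second-order polynomial (intercept, linear, pure-quadratic and
two-factor interaction terms) is fitted by least squares on the coded
factor levels.  Model quality is tracked with R2 and with the
cross-validated goodness of prediction Q2 = 1 - PRESS / SS_total, where
PRESS uses the exact leave-one-out identity e_i / (1 - h_ii).  Models are
refined by backward elimination: among the currently non-significant
terms, repeatedly drop the one whose removal raises Q2 the most, until no
removal helps.

Responses may be fitted on a log10 scale (used for plate counts, which
are strictly positive and span orders of magnitude); predictions are
reported back on the original scale.  Runs with a missing response (the
co-migration case, where efficiency cannot be measured) are excluded from
that response's fit only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._ols import OLSFit, ols
from .design import DesignMatrix

__all__ = [
    "QuadraticSurface",
    "SurfaceResults",
    "quadratic_terms",
    "PanelGrid",
    "make_panels",
    "sweet_spot",
    "SweetSpot",
]


class ExtrapolationWarning(UserWarning):
    """Prediction requested beyond the modeled coded domain."""


# ---------------------------------------------------------------------------
# term bookkeeping
# ---------------------------------------------------------------------------

def term_definitions(n_factors: int) -> list[tuple]:
    """Canonical term order: intercept, linear, quadratic, interactions."""
    terms: list[tuple] = [("const",)]
    terms += [("lin", i) for i in range(n_factors)]
    terms += [("quad", i) for i in range(n_factors)]
    terms += [
        ("int", i, j)
        for i in range(n_factors)
        for j in range(i + 1, n_factors)
    ]
    return terms


def term_name(term: tuple, names: list[str]) -> str:
    if term[0] == "const":
        return "intercept"
    if term[0] == "lin":
        return names[term[1]]
    if term[0] == "quad":
        return f"{names[term[1]]}^2"
    return f"{names[term[1]]}*{names[term[2]]}"


def build_columns(points: np.ndarray, terms: list[tuple]) -> np.ndarray:
    """Evaluate model-matrix columns for coded points."""
    Z = np.atleast_2d(np.asarray(points, float))
    cols = []
    for t in terms:
        if t[0] == "const":
            cols.append(np.ones(len(Z)))
        elif t[0] == "lin":
            cols.append(Z[:, t[1]])
        elif t[0] == "quad":
            cols.append(Z[:, t[1]] ** 2)
        else:
            cols.append(Z[:, t[1]] * Z[:, t[2]])
    return np.column_stack(cols)


def quadratic_terms(design: DesignMatrix) -> tuple[np.ndarray, list[str]]:
    """Full quadratic model matrix for a coded design.

    For k factors: 1 + k + k + k(k-1)/2 columns in canonical order.
    """
    terms = term_definitions(design.n_factors)
    names = [term_name(t, design.factor_names) for t in terms]
    return build_columns(design.coded, terms), names


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class QuadraticSurface:
    """Second-order polynomial response model on a coded design.

    Parameters
    ----------
    endog : array-like
        Response values aligned with the design runs; NaN marks runs to
        exclude from this response's fit.
    design : DesignMatrix
    transform : {None, "log10"}
        Fit on log10(y) instead of y.  Requires positive used responses.
    """

    def __init__(self, endog, design: DesignMatrix, transform: str | None = None):
        y = np.asarray(endog, float).ravel()
        if len(y) != len(design):
            raise ValueError("response length must match the number of runs")
        if transform not in (None, "log10"):
            raise ValueError("transform must be None or 'log10'")
        mask = np.isfinite(y)
        y_used = y[mask]
        if transform == "log10":
            if np.any(y_used <= 0):
                raise ValueError("log10 transform requires positive responses")
            y_used = np.log10(y_used)
        self.design = design
        self.endog = y
        self.mask = mask
        self.transform = transform
        self.y_fit = y_used
        self.terms = term_definitions(design.n_factors)
        self.term_names = [
            term_name(t, design.factor_names) for t in self.terms
        ]
        #: coded-radius guard beyond which predictions warn
        self.extrapolation_guard = float(np.abs(design.coded).max()) + 0.1

    @property
    def n_used(self) -> int:
        return int(self.mask.sum())

    def _fit_terms(self, term_idx: list[int]) -> OLSFit:
        terms = [self.terms[i] for i in term_idx]
        X = build_columns(self.design.coded[self.mask], terms)
        if self.n_used < len(term_idx):
            raise ValueError(
                f"{self.n_used} usable runs cannot support "
                f"{len(term_idx)} model terms"
            )
        return ols(X, self.y_fit)

    def fit(self, terms: list[int] | None = None) -> "SurfaceResults":
        idx = list(range(len(self.terms))) if terms is None else list(terms)
        return SurfaceResults(self, idx, self._fit_terms(idx))


class SurfaceResults:
    """A fitted (possibly refined) response-surface model."""

    def __init__(self, model: QuadraticSurface, term_idx: list[int], fit: OLSFit):
        self.model = model
        self.term_idx = term_idx
        self._fit = fit
        self.params = fit.params
        self.bse = fit.bse
        self.pvalues = fit.pvalues
        self.df_resid = fit.df_resid
        self.transform = model.transform
        self.n_used = model.n_used

    @property
    def term_names(self) -> list[str]:
        return [self.model.term_names[i] for i in self.term_idx]

    @property
    def terms(self) -> list[tuple]:
        return [self.model.terms[i] for i in self.term_idx]

    # -- quality -----------------------------------------------------------
    @property
    def rsquared(self) -> float:
        return self._fit.rsquared

    @property
    def press(self) -> float:
        return self._fit.press

    @property
    def q2(self) -> float:
        """Raw goodness of prediction (may be negative for poor models)."""
        return self._fit.q2

    @property
    def q2_floored(self) -> float:
        """Q2 floored at zero, as some RSM software reports it."""
        return max(0.0, self.q2)

    @property
    def residual_sd(self) -> float:
        return float(np.sqrt(self._fit.s2))

    def cov_params(self) -> np.ndarray:
        """Parameter covariance s2 * (X'X)^-1 on the fitting scale."""
        return self._fit.cov_unscaled * self._fit.s2

    # -- refinement ----------------------------------------------------------
    def refine(self, alpha: float = 0.05) -> "SurfaceResults":
        """Backward elimination maximizing Q2.

        At each step the candidates are the non-intercept terms with
        p > ``alpha`` in the *current* model; the candidate whose removal
        yields the largest Q2 is dropped, provided that removal increases
        Q2 at all.  Ties (within 1e-12 in Q2) go to the larger p value,
        then to the later term in canonical order.  Returns the refitted
        model (itself, unchanged, if no removal helps).
        """
        current = self
        while True:
            pv = current.pvalues
            candidates = [
                pos for pos, i in enumerate(current.term_idx)
                if current.model.terms[i][0] != "const" and pv[pos] > alpha
            ]
            best = None  # (q2, p, canonical_idx, position)
            for pos in candidates:
                idx = current.term_idx[:pos] + current.term_idx[pos + 1:]
                try:
                    q2_new = current.model._fit_terms(idx).q2
                except (ValueError, np.linalg.LinAlgError):
                    continue
                if q2_new <= current.q2 + 1e-12:
                    continue
                key = (q2_new, pv[pos], current.term_idx[pos])
                if best is None or _better(key, best[:3]):
                    best = (*key, pos)
            if best is None:
                return current
            pos = best[3]
            idx = current.term_idx[:pos] + current.term_idx[pos + 1:]
            current = current.model.fit(idx)

    # -- prediction ----------------------------------------------------------
    def predict(self, points, with_sd: bool = False):
        """Mean prediction on the original response scale.

        With ``with_sd=True`` also returns the prediction standard
        deviation on the *fitting* scale: sqrt(x'(X'X)^-1 x s2 + s2),
        combining coefficient uncertainty with residual noise.
        """
        Z = np.atleast_2d(np.asarray(points, float))
        if Z.shape[1] != self.model.design.n_factors:
            raise ValueError("points must have one column per factor")
        r = np.abs(Z).max() if Z.size else 0.0
        if r > self.model.extrapolation_guard:
            warnings.warn(
                f"prediction at coded radius {r:.3g} beyond guard "
                f"{self.model.extrapolation_guard:.3g}",
                ExtrapolationWarning,
                stacklevel=2,
            )
        X = build_columns(Z, self.terms)
        mean_fit = X @ self.params
        mean = 10.0**mean_fit if self.transform == "log10" else mean_fit
        if not with_sd:
            return mean
        s2 = self._fit.s2
        var = np.einsum("ij,jk,ik->i", X, self._fit.cov_unscaled, X) * s2 + s2
        return mean, np.sqrt(var)

    def summary(self) -> str:
        lines = [
            "Quadratic response-surface model"
            + (f" (transform: {self.transform})" if self.transform else ""),
            f"  runs used: {self.n_used}   terms: {len(self.term_idx)}",
            f"  R2 = {self.rsquared:.4f}   Q2 = {self.q2:.4f}   "
            f"residual sd = {self.residual_sd:.4g} (df={self.df_resid})",
            "",
            pd.DataFrame(
                {"coef": self.params, "se": self.bse, "p": self.pvalues},
                index=self.term_names,
            ).round(4).to_string(),
        ]
        return "\n".join(lines)

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "t": self._fit.tvalues,
             "p": self.pvalues},
            index=self.term_names,
        )


def _better(key, ref) -> bool:
    """Refinement candidate ordering: Q2, then p, then canonical index."""
    q2a, pa, ia = key
    q2b, pb, ib = ref
    if abs(q2a - q2b) > 1e-12:
        return q2a > q2b
    if pa != pb:
        return pa > pb
    return ia > ib


# ---------------------------------------------------------------------------
# grids and sweet-spot overlay
# ---------------------------------------------------------------------------

@dataclass
class PanelGrid:
    """A 3x3 trellis of 2D grids over the coded factor space.

    ``panels`` maps (panel_row_coded, panel_col_coded) to an
    ``(n*n, k)`` array of coded points; the grid axes are ``x`` (varies
    fastest) and ``y``.
    """

    x_name: str
    y_name: str
    panel_names: tuple[str, str]
    x_coded: np.ndarray
    y_coded: np.ndarray
    panels: dict[tuple[float, float], np.ndarray]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.y_coded), len(self.x_coded))


def make_panels(
    factors,
    x: str,
    y: str,
    panel_rows: tuple[str, list[float]],
    panel_cols: tuple[str, list[float]],
    fixed: dict[str, float] | None = None,
    n: int = 61,
    span: float | None = None,
) -> PanelGrid:
    """Build the trellis layout used for contour / sweet-spot / risk maps.

    All level values are *coded*.  ``span`` sets the half-width of the x/y
    axes in coded units (default: the largest coded design radius is the
    caller's concern; here +-max(|panel levels|, 1.664) is avoided in favor
    of an explicit value).
    """
    names = [f.name for f in factors]
    ix, iy = names.index(x), names.index(y)
    row_name, row_levels = panel_rows
    col_name, col_levels = panel_cols
    ir, ic = names.index(row_name), names.index(col_name)
    if span is None:
        span = 1.664
    xs = np.linspace(-span, span, n)
    ys = np.linspace(-span, span, n)
    XX, YY = np.meshgrid(xs, ys)
    panels = {}
    for rv in row_levels:
        for cv in col_levels:
            pts = np.zeros((XX.size, len(factors)))
            for nm, val in (fixed or {}).items():
                pts[:, names.index(nm)] = val
            pts[:, ix] = XX.ravel()
            pts[:, iy] = YY.ravel()
            pts[:, ir] = rv
            pts[:, ic] = cv
            panels[(rv, cv)] = pts
    return PanelGrid(x, y, (row_name, col_name), xs, ys, panels)


@dataclass
class SweetSpot:
    """Satisfied-criteria counts over a panel grid (0..n_specs per node)."""

    grid: PanelGrid
    counts: dict[tuple[float, float], np.ndarray]  # 2D int arrays
    n_specs: int

    def full_pass_area(self) -> dict[tuple[float, float], int]:
        """Number of nodes per panel where every criterion is met."""
        return {
            key: int((arr == self.n_specs).sum())
            for key, arr in self.counts.items()
        }

    def widest_panel(self) -> tuple[float, float]:
        areas = self.full_pass_area()
        return max(areas, key=areas.get)


def satisfied_counts(results, specs, points) -> np.ndarray:
    """Per-point count of specs whose mean prediction meets the threshold."""
    counts = np.zeros(len(np.atleast_2d(points)), dtype=int)
    for spec in specs:
        mean = results[spec.response].predict(points)
        counts += spec.passes(mean).astype(int)
    return counts


def sweet_spot(results, specs, grid: PanelGrid) -> SweetSpot:
    """Overlay mean-prediction compliance for all specs on a panel grid."""
    counts = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        for key, pts in grid.panels.items():
            counts[key] = satisfied_counts(results, specs, pts).reshape(
                grid.shape
            )
    return SweetSpot(grid, counts, len(specs))
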