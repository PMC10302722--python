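"""Embedded study data: factor definitions, design tables, and CMA specs.

The package ships, as plain-CSV fixtures, the two printed experiment
tables of the trimecaine CyD-MEKC development study:

* a 16-run symmetric ``3^7//16`` screening array over seven method
  parameters with five measured Critical Method Attributes (CMAs), and
* a 29-run orthogonal central composite design over the five parameters
  retained for optimization.

Responses are R2 (resolution impurity1/impurity2), R3 (signed resolution
impurity2/impurity3 — negative means the migration order inverted, zero
means co-migration), R5 (resolution API/impurity4), N_I2 (plate count of
the impurity-2 peak, unmeasurable when the peak co-migrates) and t
(analysis time, min).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .design import DesignMatrix, Factor, orthogonal_alpha

__all__ = [
    "screening_factors",
    "rsm_factors",
    "fixed_parameters",
    "default_specs",
    "working_point",
    "table2_fixture",
    "table3_fixture",
    "RESPONSES",
]

#: the five CMA response names, in canonical order
RESPONSES = ("R2", "R3", "R5", "N_I2", "t")

#: method parameters fixed after screening, excluded from the RSM domain
FIXED_PARAMETERS = {"SDS conc": 65.0, "T": 22.0}


def screening_factors() -> list[Factor]:
    """The seven screened method parameters, three equispaced levels each.

    Coded -1/0/+1 map to the printed low/middle/high screening levels.
    """
    return [
        Factor("Buffer conc", 25.0, 10.0, "mM", 0, domain=(15, 35)),
        Factor("pH", 9.20, 1.00, "", 2, domain=(8.20, 10.20)),
        Factor("SDS conc", 62.5, 12.5, "mM", 1, domain=(50.0, 75.0)),
        Factor("CyD conc", 20.0, 10.0, "mM", 0, domain=(10, 30)),
        Factor("BuOH conc", 1.00, 1.00, "% v/v", 2, domain=(0.0, 2.0)),
        Factor("V", 25.0, 5.0, "kV", 0, domain=(20, 30)),
        Factor("T", 22.0, 3.0, "degC", 0, domain=(19, 25)),
    ]


def rsm_factors() -> list[Factor]:
    """The five parameters optimized by response-surface methodology.

    Centers and steps place the factorial points at the printed +-1 levels;
    the orthogonal axial points at +-1.664 decode (after per-factor
    rounding) to the printed extremes of the experimental domain.
    """
    return [
        Factor("pH", 9.50, 0.30, "", 2, domain=(9.00, 10.00)),
        Factor("Buffer conc", 25.0, 3.0, "mM", 0, domain=(20, 30)),
        Factor("CyD conc", 17.5, 4.5, "mM", 1, domain=(10.0, 25.0)),
        Factor("V", 25.0, 3.0, "kV", 0, domain=(20, 30)),
        Factor("BuOH conc", 1.00, 0.48, "% v/v", 2, domain=(0.20, 1.80)),
    ]


def fixed_parameters() -> dict[str, float]:
    """Parameters held constant after screening (not modeled, not simulated)."""
    return dict(FIXED_PARAMETERS)


def default_specs():
    """The five CMA acceptance thresholds of the target profile."""
    from .modr import CMASpec

    return [
        CMASpec("R2", "ge", 1.5),
        CMASpec("R3", "ge", 1.5),
        CMASpec("R5", "ge", 1.5),
        CMASpec("N_I2", "ge", 10_000),
        CMASpec("t", "le", 10.0),
    ]


def working_point() -> dict[str, float]:
    """The routine-analysis working point (physical units)."""
    return {
        "pH": 9.70,
        "Buffer conc": 23.0,
        "CyD conc": 20.0,
        "V": 25.0,
        "BuOH conc": 1.00,
    }


def _read_csv(name: str, **kw) -> pd.DataFrame:
    with resources.files("aqbd.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#", index_col="run_id",
                           na_values=["n.d."], **kw)


def _fixture_bytes(name: str) -> bytes:
    """Raw bytes of an embedded CSV (for integrity checks)."""
    return resources.files("aqbd.data").joinpath(name).read_bytes()


def _snap(coded: np.ndarray, grid: np.ndarray, tol: float = 0.02) -> np.ndarray:
    """Snap near-grid coded values (rounding artifacts of printed physical
    levels) onto the exact design levels."""
    out = coded.copy()
    for g in grid:
        out[np.abs(out - g) < tol] = g
    return out


def table2_fixture() -> tuple[DesignMatrix, pd.DataFrame]:
    """The printed screening array and its measured responses."""
    factors = screening_factors()
    df = _read_csv("table2_design.csv")
    coded = np.column_stack(
        [f.code(df[f.label].to_numpy()) for f in factors]
    )
    coded = _snap(coded, np.array([-1.0, 0.0, 1.0]), tol=1e-6)
    design = DesignMatrix(coded, factors, design_kind="screening",
                          run_ids=df.index.to_numpy())
    responses = _read_csv("table2_responses.csv")
    return design, responses


def table3_fixture() -> tuple[DesignMatrix, pd.DataFrame]:
    """The printed orthogonal CCD and its measured responses.

    The printed axial levels are physical values rounded for reporting
    (e.g. CyD 25.0 mM for coded +1.664...); loading snaps them back onto
    the exact coded axial distance so orthogonality is preserved.
    """
    factors = rsm_factors()
    alpha = orthogonal_alpha(16, 10, 3)
    df = _read_csv("table3_design.csv")
    coded = np.column_stack(
        [f.code(df[f.label].to_numpy()) for f in factors]
    )
    coded = _snap(coded, np.array([-alpha, -1.0, 0.0, 1.0, alpha]))
    design = DesignMatrix(coded, factors, design_kind="ccd",
                          run_ids=df.index.to_numpy())
    responses = _read_csv("table3_responses.csv")
    return design, responses
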