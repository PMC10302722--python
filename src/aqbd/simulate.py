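"""Synthetic method-development studies with the structure the analysis
assumes.

The generator draws responses from known quadratic truths on the coded
factor space with additive Gaussian noise, reproducing the features the
real data exhibit: a signed resolution that changes sign across the
domain (migration-order inversion), co-migration (resolution exactly
zero within tolerance) which makes the companion efficiency response
unmeasurable, and a strictly positive efficiency generated on a log10
scale.  A screening-study generator with additive per-level effects
supports recovery tests of the Free-Wilson fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix
from .rsm import QuadraticSurface, SurfaceResults, build_columns, term_definitions

__all__ = [
    "TruthModel",
    "simulate_study",
    "truth_from_table3",
    "simulate_screening",
]


@dataclass
class TruthModel:
    """Known data-generating quadratic truth for a set of responses.

    ``coefficients`` maps response name -> {term tuple: value} on the
    coded quadratic basis (term tuples as in :mod:`aqbd.rsm`:
    ``("const",)``, ``("lin", i)``, ``("quad", i)``, ``("int", i, j)``).
    Responses listed in ``transform`` with ``"log10"`` are generated on
    the log10 scale and exponentiated.  Where the co-migration rule fires
    (|signed resolution| < tolerance) the companion efficiency response
    is set missing.
    """

    factor_names: list[str]
    coefficients: dict[str, dict[tuple, float]]
    noise_sd: dict[str, float]
    transform: dict[str, str] = field(default_factory=dict)
    comigration_tol: float = 0.05
    #: (signed resolution response, efficiency response it censors)
    comigration_pair: tuple[str, str] | None = ("R3", "N_I2")

    def __post_init__(self):
        for name, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise sd for {name!r} must be >= 0")

    def mean(self, design: DesignMatrix, response: str) -> np.ndarray:
        """Noise-free truth on the generating (possibly log) scale."""
        coefs = self.coefficients[response]
        terms = list(coefs)
        X = build_columns(design.coded, terms)
        return X @ np.array([coefs[t] for t in terms])


def _check_factors(truth: TruthModel, design: DesignMatrix) -> None:
    if truth.factor_names != design.factor_names:
        raise ValueError(
            "truth and design factor sets differ: "
            f"{truth.factor_names} vs {design.factor_names}"
        )


def simulate_study(
    truth: TruthModel, design: DesignMatrix, seed=None
) -> pd.DataFrame:
    """Draw one synthetic study: truth + N(0, sd) per response.

    Log-scale responses are generated on the log scale then exponentiated.
    The efficiency response is censored (NaN) wherever the simulated
    signed resolution falls within the co-migration tolerance.
    Deterministic for a fixed seed.
    """
    _check_factors(truth, design)
    rng = np.random.default_rng(seed)
    data = {}
    for name in truth.coefficients:
        y = truth.mean(design, name)
        sd = truth.noise_sd.get(name, 0.0)
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=len(y))
        if truth.transform.get(name) == "log10":
            y = 10.0**y
        data[name] = y
    df = pd.DataFrame(data, index=pd.Index(design.run_ids, name="run_id"))
    if truth.comigration_pair is not None:
        res_name, eff_name = truth.comigration_pair
        if res_name in df and eff_name in df:
            comigrating = df[res_name].abs() < truth.comigration_tol
            df.loc[comigrating, eff_name] = np.nan
    return df


def truth_from_table3(
    alpha: float = 0.05,
) -> tuple[TruthModel, dict[str, SurfaceResults]]:
    """A realistic generator: refined models fitted to the printed CCD.

    Truth coefficients are the refined-model estimates and the noise sd
    is each model's residual sd, so re-analyzing simulated studies should
    reproduce the workflow's conclusions (compliant working point, MODR
    around it) up to sampling noise.
    """
    from . import datasets

    design, responses = datasets.table3_fixture()
    results: dict[str, SurfaceResults] = {}
    coefficients, noise_sd, transform = {}, {}, {}
    for name in datasets.RESPONSES:
        tr = "log10" if name == "N_I2" else None
        res = QuadraticSurface(
            responses[name].to_numpy(), design, transform=tr
        ).fit().refine(alpha=alpha)
        results[name] = res
        coefficients[name] = dict(zip(res.terms, res.params))
        noise_sd[name] = res.residual_sd
        if tr:
            transform[name] = tr
    truth = TruthModel(
        design.factor_names, coefficients, noise_sd, transform
    )
    return truth, results


def simulate_screening(
    design: DesignMatrix,
    intercept: float,
    level_effects: dict[str, tuple[float, float, float]],
    sd: float,
    seed=None,
) -> np.ndarray:
    """Additive per-level truth for a three-level screening design.

    ``level_effects[name]`` gives the (level1, level2, level3) effects of
    that factor; effects need not sum to zero (the fit's deviation coding
    absorbs the mean shift).
    """
    rng = np.random.default_rng(seed)
    lv = np.rint(design.coded).astype(int) + 2
    y = np.full(len(design), float(intercept))
    for j, f in enumerate(design.factors):
        eff = level_effects.get(f.name)
        if eff is None:
            continue
        y += np.asarray(eff, float)[lv[:, j] - 1]
    if sd > 0:
        y = y + rng.normal(0.0, sd, size=len(y))
    return y
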