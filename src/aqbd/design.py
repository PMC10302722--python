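"""Coded experimental designs for analytical method development.

This module owns the mapping between physical factor settings (buffer
concentration in mM, pH, voltage in kV, ...) and the dimensionless coded
levels that design-of-experiments models are fitted on, and it constructs
the three design families the workflow needs:

* two-level **full / half-fraction factorials** as the cube portion of a
  central composite design (CCD),
* **orthogonal CCDs**, where the axial distance ``alpha`` is chosen so that
  the centered quadratic columns of the model matrix are mutually
  orthogonal and orthogonal to the intercept,
* **Plackett-Burman** two-level screens for robustness testing.

The 16-run, seven-factor three-level screening array used in the screening
phase is an orthogonal array of external origin; it ships as a data fixture
(see :mod:`aqbd.datasets`) rather than being generated.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignMatrix",
    "CCDConfig",
    "orthogonal_alpha",
    "ccd",
    "full_factorial",
    "half_fraction",
    "plackett_burman",
    "screening_matrix_3_7_16",
    "quadratic_cross_moments",
]


class DomainWarning(UserWarning):
    """A physical value lies outside a factor's declared domain."""


@dataclass(frozen=True)
class Factor:
    """A controllable method parameter with a coded metric.

    Coding is affine: ``coded = (physical - center) / step``. ``rounding``
    is the number of decimal places used when *reporting* physical levels
    (matching how instrument settings are actually dialed in); coded values
    are never rounded.
    """

    name: str
    center: float
    step: float
    units: str = ""
    rounding: int = 2
    kind: str = "continuous"
    #: optional physical (low, high) domain; values outside warn on coding
    domain: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind == "continuous" and not self.step > 0:
            raise ValueError(f"factor {self.name!r}: step must be > 0")

    @property
    def label(self) -> str:
        return f"{self.name} [{self.units}]" if self.units else self.name

    def code(self, physical):
        """Physical value(s) -> coded value(s)."""
        x = np.asarray(physical, dtype=float)
        if self.domain is not None:
            lo, hi = self.domain
            tol = 10.0 ** (-self.rounding) / 2
            if np.any(x < lo - tol) or np.any(x > hi + tol):
                warnings.warn(
                    f"value outside declared domain {self.domain} for "
                    f"factor {self.name!r}",
                    DomainWarning,
                    stacklevel=2,
                )
        return (x - self.center) / self.step

    def decode(self, coded):
        """Coded value(s) -> physical value(s), rounded for reporting."""
        z = np.asarray(coded, dtype=float)
        return np.round(self.center + z * self.step, self.rounding)

    def coded_domain(self, default: float = np.inf) -> tuple[float, float]:
        """The domain expressed in coded units (unbounded -> +-default)."""
        if self.domain is None:
            return (-default, default)
        lo, hi = self.domain
        return (float(self.code(lo)), float(self.code(hi)))


@dataclass
class DesignMatrix:
    """An ordered set of experimental runs in coded factor levels."""

    coded: np.ndarray
    factors: list[Factor]
    design_kind: str = "custom"
    run_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coded = np.asarray(self.coded, dtype=float)
        if self.coded.ndim != 2 or self.coded.shape[1] != len(self.factors):
            raise ValueError(
                "coded matrix must be n_runs x n_factors matching `factors`"
            )
        if self.run_ids is None:
            self.run_ids = np.arange(1, len(self.coded) + 1)
        else:
            self.run_ids = np.asarray(self.run_ids)
            if len(self.run_ids) != len(self.coded):
                raise ValueError("run_ids length mismatch")
        if self.design_kind == "plackett_burman" and not np.all(
            np.isin(self.coded, (-1.0, 1.0))
        ):
            raise ValueError("Plackett-Burman designs must be two-level (+-1)")

    def __len__(self) -> int:
        return len(self.coded)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def physical(self) -> np.ndarray:
        cols = [f.decode(self.coded[:, j]) for j, f in enumerate(self.factors)]
        return np.column_stack(cols)

    def to_frame(self, coding: str = "coded") -> pd.DataFrame:
        if coding == "coded":
            data = self.coded
        elif coding == "physical":
            data = self.physical
        else:
            raise ValueError("coding must be 'coded' or 'physical'")
        df = pd.DataFrame(
            data, columns=[f.label for f in self.factors],
            index=pd.Index(self.run_ids, name="run_id"),
        )
        return df


@dataclass(frozen=True)
class CCDConfig:
    """Geometry of a central composite design.

    ``alpha`` may be a number, or ``"orthogonal"`` to derive the axial
    distance from the orthogonality condition.
    """

    n_factors: int
    fraction: str = "full"  # "full" | "half"
    n_center: int = 3
    alpha: float | str = "orthogonal"

    @property
    def n_factorial(self) -> int:
        k = self.n_factors
        return 2 ** (k - 1) if self.fraction == "half" else 2**k

    @property
    def n_axial(self) -> int:
        return 2 * self.n_factors

    @property
    def n_runs(self) -> int:
        return self.n_factorial + self.n_axial + self.n_center


def orthogonal_alpha(n_factorial: int, n_axial: int, n_center: int) -> float:
    """Axial distance making a CCD orthogonal.

    With ``F`` factorial runs and ``N`` total runs, the pure-quadratic
    columns of the quadratic model matrix, centered on their column means,
    are mutually orthogonal (and orthogonal to the intercept) exactly when

        alpha**2 = (sqrt(N * F) - F) / 2

    Raises ``ValueError`` when no real solution exists.
    """
    for v, nm in ((n_factorial, "n_factorial"), (n_axial, "n_axial"),
                  (n_center, "n_center")):
        if v < 1:
            raise ValueError(f"{nm} must be >= 1")
    if n_axial % 2:
        raise ValueError("n_axial must be even (one low/high pair per factor)")
    F = float(n_factorial)
    N = F + n_axial + n_center
    disc = math.sqrt(N * F) - F
    if disc <= 0:
        raise ValueError("no real orthogonal alpha: sqrt(N*F) <= F")
    return math.sqrt(disc / 2.0)


def full_factorial(n_factors: int) -> np.ndarray:
    """Two-level full factorial in standard order, first factor fastest."""
    n = 2**n_factors
    out = np.empty((n, n_factors))
    for j in range(n_factors):
        out[:, j] = [1.0 if (i >> j) & 1 else -1.0 for i in range(n)]
    return out


def half_fraction(n_factors: int) -> np.ndarray:
    """Half-fraction 2^(k-1) with defining relation I = AB...K.

    The last factor is aliased to the product of all others, giving the
    maximum-resolution regular half fraction (resolution = k).
    """
    base = full_factorial(n_factors - 1)
    last = np.prod(base, axis=1)
    return np.column_stack([base, last])


def ccd(
    factors: list[Factor],
    fraction: str = "full",
    n_center: int = 3,
    alpha: float | str = "orthogonal",
) -> DesignMatrix:
    """Construct a central composite design.

    Run order is deterministic: factorial block (first factor fastest),
    axial block (one low/high pair per factor, in factor order), then the
    center points.  A half fraction is refused below five factors because
    its resolution (= k for the I = AB...K fraction) would alias two-factor
    interactions with main effects, invalidating the quadratic model.
    """
    k = len(factors)
    if fraction == "half":
        if k < 5:
            raise ValueError(
                "half fraction has resolution < V for fewer than 5 factors; "
                "use fraction='full'"
            )
        cube = half_fraction(k)
    elif fraction == "full":
        cube = full_factorial(k)
    else:
        raise ValueError("fraction must be 'full' or 'half'")

    cfg = CCDConfig(k, fraction, n_center, alpha)
    a = (
        orthogonal_alpha(cfg.n_factorial, cfg.n_axial, cfg.n_center)
        if alpha == "orthogonal"
        else float(alpha)
    )
    if not a > 0:
        raise ValueError("alpha must be > 0")

    blocks = [cube]
    for j in range(k):
        row_lo = np.zeros(k)
        row_hi = np.zeros(k)
        row_lo[j] = -a
        row_hi[j] = a
        blocks.append(np.vstack([row_lo, row_hi]))
    blocks.append(np.zeros((n_center, k)))
    return DesignMatrix(np.vstack(blocks), list(factors), design_kind="ccd")


#: cyclic first rows of the Plackett-Burman construction (Paley designs)
_PB_GENERATORS = {
    8: "+++-+--",
    12: "++-+++---+-",
    16: "++++-+-++--+---",
    20: "++--++++-+-+----++-",
    24: "+++++-+-++--++--+-+----",
}


def plackett_burman(
    n_runs: int, factors: list[Factor] | None = None
) -> DesignMatrix:
    """Plackett-Burman two-level design from the standard cyclic first row.

    Columns are pairwise orthogonal and balanced.  When ``factors`` has
    fewer entries than the ``n_runs - 1`` available columns, the leading
    columns carry the real factors and the remainder act as dummy columns
    whose apparent effects estimate pure noise.
    """
    if n_runs not in _PB_GENERATORS:
        raise ValueError(
            f"unsupported n_runs={n_runs}; choose from "
            f"{sorted(_PB_GENERATORS)}"
        )
    first = np.array([1.0 if c == "+" else -1.0 for c in _PB_GENERATORS[n_runs]])
    rows = [np.roll(first, i) for i in range(n_runs - 1)]
    rows.append(-np.ones(n_runs - 1))
    coded = np.vstack(rows)
    if factors is None:
        factors = [
            Factor(f"X{j + 1}", 0.0, 1.0, rounding=6)
            for j in range(n_runs - 1)
        ]
    else:
        if len(factors) > n_runs - 1:
            raise ValueError("more factors than available columns")
        factors = list(factors) + [
            Factor(f"dummy{j + 1}", 0.0, 1.0, rounding=6)
            for j in range(n_runs - 1 - len(factors))
        ]
    return DesignMatrix(coded, factors, design_kind="plackett_burman")


def default_pb_runs(n_factors: int) -> int:
    """Smallest supported PB size leaving at least 4 dummy columns."""
    for n in sorted(_PB_GENERATORS):
        if n - 1 >= n_factors + 4:
            return n
    raise ValueError(f"too many factors ({n_factors}) for supported PB sizes")


def screening_matrix_3_7_16() -> DesignMatrix:
    """The embedded 16-run, seven-factor, three-level screening array."""
    from . import datasets

    design, _ = datasets.table2_fixture()
    return design


def quadratic_cross_moments(design: DesignMatrix) -> float:
    """Worst absolute cross moment between centered quadratic columns.

    Zero (to rounding) certifies that the design supports uncorrelated
    pure-quadratic estimates: the orthogonality property the axial
    distance of an orthogonal CCD is chosen for.
    """
    q = design.coded**2
    q = q - q.mean(axis=0)
    k = design.n_factors
    worst = 0.0
    for i, j in itertools.combinations(range(k), 2):
        worst = max(worst, abs(float(q[:, i] @ q[:, j])))
    return worst
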