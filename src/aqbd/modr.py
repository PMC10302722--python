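"""Method Operable Design Region mapping by Monte Carlo simulation.

The fitted response-surface models are treated as uncertain: each Monte
Carlo draw samples a coefficient vector from the least-squares multivariate
normal (mean = estimates, covariance = s2 (X'X)^-1) and adds residual noise
N(0, s2) on the fitting scale, then back-transforms (for log-scale models)
and checks every CMA threshold on the original response scale.  The joint
pass probability at a factor setting is the fraction of draws meeting all
thresholds simultaneously; DPMO = 1e6 * (1 - probability).  The MODR is
the region where DPMO stays at or below the target (default 100,000,
i.e. a risk of failure of at most 10%).

Both uncertainty sources can be switched off independently (some design
-space engines sample only one of them); sampling both is the default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .design import DesignMatrix, Factor
from .rsm import PanelGrid, SurfaceResults, build_columns

__all__ = [
    "CMASpec",
    "MODRConfig",
    "MODRBox",
    "ProbabilityMap",
    "joint_pass_probability",
    "probability_map",
    "extract_modr_box",
    "verify_edges",
    "node_seed",
]


@dataclass(frozen=True)
class CMASpec:
    """An acceptance threshold for one Critical Method Attribute."""

    response: str
    direction: str  # "ge" | "le"
    threshold: float
    scale: str = "original"

    def __post_init__(self):
        if self.direction not in ("ge", "le"):
            raise ValueError("direction must be 'ge' or 'le'")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def passes(self, values) -> np.ndarray:
        v = np.asarray(values, float)
        return v >= self.threshold if self.direction == "ge" else v <= self.threshold


@dataclass
class MODRConfig:
    """Monte Carlo settings for MODR mapping."""

    n_sims: int = 20_000
    dpmo_target: float = 100_000.0
    seed: int = 20230613
    grid_n: int = 21
    sample_coefficients: bool = True
    sample_residual: bool = True

    def __post_init__(self):
        if self.n_sims < 1000:
            raise ValueError("n_sims must be >= 1000")
        if not 0 < self.dpmo_target < 1e6:
            raise ValueError("dpmo_target must lie in (0, 1e6)")

    @property
    def target_pass_percent(self) -> float:
        """Minimum joint pass probability (%) implied by the DPMO target."""
        return 100.0 - self.dpmo_target / 10_000.0


def node_seed(seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic per-node seed used by :func:`probability_map`."""
    return np.random.SeedSequence([int(seed), int(index)])


def _check_models(results, specs) -> None:
    for spec in specs:
        if spec.response not in results:
            raise KeyError(f"no fitted model for response {spec.response!r}")
        res = results[spec.response]
        if res.df_resid <= 0 or not np.isfinite(res.residual_sd):
            raise ValueError(
                f"model for {spec.response!r} lacks a residual-variance "
                "estimate; Monte Carlo uncertainty propagation needs one"
            )


def _pass_fraction(
    results: dict[str, SurfaceResults],
    specs,
    point,
    n_sims: int,
    rng: np.random.Generator,
    sample_coefficients: bool = True,
    sample_residual: bool = True,
) -> float:
    """Fraction of joint-compliant draws at one coded point."""
    ok = np.ones(n_sims, dtype=bool)
    for spec in specs:
        res = results[spec.response]
        x = build_columns(np.atleast_2d(point), res.terms)[0]
        if sample_coefficients:
            draws = rng.multivariate_normal(
                res.params, res.cov_params(), size=n_sims, method="svd"
            )
            y = draws @ x
        else:
            y = np.full(n_sims, float(res.params @ x))
        if sample_residual:
            y = y + rng.normal(0.0, res.residual_sd, size=n_sims)
        vals = 10.0**y if res.transform == "log10" else y
        ok &= spec.passes(vals)
    return float(ok.mean())


def joint_pass_probability(
    results: dict[str, SurfaceResults],
    specs,
    point,
    n_sims: int = 20_000,
    seed=None,
    sample_coefficients: bool = True,
    sample_residual: bool = True,
) -> float:
    """Monte Carlo probability (%) of meeting every CMA spec at a point.

    Reproducible for a fixed ``seed`` (an int or a ``SeedSequence``).
    """
    _check_models(results, specs)
    rng = np.random.default_rng(seed)
    frac = _pass_fraction(
        results, specs, np.asarray(point, float), n_sims, rng,
        sample_coefficients, sample_residual,
    )
    return 100.0 * frac


@dataclass
class ProbabilityMap:
    """Gridded failure risk over the factor domain."""

    grid: PanelGrid
    risk: dict[tuple[float, float], np.ndarray]  # % failure per node
    dpmo_target: float

    @property
    def dpmo(self) -> dict[tuple[float, float], np.ndarray]:
        return {k: v * 10_000.0 for k, v in self.risk.items()}

    @property
    def in_modr(self) -> dict[tuple[float, float], np.ndarray]:
        return {
            k: v * 10_000.0 <= self.dpmo_target for k, v in self.risk.items()
        }

    def inmodr_area(self) -> dict[tuple[float, float], int]:
        """Size of the largest connected compliant patch per panel
        (4-connectivity on the grid)."""
        out = {}
        for key, flags in self.in_modr.items():
            labels, n = ndimage.label(flags)
            sizes = ndimage.sum_labels(flags, labels, range(1, n + 1)) if n else []
            out[key] = int(max(sizes)) if n else 0
        return out

    def widest_panel(self) -> tuple[float, float]:
        areas = self.inmodr_area()
        return max(areas, key=areas.get)


def probability_map(
    results: dict[str, SurfaceResults],
    specs,
    grid: PanelGrid,
    config: MODRConfig | None = None,
    n_sims: int | None = None,
) -> ProbabilityMap:
    """Evaluate the failure-risk map node by node.

    Each node uses an independent, deterministic seed stream
    ``node_seed(config.seed, global_node_index)``, so any node's risk can
    be reproduced exactly with :func:`joint_pass_probability`.
    """
    config = config or MODRConfig()
    n_sims = n_sims or config.n_sims
    _check_models(results, specs)
    risk = {}
    node = 0
    per_panel = grid.shape[0] * grid.shape[1]
    for key, pts in grid.panels.items():
        vals = np.empty(len(pts))
        for i, pt in enumerate(pts):
            rng = np.random.default_rng(node_seed(config.seed, node + i))
            vals[i] = 100.0 * (
                1.0
                - _pass_fraction(
                    results, specs, pt, n_sims, rng,
                    config.sample_coefficients, config.sample_residual,
                )
            )
        risk[key] = vals.reshape(grid.shape)
        node += per_panel
    return ProbabilityMap(grid, risk, config.dpmo_target)


# ---------------------------------------------------------------------------
# MODR box extraction
# ---------------------------------------------------------------------------

@dataclass
class MODRBox:
    """Axis-aligned compliant box around a working point.

    The box is a reporting convenience (per-factor operating intervals);
    the full probability map remains the primary design-space artifact,
    since the true compliant region need not be a box.
    """

    factors: list[Factor]
    working_point: np.ndarray  # coded
    lo: np.ndarray  # coded lower corners
    hi: np.ndarray  # coded upper corners
    min_vertex_pass: float  # % at the worst validated vertex

    @property
    def intervals(self) -> pd.DataFrame:
        rows = []
        for j, f in enumerate(self.factors):
            rows.append(
                {"factor": f.name, "units": f.units,
                 "low": float(f.decode(self.lo[j])),
                 "high": float(f.decode(self.hi[j])),
                 "working_point": float(f.decode(self.working_point[j]))}
            )
        return pd.DataFrame(rows).set_index("factor")

    def vertices(self) -> np.ndarray:
        """Unique corner points of the box (coded)."""
        corners = list(
            itertools.product(*[(self.lo[j], self.hi[j])
                                for j in range(len(self.factors))])
        )
        return np.unique(np.array(corners), axis=0)


class _CountedEvaluator:
    """Deterministic MC evaluator: k-th call uses its own seed stream."""

    def __init__(self, results, specs, config: MODRConfig, n_sims: int,
                 salt: int = 10_000_019):
        self.results, self.specs, self.config = results, specs, config
        self.n_sims = n_sims
        self.salt = salt
        self.calls = 0

    def __call__(self, point) -> float:
        rng = np.random.default_rng(
            np.random.SeedSequence([self.config.seed, self.salt, self.calls])
        )
        self.calls += 1
        return 100.0 * _pass_fraction(
            self.results, self.specs, point, self.n_sims, rng,
            self.config.sample_coefficients, self.config.sample_residual,
        )


def extract_modr_box(
    results: dict[str, SurfaceResults],
    specs,
    working_point,
    config: MODRConfig | None = None,
    domain_radius: float | None = None,
    n_sims: int | None = None,
    bisect_iter: int = 18,
    shrink: float = 0.95,
    max_shrink_iter: int = 80,
) -> MODRBox:
    """Grow per-factor intervals around a compliant working point.

    Each axis is expanded by bisection (other factors held at the working
    point) until the pass probability drops below the DPMO-implied target;
    the resulting box is then validated at all its vertices and shrunk
    proportionally toward the working point until every vertex complies.
    """
    config = config or MODRConfig()
    n_sims = n_sims or config.n_sims
    _check_models(results, specs)
    first = next(iter(results.values()))
    factors = first.model.design.factors
    wp = np.asarray(working_point, float)
    target = config.target_pass_percent
    ev = _CountedEvaluator(results, specs, config, n_sims)

    if ev(wp) < target:
        raise ValueError("working point outside MODR: its joint pass "
                         "probability is below the DPMO target")

    k = len(factors)
    ext = np.zeros((k, 2))  # [:,0] = extent toward low, [:,1] toward high
    for j in range(k):
        lo_cd, hi_cd = factors[j].coded_domain(
            default=domain_radius or np.abs(first.model.design.coded).max()
        )
        for s, col, bound in ((-1.0, 0, wp[j] - lo_cd), (1.0, 1, hi_cd - wp[j])):
            bound = max(bound, 0.0)
            point = wp.copy()
            point[j] = wp[j] + s * bound
            if ev(point) >= target:
                ext[j, col] = bound
                continue
            lo_t, hi_t = 0.0, bound
            for _ in range(bisect_iter):
                mid = 0.5 * (lo_t + hi_t)
                point[j] = wp[j] + s * mid
                if ev(point) >= target:
                    lo_t = mid
                else:
                    hi_t = mid
            ext[j, col] = lo_t

    # vertex validation with proportional shrink
    scale = 1.0
    min_pass = 0.0
    for _ in range(max_shrink_iter):
        lo = wp - scale * ext[:, 0]
        hi = wp + scale * ext[:, 1]
        corners = np.unique(
            np.array(list(itertools.product(*zip(lo, hi)))), axis=0
        )
        passes = np.array([ev(c) for c in corners])
        min_pass = float(passes.min())
        if min_pass >= target:
            break
        scale *= shrink
    return MODRBox(list(factors), wp, wp - scale * ext[:, 0],
                   wp + scale * ext[:, 1], min_pass)


def verify_edges(
    results: dict[str, SurfaceResults],
    specs,
    box: MODRBox,
) -> pd.DataFrame:
    """Mean CMA predictions and spec flags at every box vertex.

    This is the desk counterpart of the wet-lab edge-verification runs:
    each row is one corner of the operating box with the model-predicted
    response means (original scale) and per-spec compliance.
    """
    corners = box.vertices()
    rows = []
    for c in corners:
        row = {
            f.name: float(f.decode(c[j])) for j, f in enumerate(box.factors)
        }
        all_pass = True
        for spec in specs:
            mean = float(results[spec.response].predict(c[None, :])[0])
            ok = bool(spec.passes(mean))
            row[f"pred_{spec.response}"] = mean
            row[f"pass_{spec.response}"] = ok
            all_pass &= ok
        row["all_pass"] = all_pass
        rows.append(row)
    return pd.DataFrame(rows)
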