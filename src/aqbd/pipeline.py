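"""End-to-end orchestration: screen -> response surfaces -> MODR -> robustness.

``run_pipeline`` reproduces the full method-development analysis from a
:class:`~aqbd.io.StudyConfig` plus design/response tables (the embedded
study tables by default), writing a report bundle of CSV tables, an
optional set of figures, a machine-readable ``summary.json`` and a run
log.  All randomness flows from the single config seed; rerunning with
the same inputs gives a byte-identical summary.
"""

from __future__ import annotations

import json
import platform
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .design import DesignMatrix, plackett_burman
from .io import StudyConfig, write_design, write_responses
from .modr import (
    MODRConfig,
    extract_modr_box,
    joint_pass_probability,
    probability_map,
    verify_edges,
)
from .robustness import PlackettBurmanLinear, suitability_ranges
from .rsm import QuadraticSurface, make_panels, sweet_spot
from .screening import FreeWilson
from .simulate import TruthModel, simulate_study

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


#: physical robustness perturbations around the working point
ROBUSTNESS_DELTAS = {
    "pH": 0.05, "Buffer conc": 1.0, "CyD conc": 1.0,
    "V": 1.5, "BuOH conc": 0.10, "SDS conc": 2.5, "T": 1.0,
}


def _round_floats(obj, nd: int = 6):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), nd)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(
    config: StudyConfig | None = None,
    outdir=None,
    rsm_design: DesignMatrix | None = None,
    rsm_responses: pd.DataFrame | None = None,
    screening_design: DesignMatrix | None = None,
    screening_responses: pd.DataFrame | None = None,
    make_plots: bool = False,
) -> dict:
    """Run the full analysis; returns the machine-readable summary dict.

    Stage failures are recorded under ``errors`` with the stage name and
    abort the stages that depend on them.
    """
    config = config or StudyConfig.default()
    outdir = Path(outdir) if outdir is not None else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    summary: dict = {
        "config": config.to_dict(),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "errors": [],
    }

    def fail(stage, exc):
        summary["errors"].append({"stage": stage, "error": str(exc)})
        log.append(f"[{stage}] FAILED: {exc}")

    # ------------------------------------------------------------------ screen
    try:
        if screening_design is None:
            screening_design, screening_responses = datasets.table2_fixture()
        screen = {}
        for name in screening_responses.columns:
            res = FreeWilson(
                screening_responses[name].to_numpy(), screening_design
            ).fit()
            an = res.anova
            screen[name] = {
                "anova_F": an["F"], "anova_p": an["p"],
                "significant": bool(an["computable"] and an["p"] < 0.05),
                "best_levels": {
                    f: int(np.argmax(v) + 1)
                    for f, v in res.level_effects().iterrows()
                },
            }
            if outdir:
                res.level_effects().to_csv(
                    outdir / f"screen_effects_{name}.csv"
                )
                res.level_contrasts().to_csv(
                    outdir / f"screen_contrasts_{name}.csv", index=False
                )
        summary["screening"] = screen
        log.append(f"[screen] fitted {len(screen)} Free-Wilson models")
    except Exception as exc:  # noqa: BLE001 - stage isolation
        fail("screen", exc)

    # --------------------------------------------------------------------- rsm
    results = None
    try:
        if rsm_design is None:
            rsm_design, rsm_responses = datasets.table3_fixture()
        if rsm_responses is None or rsm_responses.empty:
            raise ValueError("empty response table")
        results = {}
        quality = {}
        for spec in config.specs:
            name = spec.response
            res = (
                QuadraticSurface(
                    rsm_responses[name].to_numpy(), rsm_design,
                    transform=config.transforms.get(name),
                )
                .fit()
                .refine(alpha=config.refine_alpha)
            )
            results[name] = res
            quality[name] = {
                "r2": res.rsquared, "q2": res.q2, "n_used": res.n_used,
                "n_terms": len(res.term_idx), "terms": res.term_names,
                "transform": res.transform,
            }
            if outdir:
                res.coefficient_table().to_csv(outdir / f"rsm_{name}.csv")
        summary["rsm"] = quality
        log.append(f"[rsm] refined {len(results)} quadratic models")
    except Exception as exc:  # noqa: BLE001
        fail("rsm", exc)

    # -------------------------------------------------------------- sweet spot
    grid = None
    if results is not None:
        try:
            panel_levels = [-5.0 / 3.0, 0.0, 5.0 / 3.0]  # 20/25/30 physical
            grid = make_panels(
                config.factors, x="pH", y="CyD conc",
                panel_rows=("V", panel_levels),
                panel_cols=("Buffer conc", panel_levels),
                fixed={"BuOH conc": 0.0},
                n=config.mc.grid_n,
            )
            sweet = sweet_spot(results, config.specs, grid)
            summary["sweet_spot"] = {
                "full_pass_area": {
                    f"V={k[0]:+.2f},Buffer={k[1]:+.2f}": v
                    for k, v in sweet.full_pass_area().items()
                },
                "widest_panel": list(sweet.widest_panel()),
            }
            log.append("[sweet_spot] computed 3x3 overlay")
            if make_plots and outdir:
                from .plots import plot_sweet_spot

                plot_sweet_spot(sweet, path=outdir / "sweet_spot.png")
        except Exception as exc:  # noqa: BLE001
            fail("sweet_spot", exc)

    # -------------------------------------------------------------------- modr
    box = None
    if results is not None:
        try:
            wp = config.working_point_coded()
            wp_pass = joint_pass_probability(
                results, config.specs, wp,
                n_sims=config.mc.n_sims,
                seed=config.mc.seed,
            )
            pmap = probability_map(
                results, config.specs, grid, config.mc,
                n_sims=config.map_n_sims,
            )
            box = extract_modr_box(
                results, config.specs, wp, config.mc,
                n_sims=config.box_n_sims,
            )
            edges = verify_edges(results, config.specs, box)
            summary["modr"] = {
                "working_point_pass_percent": wp_pass,
                "dpmo_target": config.mc.dpmo_target,
                "inmodr_area": {
                    f"V={k[0]:+.2f},Buffer={k[1]:+.2f}": v
                    for k, v in pmap.inmodr_area().items()
                },
                "widest_panel": list(pmap.widest_panel()),
                "box_intervals": _round_floats(
                    box.intervals.reset_index().to_dict(orient="records")
                ),
                "min_vertex_pass_percent": box.min_vertex_pass,
                "all_edges_pass": bool(edges["all_pass"].all()),
            }
            if outdir:
                box.intervals.to_csv(outdir / "modr_box.csv")
                edges.to_csv(outdir / "modr_edges.csv", index=False)
                for key, risk in pmap.risk.items():
                    tag = f"V{key[0]:+.2f}_B{key[1]:+.2f}".replace(".", "p")
                    pd.DataFrame(
                        risk, index=pmap.grid.y_coded,
                        columns=pmap.grid.x_coded,
                    ).to_csv(outdir / f"risk_{tag}.csv")
            if make_plots and outdir:
                from .plots import plot_probability_map

                plot_probability_map(pmap, path=outdir / "risk_map.png")
            log.append(
                f"[modr] working point pass = {wp_pass:.2f}%"
            )
        except Exception as exc:  # noqa: BLE001
            fail("modr", exc)

    # -------------------------------------------------------------- robustness
    if results is not None:
        try:
            truth = TruthModel(
                [f.name for f in config.factors],
                {n: dict(zip(r.terms, r.params)) for n, r in results.items()},
                {n: r.residual_sd for n, r in results.items()},
                transform={
                    n: t for n, t in config.transforms.items() if n in results
                },
            )
            rob_factors = list(config.factors) + [
                type(config.factors[0])(nm, val, 1.0)
                for nm, val in config.fixed.items()
            ]
            pb = plackett_burman(12, factors=rob_factors)
            # map PB +-1 to coded perturbations around the working point
            wp = config.working_point_coded()
            deltas = np.array(
                [ROBUSTNESS_DELTAS.get(f.name, 0.0) / f.step
                 for f in config.factors]
            )
            coded_rows = wp + pb.coded[:, : len(config.factors)] * deltas
            sim_design = DesignMatrix(
                coded_rows, list(config.factors), design_kind="custom"
            )
            rob_responses = simulate_study(
                truth, sim_design,
                seed=np.random.SeedSequence([config.mc.seed, 7]),
            )
            rob = {}
            for name in rob_responses.columns:
                y = rob_responses[name]
                if y.isna().any():
                    rob[name] = {"significant_factors": None,
                                 "note": "missing values (co-migration)"}
                    continue
                fitres = PlackettBurmanLinear(y.to_numpy(), pb).fit()
                rob[name] = {
                    "significant_factors": fitres.significant_factors(),
                    "error_source": fitres.error_source,
                }
                if outdir:
                    fitres.table().to_csv(outdir / f"robustness_{name}.csv")
            preds = {
                n: float(r.predict(wp[None, :])[0])
                for n, r in results.items()
            }
            ranges = suitability_ranges(rob_responses, preds)
            summary["robustness"] = {
                "models": rob,
                "suitability_ranges": [
                    {"response": r.response, "low": r.low, "high": r.high,
                     "widened": r.widened}
                    for r in ranges
                ],
            }
            if outdir:
                write_responses(rob_responses, outdir / "robustness_data.csv")
            log.append("[robustness] synthetic PB study analyzed")
        except Exception as exc:  # noqa: BLE001
            fail("robustness", exc)

    summary = _round_floats(summary)
    if outdir:
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
        with open(outdir / "run.log", "w") as fh:
            fh.write(f"seed: {config.mc.seed}\n")
            fh.write(f"python: {sys.version.split()[0]}\n")
            fh.write("\n".join(log) + "\n")
    return summary
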