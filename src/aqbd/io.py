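"""Delimited-text I/O and study configuration.

Tables are plain comma-separated text: an optional ``#coding=coded`` /
``#coding=physical`` comment line, one header row (factor names with
units in brackets, or response names), a ``run_id`` first column, and one
row per run.  Missing response cells are written and read as ``n.d.``.
The parser is strict: any cell that is not a plain decimal-point numeral
(or ``n.d.``/empty) is a hard error naming the file and line — locale
decimals such as ``1,48`` change the field count and are rejected, never
silently coerced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import DesignMatrix, Factor
from .modr import CMASpec, MODRConfig

__all__ = [
    "ParseError",
    "read_table",
    "read_design",
    "read_responses",
    "write_design",
    "write_responses",
    "StudyConfig",
]

_MISSING = {"", "n.d.", "nd", "na"}


class ParseError(ValueError):
    """A malformed table cell, located by file and line."""


def _parse_cell(cell: str, path, lineno: int, colname: str) -> float:
    s = cell.strip()
    if s.lower() in _MISSING:
        return np.nan
    try:
        return float(s)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: column {colname!r}: cannot parse {cell!r} "
            "as a number (decimal point '.', no thousands separators)"
        ) from None


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Parse a delimited table into a run_id-indexed frame plus metadata."""
    path = Path(path)
    meta: dict = {}
    header: list[str] | None = None
    ids, rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
                continue
            cells = line.split(",")
            if header is None:
                header = [c.strip() for c in cells]
                if not header or header[0] != "run_id":
                    raise ParseError(
                        f"{path}:{lineno}: first header column must be 'run_id'"
                    )
                continue
            if len(cells) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got "
                    f"{len(cells)} (check for locale decimals like '1,48')"
                )
            try:
                ids.append(int(cells[0]))
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: run_id {cells[0]!r} is not an integer"
                ) from None
            rows.append(
                [_parse_cell(c, path, lineno, h)
                 for c, h in zip(cells[1:], header[1:])]
            )
    if header is None or not rows:
        raise ParseError(f"{path}: empty table (no header or no data rows)")
    df = pd.DataFrame(rows, columns=header[1:],
                      index=pd.Index(ids, name="run_id"))
    return df, meta


def _match_column(df: pd.DataFrame, factor: Factor) -> str:
    for cand in (factor.label, factor.name):
        if cand in df.columns:
            return cand
    raise ParseError(
        f"no column found for factor {factor.name!r} "
        f"(expected {factor.label!r})"
    )


def read_design(path, factors: list[Factor],
                design_kind: str = "custom") -> DesignMatrix:
    """Read a design table; physical tables are coded via the factors."""
    df, meta = read_table(path)
    coding = meta.get("coding", "physical")
    cols = [df[_match_column(df, f)].to_numpy(float) for f in factors]
    mat = np.column_stack(cols)
    if np.isnan(mat).any():
        raise ParseError(f"{path}: design tables cannot contain missing cells")
    if coding == "physical":
        mat = np.column_stack(
            [f.code(mat[:, j]) for j, f in enumerate(factors)]
        )
    elif coding != "coded":
        raise ParseError(f"{path}: unknown coding {coding!r}")
    return DesignMatrix(mat, list(factors), design_kind=design_kind,
                        run_ids=df.index.to_numpy())


def read_responses(path) -> pd.DataFrame:
    df, _ = read_table(path)
    return df


def _fmt(x: float, rounding: int) -> str:
    if np.isnan(x):
        return "n.d."
    return f"{x:.{max(rounding, 0)}f}"


def write_design(design: DesignMatrix, path, coding: str = "physical") -> None:
    path = Path(path)
    df = design.to_frame(coding=coding)
    with open(path, "w") as fh:
        fh.write(f"#coding={coding}\n")
        fh.write("run_id," + ",".join(df.columns) + "\n")
        for rid, row in zip(df.index, df.to_numpy()):
            if coding == "physical":
                cells = [
                    _fmt(v, f.rounding)
                    for v, f in zip(row, design.factors)
                ]
            else:
                cells = [f"{v:.6g}" for v in row]
            fh.write(f"{rid}," + ",".join(cells) + "\n")


def write_responses(df: pd.DataFrame, path, decimals: int = 6) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("run_id," + ",".join(df.columns) + "\n")
        for rid, row in zip(df.index, df.to_numpy(float)):
            cells = ["n.d." if np.isnan(v) else f"{v:.{decimals}g}"
                     for v in row]
            fh.write(f"{rid}," + ",".join(cells) + "\n")


# ---------------------------------------------------------------------------
# study configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Everything a method-development analysis needs, in one object."""

    factors: list[Factor]
    specs: list[CMASpec]
    working_point: dict[str, float]
    transforms: dict[str, str] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)
    mc: MODRConfig = field(default_factory=MODRConfig)
    #: draws per node for risk maps (maps trade draws for nodes)
    map_n_sims: int = 2000
    #: draws per evaluation during box extraction
    box_n_sims: int = 4000
    refine_alpha: float = 0.05

    def __post_init__(self):
        names = {f.name for f in self.factors}
        for f in self.factors:
            if f.name in self.fixed:
                raise ValueError(
                    f"factor {f.name!r} is declared both variable and fixed"
                )
        for nm in self.working_point:
            if nm not in names:
                raise ValueError(f"working point names unknown factor {nm!r}")
        for nm, tr in self.transforms.items():
            if tr not in ("log10",):
                raise ValueError(f"unknown transform {tr!r} for {nm!r}")

    @property
    def response_names(self) -> list[str]:
        return [s.response for s in self.specs]

    def working_point_coded(self) -> np.ndarray:
        return np.array(
            [f.code(self.working_point[f.name]) for f in self.factors]
        )

    @classmethod
    def default(cls) -> "StudyConfig":
        """The embedded trimecaine-study configuration."""
        from . import datasets

        return cls(
            factors=datasets.rsm_factors(),
            specs=datasets.default_specs(),
            working_point=datasets.working_point(),
            transforms={"N_I2": "log10"},
            fixed=datasets.fixed_parameters(),
        )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        factors = [
            Factor(
                name=f["name"], center=float(f["center"]),
                step=float(f["step"]), units=f.get("units", ""),
                rounding=int(f.get("rounding", 2)),
                domain=tuple(f["domain"]) if "domain" in f else None,
            )
            for f in raw["factors"]
        ]
        specs = [
            CMASpec(s["response"], s["direction"], float(s["threshold"]))
            for s in raw["specs"]
        ]
        mc_raw = raw.get("mc", {})
        mc = MODRConfig(
            n_sims=int(mc_raw.get("n_sims", 20_000)),
            dpmo_target=float(mc_raw.get("dpmo_target", 100_000)),
            seed=int(mc_raw.get("seed", raw.get("seed", 20230613))),
            grid_n=int(mc_raw.get("grid_n", 21)),
        )
        return cls(
            factors=factors,
            specs=specs,
            working_point=dict(raw.get("working_point", {})),
            transforms=dict(raw.get("transforms", {})),
            fixed=dict(raw.get("fixed", {})),
            mc=mc,
            map_n_sims=int(mc_raw.get("map_n_sims", 2000)),
            box_n_sims=int(mc_raw.get("box_n_sims", 4000)),
            refine_alpha=float(raw.get("refine_alpha", 0.05)),
        )

    def to_dict(self) -> dict:
        return {
            "factors": [
                {"name": f.name, "center": f.center, "step": f.step,
                 "units": f.units, "rounding": f.rounding,
                 "domain": list(f.domain) if f.domain else None}
                for f in self.factors
            ],
            "specs": [
                {"response": s.response, "direction": s.direction,
                 "threshold": s.threshold}
                for s in self.specs
            ],
            "working_point": self.working_point,
            "transforms": self.transforms,
            "fixed": self.fixed,
            "mc": {"n_sims": self.mc.n_sims,
                   "dpmo_target": self.mc.dpmo_target,
                   "seed": self.mc.seed, "grid_n": self.mc.grid_n,
                   "map_n_sims": self.map_n_sims,
                   "box_n_sims": self.box_n_sims},
            "refine_alpha": self.refine_alpha,
        }
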