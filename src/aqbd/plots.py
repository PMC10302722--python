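"""Diagnostic and design-space graphics.

Matches the displays method developers read during a QbD campaign:
per-level effect bars for the screen, sweet-spot overlays counting how
many CMA criteria the mean predictions satisfy, and risk maps with the
compliance isoline.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
from matplotlib import colors  # noqa: E402

from .modr import ProbabilityMap  # noqa: E402
from .rsm import SweetSpot  # noqa: E402

__all__ = [
    "plot_level_effects",
    "plot_level_contrasts",
    "plot_sweet_spot",
    "plot_probability_map",
]


def plot_level_effects(results, title: str = "", path=None):
    """Three bars per factor: predicted response at each tested level."""
    eff = results.level_effects()
    k = len(eff)
    fig, ax = plt.subplots(figsize=(1.4 * k + 1, 3.2))
    width = 0.25
    xs = np.arange(k)
    for lv in range(3):
        ax.bar(xs + (lv - 1) * width, eff.iloc[:, lv], width,
               label=f"level {lv + 1}")
    ax.axhline(results.params[0], lw=0.8, color="k", alpha=0.5)
    ax.set_xticks(xs, eff.index, rotation=30, ha="right")
    ax.set_ylabel("predicted response")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_level_contrasts(results, alpha: float = 0.05, title: str = "",
                         path=None):
    """Level-change effects; significant contrasts highlighted."""
    tab = results.level_contrasts(alpha=alpha)
    labels = [
        f"{r.factor}\n{r.from_level}->{r.to_level}" for r in tab.itertuples()
    ]
    cols = ["tab:orange" if s else "tab:gray" for s in tab.significant]
    fig, ax = plt.subplots(figsize=(0.45 * len(tab) + 1, 3.2))
    ax.bar(range(len(tab)), tab.estimate, color=cols,
           yerr=tab.se, capsize=2)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(range(len(tab)), labels, fontsize=6)
    ax.set_title(title or f"level changes (orange: p < {alpha})")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def _panel_axes(grid, fig_title):
    rows = sorted({k[0] for k in grid.panels})
    cols = sorted({k[1] for k in grid.panels})
    fig, axes = plt.subplots(
        len(rows), len(cols), figsize=(3 * len(cols), 2.6 * len(rows)),
        sharex=True, sharey=True, squeeze=False,
    )
    fig.suptitle(fig_title, fontsize=10)
    return fig, axes, rows, cols


def plot_sweet_spot(sweet: SweetSpot, factors=None, path=None):
    """Satisfied-criteria counts; the darkest zone meets every criterion."""
    grid = sweet.grid
    cmap = colors.ListedColormap(
        ["#7f1d1d", "#ef4444", "#f97316", "#facc15", "#a3e635", "#166534"]
        [-(sweet.n_specs + 1):]
    )
    fig, axes, rows, cols = _panel_axes(
        grid, f"sweet spot: {grid.y_name} vs {grid.x_name}"
    )
    for i, rv in enumerate(rows):
        for j, cv in enumerate(cols):
            ax = axes[i][j]
            ax.pcolormesh(
                grid.x_coded, grid.y_coded, sweet.counts[(rv, cv)],
                cmap=cmap, vmin=0, vmax=sweet.n_specs, shading="nearest",
            )
            ax.set_title(
                f"{grid.panel_names[0]}={rv:+.2f}, "
                f"{grid.panel_names[1]}={cv:+.2f} (coded)", fontsize=7,
            )
    for ax in axes[-1]:
        ax.set_xlabel(grid.x_name, fontsize=8)
    for row in axes:
        row[0].set_ylabel(grid.y_name, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_probability_map(pmap: ProbabilityMap, path=None):
    """% risk of failing any criterion, with the target isoline."""
    grid = pmap.grid
    risk_limit = pmap.dpmo_target / 10_000.0
    fig, axes, rows, cols = _panel_axes(
        grid, f"failure risk (%), isoline at {risk_limit:g}%"
    )
    for i, rv in enumerate(rows):
        for j, cv in enumerate(cols):
            ax = axes[i][j]
            r = pmap.risk[(rv, cv)]
            ax.pcolormesh(grid.x_coded, grid.y_coded, r, cmap="RdYlGn_r",
                          vmin=0, vmax=100, shading="nearest")
            if (r <= risk_limit).any() and (r > risk_limit).any():
                ax.contour(grid.x_coded, grid.y_coded, r,
                           levels=[risk_limit], colors="k", linewidths=1.0)
            ax.set_title(
                f"{grid.panel_names[0]}={rv:+.2f}, "
                f"{grid.panel_names[1]}={cv:+.2f} (coded)", fontsize=7,
            )
    for ax in axes[-1]:
        ax.set_xlabel(grid.x_name, fontsize=8)
    for row in axes:
        row[0].set_ylabel(grid.y_name, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
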