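"""Figure builders for screen and multistability results.

Each function takes the plot-ready tables produced by the analysis
modules and returns a matplotlib Figure; nothing here recomputes results.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .model import MRNAS, ODESystem  # noqa: E402
from .simulate import Trajectory  # noqa: E402

__all__ = ["spoke_plot", "trajectory_grid", "multistability_figure"]


def spoke_plot(table: pd.DataFrame, title: str = "parameter sets scoring below threshold"):
    """Radial display of hit parameter sets.

    ``table`` is the output of :func:`segpol.sampling.plot_solutions`: one
    spoke per displayed parameter, radius = normalized log position in the
    sampling range; the mean/sd rows are drawn in black.
    """
    cols = list(table.columns)
    hits = table.drop(index=[i for i in ("mean", "sd") if i in table.index])
    theta = np.linspace(0, 2 * np.pi, len(cols), endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    closed = np.append(theta, theta[0])
    for _, row in hits.iterrows():
        vals = row[cols].to_numpy(dtype=float)
        ax.plot(closed, np.append(vals, vals[0]), color="tab:orange",
                alpha=min(1.0, 20.0 / max(len(hits), 1)), lw=0.6)
    if "mean" in table.index:
        mean = table.loc["mean", cols].to_numpy(dtype=float)
        sd = table.loc["sd", cols].to_numpy(dtype=float)
        ax.plot(closed, np.append(mean, mean[0]), color="black", lw=2)
        for sign in (-1, 1):
            band = np.clip(mean + sign * sd, 0, 1)
            ax.plot(closed, np.append(band, band[0]), color="black", lw=1, ls="--")
    ax.set_xticks(theta)
    ax.set_xticklabels(cols, fontsize=7)
    ax.set_ylim(0, 1)
    ax.set_title(title)
    return fig


def trajectory_grid(traj: Trajectory, model: ODESystem,
                    species: tuple[str, ...] = MRNAS):
    """Per-cell time-course panels (columns = cells along the row).

    The dashed separator between cells 2 and 3 marks the parasegment
    boundary of the target pattern.
    """
    n_cells = model.n_cells
    fig, axes = plt.subplots(1, n_cells, figsize=(3 * n_cells, 2.8),
                             sharey=True, squeeze=False)
    for c in range(n_cells):
        ax = axes[0, c]
        for nm in species:
            ax.plot(traj.times, traj.states[:, model.species_index(nm, c)],
                    label=nm, lw=1)
        ax.set_title(f"cell {c + 1}")
        ax.set_xlabel("time")
    axes[0, 0].set_ylabel("concentration")
    axes[0, 0].legend(fontsize=7)
    if n_cells == 4:
        fig.subplots_adjust(wspace=0.25)
        mid = (axes[0, 1].get_position().x1 + axes[0, 2].get_position().x0) / 2
        fig.add_artist(plt.Line2D([mid, mid], [0.1, 0.9], color="k", ls="--",
                                  transform=fig.transFigure))
    return fig


def multistability_figure(tables: dict[str, pd.DataFrame],
                          parameters: tuple[str, str] = ("kappa_CNptc", "kappa_CNen")):
    """Scatter of a parameter pair plus marginal histograms, mono vs multi."""
    px, py = parameters
    sc = tables["scatter"]
    fig, axes = plt.subplots(2, 2, figsize=(8, 8),
                             gridspec_kw={"width_ratios": [3, 1],
                                          "height_ratios": [1, 3]})
    axes[0, 1].axis("off")
    ax = axes[1, 0]
    for cls, color in (("monostable", "tab:blue"), ("multistable", "tab:orange")):
        sub = sc[sc["class"] == cls]
        ax.scatter(sub[px], sub[py], s=8, alpha=0.5, color=color, label=cls)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(px)
    ax.set_ylabel(py)
    ax.legend(fontsize=8)
    for axh, p, orient in ((axes[0, 0], px, "vertical"), (axes[1, 1], py, "horizontal")):
        h = tables[f"hist_{p}"]
        centers = np.sqrt(h["bin_low"] * h["bin_high"])
        widths = h["bin_high"] - h["bin_low"]
        if orient == "vertical":
            axh.bar(centers, h["monostable"], width=widths, alpha=0.5, color="tab:blue")
            axh.bar(centers, h["multistable"], width=widths, alpha=0.5, color="tab:orange")
            axh.set_xscale("log")
        else:
            axh.barh(centers, h["monostable"], height=widths, alpha=0.5, color="tab:blue")
            axh.barh(centers, h["multistable"], height=widths, alpha=0.5, color="tab:orange")
            axh.set_yscale("log")
    return fig
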