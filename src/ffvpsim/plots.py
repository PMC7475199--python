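"""Optional matplotlib views of the reporting tables.

Each function takes a table produced by :mod:`ffvpsim.report` and returns
a Figure; nothing here computes statistics, so the analysis itself stays
headless and testable without a display.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_pattern_bubbles", "plot_trajectory_panel", "plot_effect_bars"]


def plot_pattern_bubbles(patterns: pd.DataFrame):
    """Bubble plot: mean end-of-study servings vs years of FFVP exposure,
    bubble area proportional to the number of agents in the pattern."""
    fig, ax = plt.subplots(figsize=(7, 5))
    n = patterns["n"].to_numpy(dtype=float)
    size = 2000.0 * n / max(n.max(), 1.0)
    ax.scatter(patterns["exposure_years"], patterns["mean_servings"], s=size, alpha=0.5)
    ax.set_xlabel("Years of FFVP exposure (K–6)")
    ax.set_ylabel("Mean servings of fruits and vegetables by grade 6")
    ax.set_title("Predicted servings by exposure pattern")
    fig.tight_layout()
    return fig


def plot_trajectory_panel(panel: pd.DataFrame):
    """Mean preference-formation curves per exposure pattern over the 1260
    simulated school days."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for pattern, g in panel.groupby("exposure_pattern"):
        ax.plot(g["step"], g["mean_v_hat_H"], label=pattern)
    ax.set_xlabel("School day (K–6)")
    ax.set_ylabel("Mean perceived valuation of healthy food")
    ax.set_ylim(0, 1)
    ax.legend(title="Exposure pattern", fontsize=8)
    fig.tight_layout()
    return fig


def plot_effect_bars(effects: pd.DataFrame):
    """FFVP effect on servings by food-desert exposure."""
    fig, ax = plt.subplots(figsize=(5, 4))
    rows = effects[effects["group"] != "total"]
    ax.bar(rows["group"], rows["ffvp_effect"], color=["#4c72b0", "#dd8452"])
    ax.set_ylabel("FFVP effect on mean servings")
    ax.set_title("Program effect by food environment")
    fig.tight_layout()
    return fig
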