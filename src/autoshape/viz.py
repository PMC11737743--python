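"""Plotting glue: trajectory curves and Q-Q diagnostics.

Thin matplotlib wrappers; everything they draw comes from the exported
tables, so figures are optional and reproducible from CSV alone.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .shaping import FUNCTION_LABELS

__all__ = ["plot_trajectories", "plot_qq"]

_COLORS = {"concave_up": "#1b9e77", "linear": "#7570b3", "concave_down": "#d95f02"}


def plot_trajectories(curves: pd.DataFrame, path: str | Path) -> None:
    """Arm-averaged raw and smoothed target-probability trajectories."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for lab in FUNCTION_LABELS:
        sub = curves[curves["function_label"] == lab]
        mean = sub.groupby("click_index")[["raw", "smoothed"]].mean()
        ax.plot(mean.index, mean["raw"], ".", ms=3, alpha=0.4, color=_COLORS[lab])
        ax.plot(mean.index, mean["smoothed"], "-", lw=2, color=_COLORS[lab], label=lab)
    ax.set_xlabel("click index")
    ax.set_ylabel("P(target click)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_qq(qq: pd.DataFrame, path: str | Path) -> None:
    """Normal Q-Q plot of standardized model residuals."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(qq["theoretical"], qq["observed"], "o", ms=3, alpha=0.6)
    lim = [qq["theoretical"].min(), qq["theoretical"].max()]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel("theoretical quantile")
    ax.set_ylabel("observed quantile")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
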