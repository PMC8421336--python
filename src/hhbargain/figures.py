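"""Plots: behaviour-change-vs-wage panels and single-run time series."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_behavior_change", "plot_time_series"]

_MODEL_COLORS = {"ihm": "tab:red", "im": "tab:blue", "um": "tab:green"}


def plot_behavior_change(summary: pd.DataFrame, path: str) -> None:
    """Panel grid of per-agent delta_alpha against post-change wage.

    One panel per (gender, condition); colour encodes the model.  Mirrors
    the standard presentation of the wage-sweep experiment.
    """
    genders = sorted(summary["gender"].unique())
    conditions = sorted(summary["condition"].unique())
    fig, axes = plt.subplots(
        len(genders), len(conditions),
        figsize=(5 * len(conditions), 4 * len(genders)),
        squeeze=False, sharey=True,
    )
    for i, g in enumerate(genders):
        for j, c in enumerate(conditions):
            ax = axes[i][j]
            sub = summary[(summary["gender"] == g) & (summary["condition"] == c)]
            for model, rows in sub.groupby("model"):
                color = _MODEL_COLORS.get(model, "gray")
                ax.scatter(rows["w_f_post"], rows["delta_alpha"], s=4,
                           alpha=0.25, color=color)
                mean = rows.groupby("w_f_post")["delta_alpha"].mean()
                ax.plot(mean.index, mean.values, color=color, label=model.upper())
            ax.axhline(0, lw=0.5, color="k")
            ax.set_title(f"{g}, {c.upper()}")
            ax.set_xlabel("post-change female wage $w_f$")
            ax.set_ylabel(r"$\Delta\alpha$ ($t=26$ to $t=150$)")
            ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_time_series(series: pd.DataFrame, path: str) -> None:
    """Per-agent alpha trajectories (by gender) plus household transfers."""
    fig, ax = plt.subplots(figsize=(8, 4.5))
    t_change = None
    for agent_id, rows in series.groupby("agent_id"):
        color = "tab:red" if rows["gender"].iloc[0] == "female" else "tab:blue"
        ax.plot(rows["t"], rows["alpha"], color=color, alpha=0.15, lw=0.7)
    theta = (
        series[series["gender"] == "female"]
        .groupby(["household_id", "t"])["theta"].first().reset_index()
    )
    for hh, rows in theta.groupby("household_id"):
        ax.plot(rows["t"], rows["theta"], color="k", alpha=0.15, lw=0.7)
    if "w_f_post" in series:
        t_change = series.attrs.get("t_change", 25)
    if t_change:
        ax.axvline(t_change, color="gray", ls="--", lw=1)
    ax.set_xlabel("t")
    ax.set_ylabel(r"$\alpha$ (red: female, blue: male); $\theta$ (black)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
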