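"""Wage-sweep experiments and behaviour-change analytics.

The headline experiment raises the female wage from 0.1 to each value of a
grid (default: the twelve levels 0.15, 0.2, 0.25, 0.3, 0.4, ..., 1.0, 1.1)
at step 25, runs each simulation to step 150, and measures each agent's
change in private-activity time between the step after the change (t = 26)
and the end (t = 150).  All sweep cells share the seed, and hence the same
population and the same pre-change trajectory.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .engine import (
    ModelConfig,
    continue_run,
    prepare_prechange_state,
    sample_parameters,
)

__all__ = [
    "DEFAULT_WAGE_GRID",
    "behavior_change",
    "wage_sweep",
    "pearson_r",
    "transition_threshold",
    "compare_groups",
    "summarize_sweep",
]

#: Post-change female wage levels of the standard experiment.
DEFAULT_WAGE_GRID = (0.15, 0.2, 0.25, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1)


def behavior_change(
    series: pd.DataFrame, t_from: int = 26, t_to: int = 150
) -> pd.DataFrame:
    """Per-agent change in private-activity time, alpha(t_to) - alpha(t_from).

    ``series`` is a tidy run table from :func:`hhbargain.engine.run`.
    Returns one row per agent with the run's grouping keys attached.
    """
    sub = series[series["t"].isin([t_from, t_to])]
    present = set(sub["t"].unique())
    if present != {t_from, t_to}:
        missing = sorted({t_from, t_to} - present)
        raise ValueError(f"steps {missing} not present in series")
    wide = sub.pivot_table(index="agent_id", columns="t", values="alpha")
    keys = (
        sub[["agent_id", "model", "condition", "seed", "w_f_post", "gender"]]
        .drop_duplicates("agent_id")
        .set_index("agent_id")
    )
    out = keys.copy()
    out["delta_alpha"] = wide[t_to] - wide[t_from]
    return out.reset_index()


def wage_sweep(
    config: ModelConfig,
    wage_grid: tuple[float, ...] = DEFAULT_WAGE_GRID,
    t_from: int = 26,
    t_to: int = 150,
    keep_series: bool = False,
) -> pd.DataFrame:
    """Run one simulation per post-change wage and collect per-agent deltas.

    All runs share ``config.seed`` (identical populations and pre-change
    segment; the pre-change steps are computed once and reused).  Returns
    the long per-agent table; with ``keep_series=True`` the full
    concatenated time series is attached as ``df.attrs['series']``.
    """
    if not wage_grid:
        raise ValueError("wage grid must be non-empty")
    if any(w <= 0 for w in wage_grid):
        raise ValueError("wages must be > 0")
    agents, high = sample_parameters(
        config.condition, config.n_agents, config.seed,
        w_f=config.w_f_pre, w_m=config.w_m,
    )
    base_cfg = replace(config, w_f_post=float(wage_grid[0]))
    prefix = prepare_prechange_state(base_cfg, agents, high)
    deltas = []
    all_series = []
    for w in wage_grid:
        cfg_w = replace(config, w_f_post=float(w))
        st = prefix.copy()
        st.config = cfg_w
        series = continue_run(st, cfg_w)
        deltas.append(behavior_change(series, t_from, t_to))
        if keep_series:
            all_series.append(series)
    out = pd.concat(deltas, ignore_index=True)
    if keep_series:
        out.attrs["series"] = pd.concat(all_series, ignore_index=True)
    return out


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y).statistic)


def transition_threshold(
    summary: pd.DataFrame,
    gender: str,
    rel_threshold: float = 0.05,
) -> tuple[float, bool]:
    """Largest grid wage at which a gender's mean response is still "flat".

    Operationalizes a sudden workforce transition: the threshold is the
    largest wage whose mean absolute delta_alpha is below ``rel_threshold``
    times the maximum mean absolute delta over the grid.  Returns
    ``(wage, transitioned)``; when no wage exceeds the flatness cut-off the
    largest grid wage is returned with ``transitioned=False``.
    """
    grp = summary[summary["gender"] == gender]
    if grp.empty:
        raise ValueError(f"no rows for gender {gender!r}")
    curve = grp.groupby("w_f_post")["delta_alpha"].mean().abs().sort_index()
    peak = curve.max()
    if peak <= 0:
        return float(curve.index[-1]), False
    flat = curve[curve < rel_threshold * peak]
    if flat.empty or len(flat) == len(curve):
        return float(curve.index[-1]), False
    return float(flat.index.max()), True


def compare_groups(deltas_low, deltas_high) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t test: (statistic, p-value)."""
    a = np.asarray(deltas_low, dtype=float)
    b = np.asarray(deltas_high, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("degenerate groups (no variance)")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def summarize_sweep(summary: pd.DataFrame) -> pd.DataFrame:
    """Mean and variance of delta_alpha per (model, condition, gender, wage)."""
    return (
        summary.groupby(["model", "condition", "gender", "w_f_post"])
        ["delta_alpha"]
        .agg(["mean", "var", "count"])
        .reset_index()
    )
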