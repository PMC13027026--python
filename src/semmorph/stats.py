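"""Group-level reporting: summaries, percent changes, and Cliff's delta.

With thousands of cells per condition, tiny mean differences reach
significance under parametric tests regardless of practical relevance, and
the per-cell distributions are right-skewed.  Group comparisons therefore
use Cliff's delta, the non-parametric effect size

    delta = P(X > Y) - P(X < Y),

estimated over all n_x * n_y sample pairs (ties contribute zero), and
categorized by the conventional thresholds: large |delta| >= 0.474, medium
>= 0.33, small >= 0.147, otherwise not significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: |delta| category boundaries (inclusive), largest first.
EFFECT_THRESHOLDS = (("large", 0.474), ("medium", 0.33), ("small", 0.147))

#: Figure-legend star convention: * small, ** medium, *** large.
STARS = {"large": "***", "medium": "**", "small": "*", "ns": "ns"}


@dataclass(frozen=True)
class EffectSize:
    delta: float
    category: str  # ns | small | medium | large

    @property
    def direction(self) -> int:
        return int(np.sign(self.delta))

    @property
    def stars(self) -> str:
        return STARS[self.category]


def categorize_effect(delta: float) -> str:
    """Map a delta in [-1, 1] to its magnitude category (boundaries inclusive)."""
    if abs(delta) > 1 + 1e-12:
        raise ValueError(f"|delta| must be <= 1, got {delta}")
    for name, threshold in EFFECT_THRESHOLDS:
        if abs(delta) >= threshold:
            return name
    return "ns"


def cliffs_delta(x, y) -> EffectSize:
    """Cliff's delta of sample ``x`` versus sample ``y``.

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (n_x * n_y), computed in
    O((n_x + n_y) log n_y) by binary search on the sorted ``y``; equivalent
    to the all-pairs count, including ties.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("Cliff's delta requires two non-empty samples")
    ys = np.sort(y)
    n_less = np.searchsorted(ys, x, side="left").sum()   # y_j <  x_i count
    n_leq = np.searchsorted(ys, x, side="right").sum()   # y_j <= x_i count
    greater = int(n_less)                # pairs with x_i > y_j
    less = int(x.size * y.size - n_leq)  # pairs with x_i < y_j
    delta = (greater - less) / (x.size * y.size)
    return EffectSize(delta=float(delta), category=categorize_effect(delta))


def cliffs_delta_bruteforce(x, y) -> float:
    """All-pairs O(n^2) Cliff's delta (independent cross-check)."""
    x = np.asarray(x, dtype=float).ravel()[:, None]
    y = np.asarray(y, dtype=float).ravel()[None, :]
    return float(((x > y).sum() - (x < y).sum()) / x.size / y.size * 1.0)


def percent_change(treated_mean: float, control_mean: float) -> float:
    """100 * (treated - control) / control, rounded to one decimal."""
    if not control_mean > 0:
        raise ValueError(f"control mean must be > 0, got {control_mean}")
    return round(100.0 * (treated_mean - control_mean) / control_mean, 1)


def _summary(values: np.ndarray, prefix: str) -> dict:
    q1, q2, q3 = np.percentile(values, [25, 50, 75])
    return {
        f"{prefix}_mean": float(np.mean(values)),
        f"{prefix}_sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        f"{prefix}_q1": float(q1),
        f"{prefix}_median": float(q2),
        f"{prefix}_q3": float(q3),
    }


def summarize_groups(
    cells: pd.DataFrame,
    control: str,
    group_col: str = "group",
    metrics: tuple[str, ...] = ("area_um2", "texture_value"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group summaries and treatment-vs-control comparisons.

    ``cells`` holds one row per cell that survived all filters; texture
    summaries additionally require ``texture_valid`` when that column is
    present.  Returns (groups, comparisons) DataFrames: per-group n, mean,
    sd and quartiles for each metric; and, for every non-control group,
    percent change of the group mean versus the control mean plus Cliff's
    delta with its category.  The control compares to itself with percent
    change 0 and delta 0.
    """
    if control not in set(cells[group_col]):
        raise ValueError(f"control group {control!r} not present in cell table")

    group_rows, comparison_rows = [], []
    groups = list(dict.fromkeys(cells[group_col]))  # preserve first-seen order

    def metric_values(frame: pd.DataFrame, metric: str) -> np.ndarray:
        sel = frame
        if metric == "texture_value" and "texture_valid" in frame.columns:
            sel = frame[frame["texture_valid"].astype(bool)]
        return sel[metric].to_numpy(dtype=float)

    for g in groups:
        sub = cells[cells[group_col] == g]
        row: dict = {group_col: g, "n_cells": int(len(sub))}
        for metric in metrics:
            vals = metric_values(sub, metric)
            row[f"n_{metric}"] = int(len(vals))
            if len(vals):
                row.update(_summary(vals, metric))
        group_rows.append(row)

    control_frame = cells[cells[group_col] == control]
    for g in groups:
        sub = cells[cells[group_col] == g]
        row = {group_col: g, "control": control}
        for metric in metrics:
            vals = metric_values(sub, metric)
            ctrl = metric_values(control_frame, metric)
            if g == control:
                row[f"{metric}_pct_change"] = 0.0
                row[f"{metric}_delta"] = 0.0
                row[f"{metric}_category"] = "ns"
            else:
                eff = cliffs_delta(vals, ctrl)
                row[f"{metric}_pct_change"] = percent_change(float(np.mean(vals)),
                                                             float(np.mean(ctrl)))
                row[f"{metric}_delta"] = eff.delta
                row[f"{metric}_category"] = eff.category
        comparison_rows.append(row)

    return pd.DataFrame(group_rows), pd.DataFrame(comparison_rows)


def violin_figure(
    cells: pd.DataFrame,
    metric: str,
    out_path,
    group_col: str = "group",
    ylabel: str | None = None,
):
    """Violin plot per group with quartile lines, written to ``out_path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(dict.fromkeys(cells[group_col]))
    data = []
    for g in groups:
        sub = cells[cells[group_col] == g]
        if metric == "texture_value" and "texture_valid" in sub.columns:
            sub = sub[sub["texture_valid"].astype(bool)]
        data.append(sub[metric].to_numpy(dtype=float))
    fig, ax = plt.subplots(figsize=(1.5 * len(groups) + 2, 4))
    parts = ax.violinplot(data, showextrema=False, showmedians=False)
    for body in parts["bodies"]:
        body.set_alpha(0.6)
    for pos, vals in enumerate(data, start=1):
        if len(vals):
            for q in np.percentile(vals, [25, 50, 75]):
                ax.hlines(q, pos - 0.18, pos + 0.18, lw=0.8, color="k")
    ax.set_xticks(range(1, len(groups) + 1), groups)
    ax.set_ylabel(ylabel or metric)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
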