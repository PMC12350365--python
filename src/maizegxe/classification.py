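"""Empirical hybrid yield classification and the selection heatmap.

Each (hybrid, treatment) pair is summarized by the max, min, median, and
mean of its observed yields and assigned one of six classes by a fixed-order
threshold rule. The rule is a parameterized reconstruction of an empirical
decision logic over the yield distribution: thresholds default to 6 and 10
Mg/ha with a wide-range span of 8 Mg/ha, all configurable.

Class order on the yield scale: extremely low < low < moderate < high <
extremely high, with "wide range" marking hybrids that straddle both low and
high regions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import ClassRule

CLASSES = [
    "extremely low", "low", "moderate", "wide range", "high", "extremely high",
]
NO_DATA = "no data"

#: Fixed color legend for the heatmap (extremely low red .. extremely high blue).
CLASS_COLORS = {
    "extremely low": "#b2182b",
    "low": "#ef8a62",
    "moderate": "#fddbc7",
    "wide range": "#999999",
    "high": "#67a9cf",
    "extremely high": "#2166ac",
    NO_DATA: "#ffffff",
}


def summarize_hybrid_yields(rows: pd.DataFrame) -> pd.DataFrame:
    """Max/min/median/mean yield per observed (hybrid, treatment)."""
    if rows.empty:
        raise ValueError("empty input")
    g = rows.groupby(["Hybrid", "treatment"])["yield"]
    return g.agg(max="max", min="min", median="median", mean="mean", n="count").reset_index()


def classify(stats, rule: ClassRule | None = None) -> str:
    """Assign a six-level yield class from distribution summaries.

    Branches apply in fixed order: (1) max at or below the low threshold is
    extremely low; (2) min at or above the high threshold is extremely high;
    (3) a span from below-low to above-high wider than ``wide_span`` is wide
    range; (4)/(5) the central statistic (median by default) at or beyond a
    threshold gives high/low; (6) otherwise moderate. The rule is total.
    """
    rule = rule or ClassRule()
    mx, mn = float(stats["max"]), float(stats["min"])
    central = float(stats["mean"] if rule.use_mean else stats["median"])
    if mx <= rule.t_low:
        return "extremely low"
    if mn >= rule.t_high:
        return "extremely high"
    if mn < rule.t_low and mx > rule.t_high and (mx - mn) > rule.wide_span:
        return "wide range"
    if central >= rule.t_high:
        return "high"
    if central <= rule.t_low:
        return "low"
    return "moderate"


def build_class_matrix(stats: pd.DataFrame, rule: ClassRule | None = None) -> pd.DataFrame:
    """Hybrids x treatments matrix of class labels; unobserved cells "no data"."""
    if stats.empty:
        raise ValueError("empty stats table")
    rule = rule or ClassRule()
    labels = stats.apply(lambda row: classify(row, rule), axis=1)
    long = stats[["Hybrid", "treatment"]].assign(label=labels)
    matrix = long.pivot(index="Hybrid", columns="treatment", values="label")
    return matrix.fillna(NO_DATA).sort_index()


def render_heatmap(matrix: pd.DataFrame, path: str | Path) -> Path:
    """Render the class matrix as a color-coded PNG heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    order = CLASSES + [NO_DATA]
    lut = {c: i for i, c in enumerate(order)}
    data = matrix.apply(lambda col: col.map(lut)).to_numpy(dtype=float)

    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * matrix.shape[1], 1.0 + 0.3 * matrix.shape[0])
    )
    cmap = ListedColormap([CLASS_COLORS[c] for c in order])
    ax.imshow(data, cmap=cmap, vmin=-0.5, vmax=len(order) - 0.5, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=6)
    ax.set_xlabel("treatment")
    ax.set_ylabel("hybrid")
    handles = [Patch(color=CLASS_COLORS[c], label=c) for c in order]
    ax.legend(handles=handles, bbox_to_anchor=(1.02, 1), loc="upper left", fontsize=7)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
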