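"""Engineered yield features and the per-state yield trend.

All statistics here are computed strictly from training-period rows (year <=
the training cutoff); the caller is responsible for passing only those rows,
and a leakage test in the suite verifies that test-year rows never change
the outputs. Unseen (state, hybrid) combinations in the test year are imputed
as the average of the state-level mean and mode of each statistic column,
the mode being taken on values rounded to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STAT_COLS = ["mean_yield", "max_yield", "min_yield"]


def _mode_1dp(values: pd.Series) -> float:
    """Mode of a continuous column after rounding to 1 decimal.

    Ties break toward the smallest value so the statistic is deterministic.
    """
    rounded = values.round(1)
    counts = rounded.value_counts()
    top = counts[counts == counts.max()].index
    return float(min(top))


def state_hybrid_stats(training: pd.DataFrame) -> pd.DataFrame:
    """Mean/max/min yield per observed (state, hybrid) with its support count."""
    if training.empty:
        raise ValueError("empty training set")
    g = training.groupby(["state", "Hybrid"])["yield"]
    out = g.agg(mean_yield="mean", max_yield="max", min_yield="min", support="count").reset_index()
    return out


def impute_unseen_combo(stats: pd.DataFrame, state: str) -> dict[str, float]:
    """Statistics for a (state, hybrid) combination absent from training.

    Each statistic column is imputed as (state mean of column + state mode of
    column) / 2. A state absent from training falls back to the global column
    mean.
    """
    rows = stats[stats["state"] == state]
    out = {}
    if rows.empty:
        for col in STAT_COLS:
            out[col] = float(stats[col].mean())
        out["provenance"] = "fallback"
        return out
    for col in STAT_COLS:
        out[col] = (float(rows[col].mean()) + _mode_1dp(rows[col])) / 2.0
    out["provenance"] = "imputed"
    return out


def hybrid_stats(training: pd.DataFrame) -> pd.DataFrame:
    """Mean/max/min yield per hybrid over all training rows."""
    if training.empty:
        raise ValueError("empty training set")
    g = training.groupby("Hybrid")["yield"]
    return g.agg(hybrid_mean="mean", hybrid_max="max", hybrid_min="min", support="count").reset_index()


def split_parents(hybrid: str) -> tuple[str, str] | None:
    """Split an F1 hybrid name "Parent1/Parent2"; None when not splittable."""
    if "/" not in str(hybrid):
        return None
    p1, _, p2 = str(hybrid).partition("/")
    return p1, p2


def parent_stats(training: pd.DataFrame) -> pd.DataFrame:
    """Mean yield per parent line over every training row naming that parent.

    A parent contributes from either side of the cross, so reciprocal crosses
    ("A/B" and "B/A") both feed the same two parent pools.
    """
    if training.empty:
        raise ValueError("empty training set")
    rows = []
    for hybrid, grp in training.groupby("Hybrid"):
        parents = split_parents(hybrid)
        if parents is None:
            continue
        for p in parents:
            rows.append(pd.DataFrame({"parent": p, "yield": grp["yield"]}))
    if not rows:
        return pd.DataFrame(columns=["parent", "parent_mean", "support"])
    long = pd.concat(rows, ignore_index=True)
    return long.groupby("parent")["yield"].agg(parent_mean="mean", support="count").reset_index()


@dataclass
class TrendModel:
    """Per-state linear yield trend: predicted = intercept + slope * year."""

    state: str
    intercept: float
    slope: float
    n_years: int

    def predict(self, year: int | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(year, dtype=float)


def fit_state_trend(training: pd.DataFrame) -> dict[str, TrendModel]:
    """Ordinary least squares of yield on calendar year, per state.

    The fit uses row-level observations (each trial contributes one point).
    States observed in a single year get slope 0 and intercept equal to their
    mean yield.
    """
    if training.empty:
        raise ValueError("empty training set")
    models: dict[str, TrendModel] = {}
    for state, grp in training.groupby("state"):
        years = grp["year"].to_numpy(dtype=float)
        y = grp["yield"].to_numpy(dtype=float)
        distinct = np.unique(years)
        if len(distinct) < 2:
            models[state] = TrendModel(state, float(y.mean()), 0.0, 1)
            continue
        slope, intercept = np.polyfit(years, y, 1)
        models[state] = TrendModel(state, float(intercept), float(slope), len(distinct))
    return models


def predict_trend(models: dict[str, TrendModel], state: str, year: int) -> float:
    if state not in models:
        raise KeyError(f"no trend model for state {state!r}")
    return float(models[state].predict(year))


@dataclass
class YieldFeatures:
    """Bundle of all engineered yield features fitted on training rows."""

    state_hybrid: pd.DataFrame
    hybrid: pd.DataFrame
    parent: pd.DataFrame
    trend: dict[str, TrendModel]
    global_means: dict[str, float]


def fit_yield_features(training: pd.DataFrame) -> YieldFeatures:
    sh = state_hybrid_stats(training)
    hy = hybrid_stats(training)
    pa = parent_stats(training)
    trend = fit_state_trend(training)
    globals_ = {
        "mean_yield": float(training["yield"].mean()),
        "max_yield": float(training["yield"].max()),
        "min_yield": float(training["yield"].min()),
    }
    return YieldFeatures(sh, hy, pa, trend, globals_)


def attach_yield_features(rows: pd.DataFrame, feats: YieldFeatures) -> pd.DataFrame:
    """Attach engineered columns to any (train or test) frame.

    Adds state-hybrid mean/max/min (imputed for unseen combinations), hybrid
    mean/max/min, the two parent means, the trend prediction for the row's
    year, and a provenance column.
    """
    out = rows.copy()
    sh = feats.state_hybrid.set_index(["state", "Hybrid"])
    hy = feats.hybrid.set_index("Hybrid")
    pa = feats.parent.set_index("parent")["parent_mean"]

    imputed_cache: dict[str, dict[str, float]] = {}
    sh_vals, hy_vals, parent_vals, prov = [], [], [], []
    for _, row in out.iterrows():
        key = (row["state"], row["Hybrid"])
        if key in sh.index:
            rec = sh.loc[key]
            sh_vals.append((rec["mean_yield"], rec["max_yield"], rec["min_yield"]))
            prov.append("observed")
        else:
            state = row["state"]
            if state not in imputed_cache:
                imputed_cache[state] = impute_unseen_combo(feats.state_hybrid, state)
            rec = imputed_cache[state]
            sh_vals.append((rec["mean_yield"], rec["max_yield"], rec["min_yield"]))
            prov.append(rec["provenance"])
        if row["Hybrid"] in hy.index:
            h = hy.loc[row["Hybrid"]]
            hy_vals.append((h["hybrid_mean"], h["hybrid_max"], h["hybrid_min"]))
        else:
            hy_vals.append((feats.global_means["mean_yield"],) * 3)
        parents = split_parents(row["Hybrid"])
        if parents is None:
            parent_vals.append((np.nan, np.nan))
        else:
            parent_vals.append(tuple(float(pa.get(p, feats.global_means["mean_yield"])) for p in parents))

    out[["sh_mean", "sh_max", "sh_min"]] = np.array(sh_vals, dtype=float)
    out[["hybrid_mean", "hybrid_max", "hybrid_min"]] = np.array(hy_vals, dtype=float)
    out[["parent1_mean", "parent2_mean"]] = np.array(parent_vals, dtype=float)
    out["trend_pred"] = [
        predict_trend(feats.trend, s, y) if s in feats.trend else feats.global_means["mean_yield"]
        for s, y in zip(out["state"], out["year"])
    ]
    out["feature_provenance"] = prov
    return out


YIELD_FEATURE_COLS = [
    "sh_mean", "sh_max", "sh_min",
    "hybrid_mean", "hybrid_max", "hybrid_min",
    "parent1_mean", "parent2_mean", "trend_pred",
]
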