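"""Yield-prediction error metrics, overall and per treatment.

RMSE is in Mg/ha; RRMSE normalizes it by the mean observed yield; MAPE here
is the mean absolute error divided by the mean observed yield (a
yield-scale-relative error, reported as a fraction); Pearson correlation is
the usual product-moment coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _check(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return y, yhat


def rmse(y, yhat) -> float:
    y, yhat = _check(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rrmse(y, yhat) -> float:
    """RMSE relative to the mean observed value (fraction)."""
    y, yhat = _check(y, yhat)
    m = y.mean()
    if m == 0:
        raise ZeroDivisionError("mean of observed values is zero")
    return rmse(y, yhat) / m


def mape(y, yhat, normalize: bool = True) -> float:
    """Mean absolute error relative to the mean observed value (fraction).

    With ``normalize=False`` the sum (rather than mean) of absolute errors is
    divided by the mean observed value.
    """
    y, yhat = _check(y, yhat)
    m = y.mean()
    if m == 0:
        raise ZeroDivisionError("mean of observed values is zero")
    abs_err = np.abs(y - yhat)
    return float((abs_err.mean() if normalize else abs_err.sum()) / m)


def pearson(y, yhat) -> float:
    y, yhat = _check(y, yhat)
    if y.size < 2:
        raise ValueError("Pearson correlation needs n >= 2")
    dy, dyh = y - y.mean(), yhat - yhat.mean()
    denom = np.sqrt((dy ** 2).sum() * (dyh ** 2).sum())
    if denom == 0:
        raise ValueError("correlation undefined: zero variance")
    return float((dy * dyh).sum() / denom)


@dataclass
class MetricsReport:
    """Overall metrics plus per-treatment sub-reports."""

    rmse: float
    rrmse: float
    mape: float
    pearson: float | None
    n: int
    per_treatment: dict[str, "MetricsReport"] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"group": "overall", "n": self.n, "rmse": self.rmse,
                 "rrmse": self.rrmse, "mape": self.mape, "pearson": self.pearson}]
        for name, sub in sorted(self.per_treatment.items()):
            rows.append({"group": name, "n": sub.n, "rmse": sub.rmse,
                         "rrmse": sub.rrmse, "mape": sub.mape, "pearson": sub.pearson})
        return pd.DataFrame(rows)


def _report(y, yhat) -> MetricsReport:
    try:
        r = pearson(y, yhat)
    except ValueError:
        r = None  # undefined for n=1 or constant vectors
    return MetricsReport(
        rmse=rmse(y, yhat), rrmse=rrmse(y, yhat), mape=mape(y, yhat),
        pearson=r, n=int(np.asarray(y).size),
    )


def evaluate_by_treatment(y, yhat, treatments) -> MetricsReport:
    """Overall metrics plus one sub-report per treatment label."""
    y, yhat = _check(y, yhat)
    treatments = np.asarray(treatments)
    if treatments.shape != y.shape:
        raise ValueError("treatment labels must align with observations")
    report = _report(y, yhat)
    for tr in np.unique(treatments):
        mask = treatments == tr
        report.per_treatment[str(tr)] = _report(y[mask], yhat[mask])
    return report
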