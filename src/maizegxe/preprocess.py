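"""Loading, imputation, date conversion, weather reshaping, and the big join.

The six trial-network tables are keyed by ``Env`` (a ``location_year``
string) except genotypes, keyed by ``Hybrid``. Preprocessing follows a fixed
hierarchy: mode imputation for categorical metadata, location-then-state mean
imputation for soil and simulator covariates, daily-to-weekly aggregation of
weather into a 48-week x 16-feature block, and finally an inner join on Env
with a flagged left join on Hybrid.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import SOIL_FEATURES, WEATHER_FEATURES

N_WEEKS = 48
DAYS_USED = N_WEEKS * 7  # 336; days beyond this are discarded

#: Default keyword -> issue-category map over the six labels.
ISSUE_KEYWORDS = {
    "drought": "drought",
    "dry": "drought",
    "storm": "storm",
    "hail": "storm",
    "wind damage": "storm",
    "deer": "animal attack",
    "bird": "animal attack",
    "animal": "animal attack",
    "raccoon": "animal attack",
    "scale": "data issues",
    "suspect": "data issues",
    "data": "data issues",
    "no issues": "no issues",
    "none": "no issues",
}


@dataclass
class EnvId:
    """Environment key: a location-year pair serialized as "location_year"."""

    location: str
    year: int

    @property
    def key(self) -> str:
        return f"{self.location}_{self.year}"

    @classmethod
    def parse(cls, key: str) -> "EnvId":
        loc, _, year = key.rpartition("_")
        if not loc or not year.isdigit():
            raise ValueError(f"not a location_year key: {key!r}")
        return cls(location=loc, year=int(year))


def classify_issue(comment: str | float, keywords: dict[str, str] | None = None) -> str:
    """Map a raw season comment onto one of the six issue categories."""
    keywords = keywords or ISSUE_KEYWORDS
    if pd.isna(comment) or not str(comment).strip():
        return "no issues"
    text = str(comment).lower()
    for kw, category in keywords.items():
        if kw in text:
            return category
    return "miscellaneous"


def impute_metadata(metadata: pd.DataFrame, column: str = "treatment") -> pd.DataFrame:
    """Fill missing categorical metadata with the column mode.

    The mode is computed over non-missing entries; ties break
    lexicographically so the result is deterministic.
    """
    out = metadata.copy()
    non_missing = out[column].dropna()
    if non_missing.empty:
        raise ValueError(f"cannot impute {column!r}: all values missing")
    counts = non_missing.value_counts()
    top = counts[counts == counts.max()].index
    mode = sorted(top)[0]
    out[column] = out[column].fillna(mode)
    return out


def planting_date_to_doy(date: str | _dt.date) -> int:
    """Convert a calendar date to a 1-based day of year (leap years honored)."""
    if isinstance(date, _dt.datetime):
        d = date.date()
    elif isinstance(date, _dt.date):
        d = date
    else:
        try:
            d = _dt.date.fromisoformat(str(date))
        except ValueError as exc:
            raise ValueError(f"unparseable date: {date!r}") from exc
    return d.timetuple().tm_yday


def weather_to_wide(daily: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Pivot long daily weather to one row per Env, columns "Feature_DayOfYear"."""
    features = features or [c for c in daily.columns if c not in ("Env", "date")]
    daily = daily.copy()
    daily["doy"] = pd.to_datetime(daily["date"]).dt.dayofyear
    wide = daily.pivot_table(index="Env", columns="doy", values=features)
    wide.columns = [f"{feat}_{doy}" for feat, doy in wide.columns]
    return wide


def weather_to_weekly(
    daily: pd.DataFrame,
    aggregator: str = "mean",
    features: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Aggregate daily weather into 48 weekly values per feature per Env.

    Week w covers days 7(w-1)+1 .. 7w; days beyond 336 are discarded. Returns
    a dict Env -> (48, n_features) array. Environments covering fewer than
    336 days are a coverage error; already-weekly input (= 48 distinct days)
    is rejected rather than silently re-aggregated.
    """
    if aggregator not in ("mean", "sum", "min", "max"):
        raise ValueError(f"unknown aggregator: {aggregator!r}")
    features = features or [c for c in daily.columns if c not in ("Env", "date")]
    daily = daily.copy()
    daily["doy"] = pd.to_datetime(daily["date"]).dt.dayofyear

    short, weekly = [], {}
    for env, grp in daily.groupby("Env", sort=True):
        n_days = grp["doy"].nunique()
        if n_days == N_WEEKS:
            raise ValueError(
                f"Env {env}: input has exactly {N_WEEKS} days — looks already "
                "weekly; refusing to re-aggregate"
            )
        if n_days < DAYS_USED:
            short.append(env)
            continue
        grp = grp[grp["doy"] <= DAYS_USED]
        week = (grp["doy"] - 1) // 7 + 1
        agg = grp[features].groupby(week.to_numpy()).agg(aggregator)
        weekly[env] = agg.loc[np.arange(1, N_WEEKS + 1), features].to_numpy(dtype=float)
    if short:
        raise ValueError(f"daily coverage below {DAYS_USED} days for Envs: {short}")
    return weekly


def impute_by_location_hierarchy(
    table: pd.DataFrame,
    feature_cols: list[str],
    location_col: str = "location",
    state_col: str = "state",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-pass mean imputation: by location across years, then by state.

    Pass 1 fills each missing cell with the mean of the same feature at the
    same location in other years; pass 2 fills what remains with the state
    mean. Cells still missing after both passes are reported in the returned
    log frame (and the corresponding rows flagged via an ``_imputation_gap``
    column). Non-missing cells are never altered.
    """
    out = table.copy()
    log_rows = []
    for col in feature_cols:
        missing0 = out[col].isna()
        if not missing0.any():
            continue
        loc_means = out.groupby(location_col)[col].transform("mean")
        out.loc[missing0, col] = loc_means[missing0]
        n_pass1 = int(missing0.sum() - out[col].isna().sum())
        missing1 = out[col].isna()
        n_pass2 = 0
        if missing1.any():
            state_means = out.groupby(state_col)[col].transform("mean")
            out.loc[missing1, col] = state_means[missing1]
            n_pass2 = int(missing1.sum() - out[col].isna().sum())
        n_left = int(out[col].isna().sum())
        log_rows.append({"feature": col, "filled_location": n_pass1, "filled_state": n_pass2, "unfilled": n_left})
    log = pd.DataFrame(log_rows, columns=["feature", "filled_location", "filled_state", "unfilled"])
    gap = out[feature_cols].isna().any(axis=1)
    out["_imputation_gap"] = gap
    return out, log


@dataclass
class MergedFrame:
    """One modeling row per (Env, Hybrid) with all feature blocks attached.

    ``frame`` holds trait, metadata, soil, and simulator columns; ``weather``
    maps Env to its (48, 16) weekly block; ``genotypes`` is the encoded
    dosage matrix; ``flagged`` are trait rows whose hybrid lacks genotype
    data (excluded from model training).
    """

    frame: pd.DataFrame
    weather: dict[str, np.ndarray]
    genotypes: pd.DataFrame
    flagged: pd.DataFrame


def join_all(
    trait: pd.DataFrame,
    metadata: pd.DataFrame,
    weather_weekly: dict[str, np.ndarray],
    soil: pd.DataFrame,
    envsim: pd.DataFrame,
    genotypes: pd.DataFrame,
) -> MergedFrame:
    """Join the preprocessed tables into one modeling frame.

    Metadata, soil, and simulator covariates inner-join on Env; genotype
    left-joins on Hybrid with unmatched rows flagged. Duplicate Env keys in a
    per-Env source table are an integrity error.
    """
    for name, tbl in (("metadata", metadata), ("soil", soil), ("envsim", envsim)):
        if tbl["Env"].duplicated().any():
            dupes = tbl.loc[tbl["Env"].duplicated(), "Env"].unique()[:5]
            raise ValueError(f"duplicate Env keys in {name} table: {list(dupes)}")

    frame = trait.merge(metadata, on="Env", how="inner")
    frame = frame.merge(soil, on="Env", how="inner")
    frame = frame.merge(envsim, on="Env", how="inner")
    frame = frame[frame["Env"].isin(weather_weekly)].reset_index(drop=True)

    has_geno = frame["Hybrid"].isin(genotypes.index)
    flagged = frame[~has_geno].reset_index(drop=True)
    frame = frame[has_geno].reset_index(drop=True)
    return MergedFrame(frame=frame, weather=weather_weekly, genotypes=genotypes, flagged=flagged)


def preprocess(raw, genotypes: pd.DataFrame, weekly_agg: str = "mean") -> MergedFrame:
    """Run the full preprocessing chain on a RawDataset.

    Imputes treatment by mode, classifies issue comments, converts planting
    dates to day of year, imputes soil and simulator gaps by the
    location-then-state hierarchy, aggregates weather to 48 weeks, and joins.
    """
    meta = impute_metadata(raw.metadata_table, "treatment")
    meta["issue_class"] = meta["issue_comment"].map(classify_issue) if "issue_comment" in meta else "no issues"
    meta["planting_doy"] = meta["planting_date"].map(planting_date_to_doy)
    meta = meta.drop(columns=[c for c in ("issue_comment", "planting_date") if c in meta])

    def _with_keys(tbl: pd.DataFrame) -> pd.DataFrame:
        tbl = tbl.copy()
        parsed = tbl["Env"].map(EnvId.parse)
        tbl["location"] = [p.location for p in parsed]
        tbl["year"] = [p.year for p in parsed]
        loc_state = meta.set_index("location")["state"].to_dict()
        tbl["state"] = tbl["location"].map(loc_state)
        return tbl

    def _impute_block(table: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
        out, _ = impute_by_location_hierarchy(_with_keys(table), cols)
        out = out.drop(columns=["location", "year", "state", "_imputation_gap"])
        # features absent at every year of a single-location state fall back
        # to the global column mean so the modeling frame stays complete
        still = [c for c in cols if out[c].isna().any()]
        for c in still:
            out[c] = out[c].fillna(out[c].mean())
        return out

    soil_cols = [c for c in raw.soil_table.columns if c in SOIL_FEATURES]
    soil = _impute_block(raw.soil_table, soil_cols)

    envsim_cols = [c for c in raw.envsim_table.columns if c != "Env"]
    envsim = _impute_block(raw.envsim_table, envsim_cols)

    weekly = weather_to_weekly(raw.weather_table, aggregator=weekly_agg, features=WEATHER_FEATURES)
    return join_all(raw.trait_table, meta, weekly, soil, envsim, genotypes)
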