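"""Imputation hierarchy, date conversion, weekly reshaping, and the join."""

import numpy as np
import pandas as pd
import pytest

from maizegxe.preprocess import (
    EnvId,
    classify_issue,
    impute_by_location_hierarchy,
    impute_metadata,
    join_all,
    planting_date_to_doy,
    weather_to_weekly,
    weather_to_wide,
)


class TestEnvId:
    def test_round_trip(self):
        env = EnvId.parse("LOC01_2018")
        assert (env.location, env.year) == ("LOC01", 2018)
        assert env.key == "LOC01_2018"

    def test_underscore_in_location_kept(self):
        assert EnvId.parse("TXH1_A_2020").location == "TXH1_A"

    def test_malformed_key_rejected(self):
        with pytest.raises(ValueError):
            EnvId.parse("no-year-here")


class TestImputeMetadata:
    def test_missing_filled_with_mode(self):
        meta = pd.DataFrame({"treatment": ["standard", "standard", "drought", None]})
        out = impute_metadata(meta)
        assert out["treatment"].tolist() == ["standard", "standard", "drought", "standard"]

    def test_no_missing_values_unchanged(self):
        meta = pd.DataFrame({"treatment": ["drought", "standard"]})
        pd.testing.assert_frame_equal(impute_metadata(meta), meta)

    def test_tie_broken_lexicographically(self):
        meta = pd.DataFrame({"treatment": ["drought", "drought", "standard", "standard", None]})
        assert impute_metadata(meta)["treatment"].iloc[-1] == "drought"

    def test_all_missing_column_errors(self):
        with pytest.raises(ValueError):
            impute_metadata(pd.DataFrame({"treatment": [None, None]}))


@pytest.mark.parametrize(
    "date,doy",
    [("2021-01-01", 1), ("2021-04-15", 105), ("2020-03-01", 61), ("2021-03-01", 60),
     ("2020-12-31", 366)],
)
def test_planting_date_to_doy(date, doy):
    assert planting_date_to_doy(date) == doy


def test_unparseable_date_raises():
    with pytest.raises(ValueError):
        planting_date_to_doy("not-a-date")


def _daily(env="LOC01_2020", n_days=365, value=None):
    doy = np.arange(1, n_days + 1)
    dates = pd.to_datetime("2020-01-01") + pd.to_timedelta(doy - 1, unit="D")
    vals = np.asarray(value if value is not None else doy, dtype=float)
    return pd.DataFrame({"Env": env, "date": dates.strftime("%Y-%m-%d"), "temp": vals})


class TestWeatherToWeekly:
    def test_constant_series_stays_constant(self):
        weekly = weather_to_weekly(_daily(value=np.full(365, 3.5)))
        assert weekly["LOC01_2020"].shape == (48, 1)
        assert np.allclose(weekly["LOC01_2020"], 3.5)

    def test_week_one_is_mean_of_first_seven_days(self):
        weekly = weather_to_weekly(_daily())
        assert weekly["LOC01_2020"][0, 0] == pytest.approx(4.0)

    def test_days_beyond_336_are_discarded(self):
        daily = _daily()
        daily.loc[daily.index >= 336, "temp"] = 1e6
        weekly = weather_to_weekly(daily)
        assert weekly["LOC01_2020"].shape == (48, 1)
        assert weekly["LOC01_2020"].max() < 1e5

    def test_short_coverage_errors_and_names_env(self):
        with pytest.raises(ValueError, match="LOC01_2020"):
            weather_to_weekly(_daily(n_days=300))

    def test_already_weekly_cadence_rejected(self):
        with pytest.raises(ValueError, match="already"):
            weather_to_weekly(_daily(n_days=48))

    def test_sum_aggregator(self):
        weekly = weather_to_weekly(_daily(value=np.ones(365)), aggregator="sum")
        assert np.allclose(weekly["LOC01_2020"], 7.0)

    def test_unknown_aggregator_rejected(self):
        with pytest.raises(ValueError):
            weather_to_weekly(_daily(), aggregator="median^2")


def test_weather_wide_pivot_names_columns_feature_doy():
    wide = weather_to_wide(_daily(n_days=40))
    assert "temp_1" in wide.columns and "temp_40" in wide.columns
    assert wide.loc["LOC01_2020", "temp_17"] == 17


class TestLocationHierarchyImputation:
    def _table(self, values):
        return pd.DataFrame({
            "Env": [f"L1_{y}" for y in (2014, 2015, 2016)] + ["L2_2014"],
            "location": ["L1", "L1", "L1", "L2"],
            "state": ["IA", "IA", "IA", "IA"],
            "year": [2014, 2015, 2016, 2014],
            "ph": values,
        })

    def test_missing_filled_with_location_mean_of_other_years(self):
        out, log = impute_by_location_hierarchy(self._table([np.nan, 5.0, 7.0, 9.0]), ["ph"])
        assert out["ph"].iloc[0] == pytest.approx(6.0)
        assert log.loc[0, "filled_location"] == 1

    def test_state_mean_fallback_when_location_all_missing(self):
        out, log = impute_by_location_hierarchy(
            self._table([np.nan, np.nan, np.nan, 4.2]), ["ph"])
        assert np.allclose(out["ph"].iloc[:3], 4.2)
        assert log.loc[0, "filled_state"] == 3

    def test_complete_table_unchanged(self):
        table = self._table([1.0, 2.0, 3.0, 4.0])
        out, log = impute_by_location_hierarchy(table, ["ph"])
        pd.testing.assert_frame_equal(out.drop(columns="_imputation_gap"), table)
        assert log.empty

    def test_unfillable_cells_flagged(self):
        table = self._table([1.0, 2.0, 3.0, 4.0])
        table["ph"] = np.nan
        out, log = impute_by_location_hierarchy(table, ["ph"])
        assert out["_imputation_gap"].all()
        assert log.loc[0, "unfilled"] == 4

    def test_imputation_never_alters_observed_cells(self, rng):
        table = self._table([np.nan, 5.0, 7.0, 9.0])
        out, _ = impute_by_location_hierarchy(table, ["ph"])
        observed = table["ph"].notna()
        assert (out.loc[observed, "ph"] == table.loc[observed, "ph"]).all()


@pytest.mark.parametrize(
    "comment,expected",
    [("severe drought stress in July", "drought"),
     ("hail storm flattened the field", "storm"),
     ("deer damage on border rows", "animal attack"),
     ("harvest scale drift", "data issues"),
     ("no issues observed", "no issues"),
     (np.nan, "no issues"),
     ("strange unclassifiable remark", "miscellaneous")],
)
def test_issue_keyword_classification(comment, expected):
    assert classify_issue(comment) == expected


class TestJoinAll:
    def _inputs(self, n_trait=6, unknown_hybrids=0):
        envs = ["L1_2020", "L2_2020"]
        hybrids = [f"A{i}/B{i}" for i in range(n_trait)]
        trait = pd.DataFrame({
            "Env": [envs[i % 2] for i in range(n_trait)],
            "Hybrid": hybrids,
            "yield": np.linspace(5, 12, n_trait),
        })
        meta = pd.DataFrame({"Env": envs, "treatment": "standard"})
        soil = pd.DataFrame({"Env": envs, "ph": [6.1, 6.5]})
        envsim = pd.DataFrame({"Env": envs, "sim": [1.0, 2.0]})
        weather = {e: np.zeros((48, 16)) for e in envs}
        known = hybrids[: n_trait - unknown_hybrids]
        geno = pd.DataFrame(np.zeros((len(known), 3)), index=known,
                            columns=["l1", "l2", "l3"])
        return trait, meta, weather, soil, envsim, geno

    def test_all_keys_resolve_row_count_preserved(self):
        merged = join_all(*self._inputs())
        assert len(merged.frame) == 6 and len(merged.flagged) == 0

    def test_unknown_hybrids_flagged_and_excluded(self):
        merged = join_all(*self._inputs(unknown_hybrids=2))
        assert len(merged.frame) == 4 and len(merged.flagged) == 2

    def test_empty_trait_table_gives_empty_frame(self):
        trait, *rest = self._inputs()
        merged = join_all(trait.iloc[:0], *rest)
        assert merged.frame.empty and merged.flagged.empty

    def test_duplicate_env_keys_are_integrity_error(self):
        trait, meta, weather, soil, envsim, geno = self._inputs()
        bad_soil = pd.concat([soil, soil.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate Env"):
            join_all(trait, meta, weather, bad_soil, envsim, geno)

    def test_join_is_order_independent(self):
        trait, meta, weather, soil, envsim, geno = self._inputs()
        shuffled = trait.sample(frac=1, random_state=0).reset_index(drop=True)
        a = join_all(trait, meta, weather, soil, envsim, geno).frame
        b = join_all(shuffled, meta, weather, soil, envsim, geno).frame
        a_sorted = a.sort_values(["Env", "Hybrid"]).reset_index(drop=True)
        b_sorted = b.sort_values(["Env", "Hybrid"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a_sorted, b_sorted)


def test_preprocessed_tiny_frame_contract(tiny_merged):
    merged, dosages = tiny_merged
    frame = merged.frame
    assert frame["treatment"].notna().all()
    assert frame["planting_doy"].between(1, 366).all()
    for env, block in merged.weather.items():
        assert block.shape == (48, 16) and not np.isnan(block).any()
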