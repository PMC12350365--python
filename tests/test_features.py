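"""Engineered yield features: group statistics, imputation rule, trend OLS."""

import numpy as np
import pandas as pd
import pytest

from maizegxe.features import (
    attach_yield_features,
    fit_state_trend,
    fit_yield_features,
    hybrid_stats,
    impute_unseen_combo,
    parent_stats,
    predict_trend,
    split_parents,
    state_hybrid_stats,
)


def frame(rows):
    return pd.DataFrame(rows, columns=["state", "Hybrid", "year", "yield"])


class TestStateHybridStats:
    def test_statistics_over_group_yields(self):
        train = frame([("IA", "H1", 2019, 8.0), ("IA", "H1", 2019, 10.0),
                       ("IA", "H1", 2020, 12.0)])
        out = state_hybrid_stats(train)
        row = out.iloc[0]
        assert (row["mean_yield"], row["max_yield"], row["min_yield"]) == (10.0, 12.0, 8.0)
        assert row["support"] == 3

    def test_single_observation_collapses(self):
        out = state_hybrid_stats(frame([("IA", "H1", 2019, 7.0)]))
        assert out.iloc[0][["mean_yield", "max_yield", "min_yield"]].tolist() == [7.0] * 3

    def test_unobserved_combination_has_no_row(self):
        out = state_hybrid_stats(frame([("IA", "H1", 2019, 7.0)]))
        assert len(out) == 1

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            state_hybrid_stats(frame([]))


class TestImputeUnseenCombo:
    def _stats(self, values, state="IA"):
        return pd.DataFrame({
            "state": state, "Hybrid": [f"H{i}" for i in range(len(values))],
            "mean_yield": values, "max_yield": values, "min_yield": values,
            "support": 1,
        })

    def test_average_of_mean_and_mode(self):
        out = impute_unseen_combo(self._stats([10.0, 10.0, 14.0]), "IA")
        assert out["mean_yield"] == pytest.approx((11.333333 + 10.0) / 2, abs=1e-5)
        assert out["provenance"] == "imputed"

    def test_identical_values_impute_to_that_value(self):
        out = impute_unseen_combo(self._stats([9.0, 9.0, 9.0]), "IA")
        assert out["mean_yield"] == pytest.approx(9.0)

    def test_mode_tie_breaks_to_smaller_value(self):
        # mean 10.0; rounded values {9.0 x2, 11.0 x2} -> mode 9.0
        out = impute_unseen_combo(self._stats([9.0, 9.0, 11.0, 11.0]), "IA")
        assert out["mean_yield"] == pytest.approx((10.0 + 9.0) / 2)

    def test_unseen_state_falls_back_to_global_mean(self):
        out = impute_unseen_combo(self._stats([9.0, 11.0]), "ZZ")
        assert out["mean_yield"] == pytest.approx(10.0)
        assert out["provenance"] == "fallback"

    def test_imputed_value_within_column_range(self):
        stats = self._stats([8.0, 9.5, 12.0, 12.0])
        out = impute_unseen_combo(stats, "IA")
        assert stats["mean_yield"].min() <= out["mean_yield"] <= stats["mean_yield"].max()


class TestParents:
    def test_hybrid_name_splits_into_parents(self):
        assert split_parents("B73/MO17") == ("B73", "MO17")
        assert split_parents("inbredline") is None

    def test_parent_mean_pools_both_sides(self):
        train = frame([("IA", "B73/MO17", 2019, 9.0), ("IA", "PHZ51/B73", 2019, 11.0)])
        out = parent_stats(train).set_index("parent")
        assert out.loc["B73", "parent_mean"] == pytest.approx(10.0)
        assert out.loc["MO17", "parent_mean"] == pytest.approx(9.0)

    def test_hybrid_level_stats(self):
        train = frame([("IA", "A/B", 2019, 7.0)])
        out = hybrid_stats(train)
        assert out.iloc[0][["hybrid_mean", "hybrid_max", "hybrid_min"]].tolist() == [7.0] * 3


class TestStateTrend:
    def test_exact_linear_data_recovered(self):
        train = frame([("IA", "H", y, v) for y, v in [(2014, 8.0), (2015, 9.0), (2016, 10.0)]])
        models = fit_state_trend(train)
        assert models["IA"].slope == pytest.approx(1.0)
        assert predict_trend(models, "IA", 2017) == pytest.approx(11.0)

    def test_constant_yields_give_zero_slope(self):
        train = frame([("IA", "H", y, 6.5) for y in (2014, 2015, 2016)])
        m = fit_state_trend(train)["IA"]
        assert m.slope == pytest.approx(0.0, abs=1e-10)
        assert m.predict(2030) == pytest.approx(6.5)

    def test_ols_on_five_years(self):
        ys = [(2014, 8.0), (2015, 9.0), (2016, 9.0), (2017, 10.0), (2018, 12.0)]
        models = fit_state_trend(frame([("IA", "H", y, v) for y, v in ys]))
        assert models["IA"].slope == pytest.approx(0.9)
        assert predict_trend(models, "IA", 2016) == pytest.approx(9.6)

    def test_single_year_state_gets_mean_and_zero_slope(self):
        models = fit_state_trend(frame([("TX", "H", 2019, 5.0), ("TX", "G", 2019, 7.0)]))
        assert models["TX"].slope == 0.0
        assert models["TX"].predict(2025) == pytest.approx(6.0)

    def test_unknown_state_lookup_errors(self):
        models = fit_state_trend(frame([("TX", "H", 2019, 5.0)]))
        with pytest.raises(KeyError):
            predict_trend(models, "IA", 2020)

    def test_prediction_is_affine_in_year(self):
        ys = [(2014, 8.2), (2015, 9.9), (2016, 9.1), (2017, 11.0)]
        m = fit_state_trend(frame([("IA", "H", y, v) for y, v in ys]))["IA"]
        assert m.predict(2020) - m.predict(2019) == pytest.approx(m.slope)


class TestLeakage:
    def test_features_identical_when_test_rows_removed_or_shuffled(self, tiny_merged):
        merged, _ = tiny_merged
        all_rows = merged.frame
        train = all_rows[all_rows["year"] <= 2020].reset_index(drop=True)
        feats_clean = fit_yield_features(train)
        # shuffling training rows must not change any feature either
        shuffled = train.sample(frac=1, random_state=7).reset_index(drop=True)
        feats_shuffled = fit_yield_features(shuffled)
        a = feats_clean.state_hybrid.sort_values(["state", "Hybrid"]).reset_index(drop=True)
        b = feats_shuffled.state_hybrid.sort_values(["state", "Hybrid"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
        # tampering with test-year yields leaves training features untouched
        tampered = all_rows.copy()
        tampered.loc[tampered["year"] == 2021, "yield"] *= 100
        feats_tampered = fit_yield_features(
            tampered[tampered["year"] <= 2020].reset_index(drop=True))
        pd.testing.assert_frame_equal(
            feats_clean.state_hybrid, feats_tampered.state_hybrid)
        assert feats_clean.trend.keys() == feats_tampered.trend.keys()
        for s in feats_clean.trend:
            assert feats_clean.trend[s].slope == feats_tampered.trend[s].slope


def test_attach_features_marks_provenance(tiny_split):
    train_f, test_f = tiny_split["train_f"], tiny_split["test_f"]
    assert set(train_f["feature_provenance"]) == {"observed"}
    assert {"observed", "imputed"} >= set(test_f["feature_provenance"])
    for col in ("sh_mean", "hybrid_mean", "parent1_mean", "trend_pred"):
        assert train_f[col].notna().all() and test_f[col].notna().all()
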