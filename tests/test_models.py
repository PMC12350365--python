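"""Model families: architectures, oversampling, baselines, ensembling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from maizegxe.config import EnsembleWeights
from maizegxe.models import (
    CNNConfig,
    CNNRegressor,
    build_multimodal,
    build_single_modal,
    ensemble_predict,
    fit_baseline,
    grid_search_ensemble_weights,
    oversample_treatments,
    small_cnn_config,
    train_xgb_yield_features,
    xgb_feature_frame,
)
from maizegxe.nn import MultiBranch


class TestSingleModal:
    def test_accepts_flat_input_returns_scalar_column(self):
        net = build_single_modal(120, small_cnn_config())
        out = net.forward(np.zeros((7, 120)))
        assert out.shape == (7, 1)

    def test_zero_input_zero_weights_give_zero_output(self):
        net = build_single_modal(60, small_cnn_config())
        # final layer bias starts at zero; zero the final weights too
        final = net.layers[-1]
        final.w[...] = 0.0
        out = net.forward(np.zeros((3, 60)))
        assert np.allclose(out, 0.0)

    def test_too_narrow_input_is_construction_error(self):
        with pytest.raises(ValueError):
            build_single_modal(10, CNNConfig(kernel1d=5))

    def test_fits_better_than_constant_mean_on_small_set(self, tiny_split):
        X, y = tiny_split["X_train"], tiny_split["y_train"]
        cfg = small_cnn_config(epochs=200, seed=0)
        reg = CNNRegressor(build_single_modal(X.shape[1], cfg), cfg).fit(X, y)
        pred = reg.predict(X)
        rmse_model = float(np.sqrt(np.mean((pred - y) ** 2)))
        rmse_const = float(np.sqrt(np.mean((y.mean() - y) ** 2)))
        assert rmse_model < rmse_const


class TestMultimodal:
    def test_envsim_branch_has_seven_parallel_subblocks(self, tiny_split):
        net = build_multimodal(tiny_split["mm_train"], small_cnn_config())
        envsim = dict(net.branches)["envsim_soil"]
        assert isinstance(envsim, MultiBranch)
        assert len(envsim.branches) == 7

    def test_accepts_declared_shapes_returns_scalar_column(self, tiny_split):
        mm = tiny_split["mm_train"]
        net = build_multimodal(mm, small_cnn_config())
        out = net.forward(mm.as_list())
        assert out.shape == (mm.n, 1)

    def test_mismatched_block_rows_rejected(self, tiny_split):
        from dataclasses import replace

        mm = tiny_split["mm_train"]
        with pytest.raises(ValueError, match="inconsistent"):
            replace(mm, soil=mm.soil[:-1])

    def test_training_is_reproducible_for_fixed_seed(self, tiny_split):
        mm, y = tiny_split["mm_train"], tiny_split["y_train"]
        cfg = small_cnn_config(epochs=3, seed=9)
        p1 = CNNRegressor(build_multimodal(mm, cfg), cfg, multimodal=True).fit(mm, y).predict(mm)
        p2 = CNNRegressor(build_multimodal(mm, cfg), cfg, multimodal=True).fit(mm, y).predict(mm)
        assert np.allclose(p1, p2)


class TestOversampling:
    def _training(self, treatments, n_per=30):
        rows = []
        for tr in treatments:
            for i in range(n_per):
                rows.append({"Hybrid": f"H{i}", "treatment": tr, "yield": 8.0 + i % 5})
        return pd.DataFrame(rows)

    def test_five_eligible_treatments_append_25000(self):
        train = self._training(["standard", "drought", "irrigated", "disease trial",
                                "late stressed", "dryland"])
        out = oversample_treatments(train, seed=0)
        assert len(out) - len(train) == 25_000
        assert (out["treatment"] == "late planting").sum() == 5_000

    def test_no_eligible_treatments_appends_nothing(self):
        train = self._training(["standard", "late planting"])
        out = oversample_treatments(train, seed=0)
        assert len(out) == len(train)

    def test_single_treatment_counts(self):
        train = self._training(["drought"])
        out = oversample_treatments(train, per_treatment=10, late_relabel=2, seed=0)
        assert len(out) - len(train) == 12
        assert (out["treatment"] == "late planting").sum() == 2

    def test_original_rows_untouched_at_front(self):
        train = self._training(["standard", "drought"])
        out = oversample_treatments(train, per_treatment=5, late_relabel=1, seed=0)
        pd.testing.assert_frame_equal(out.iloc[: len(train)].reset_index(drop=True), train)

    @given(st.sets(st.sampled_from(
        ["standard", "drought", "irrigated", "disease trial", "early planting",
         "late planting", "late stressed", "dryland"]), min_size=1, max_size=8))
    def test_appended_count_formula_for_any_label_set(self, labels):
        train = self._training(sorted(labels), n_per=4)
        out = oversample_treatments(train, per_treatment=7, late_relabel=3, seed=1)
        eligible = labels - {"standard", "late planting"}
        assert len(out) - len(train) == len(eligible) * 10


class TestYieldFeatureXGB:
    def test_feature_frame_excludes_raw_blocks(self, tiny_split):
        X = xgb_feature_frame(tiny_split["train_f"], tiny_split["encoders"])
        assert not any(c.startswith("locus_") for c in X.columns)
        assert not any(c in ("temp_max", "ph", "precip") for c in X.columns)
        assert {"sh_mean", "hybrid_mean", "trend_pred"} <= set(X.columns)

    def test_missing_feature_columns_is_schema_error(self, tiny_split):
        broken = tiny_split["train_f"].drop(columns=["sh_mean"])
        with pytest.raises(KeyError, match="sh_mean"):
            xgb_feature_frame(broken, tiny_split["encoders"])

    def test_same_seed_identical_predictions(self, tiny_split):
        train_f, enc = tiny_split["train_f"], tiny_split["encoders"]
        m1 = train_xgb_yield_features(train_f, enc, n_trees=50, seed=3)
        m2 = train_xgb_yield_features(train_f, enc, n_trees=50, seed=3)
        X = xgb_feature_frame(tiny_split["test_f"], enc)
        assert np.allclose(m1.predict(X), m2.predict(X))


class TestBaselines:
    def test_default_hyperparameters_match_reference(self):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(40, 6)), rng.normal(size=40)
        lasso = fit_baseline("lasso", X, y)
        assert lasso.alpha == 0.05
        rf = fit_baseline("rf", X, y, n_estimators=10)
        assert (rf.max_depth, rf.max_features, rf.min_samples_split) == (15, "sqrt", 15)
        xgb = fit_baseline("xgb", X, y, n_estimators=10)
        p = xgb.get_params()
        assert (p["max_depth"], p["learning_rate"], p["subsample"]) == (5, 0.05, 0.75)

    def test_default_tree_counts_match_reference(self):
        from maizegxe.models import BaselineConfig

        c = BaselineConfig()
        assert (c.rf_n_trees, c.xgb_n_trees) == (400, 4000)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            fit_baseline("svm", np.zeros((4, 2)), np.zeros(4))


class TestEnsemble:
    def test_identical_members_pass_through_any_weights(self):
        p = np.array([1.0, 2.0, 3.0])
        for w in (0.0, 0.3, 1.0):
            out = ensemble_predict(EnsembleWeights(w, 1 - w), p, p)
            assert np.allclose(out, p)

    def test_reference_weight_arithmetic(self):
        out = ensemble_predict(EnsembleWeights(0.1, 0.9), np.array([20.0]), np.array([10.0]))
        assert out[0] == pytest.approx(11.0)

    def test_perfect_cnn_gets_full_weight(self, rng):
        y = rng.normal(10, 2, size=50)
        noise = y + rng.normal(0, 5, size=50)
        w = grid_search_ensemble_weights(noise, y, y)
        assert (w.w_xgb, w.w_cnn) == (0.0, 1.0)

    def test_grid_search_matches_exhaustive_scan(self, rng):
        y = rng.normal(10, 2, size=80)
        pa = y + rng.normal(0, 1.0, size=80)
        pb = y + rng.normal(0, 1.5, size=80)
        found = grid_search_ensemble_weights(pa, pb, y)
        grid = [round(0.1 * i, 10) for i in range(11)]
        rmses = {w: float(np.sqrt(np.mean((w * pa + (1 - w) * pb - y) ** 2))) for w in grid}
        best = min(rmses.values())
        # ties break toward larger CNN weight (smaller w_xgb)
        expected = min(w for w, r in rmses.items() if abs(r - best) < 1e-12)
        assert found.w_xgb == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            grid_search_ensemble_weights(np.zeros(3), np.zeros(4), np.zeros(3))
        with pytest.raises(ValueError):
            ensemble_predict(EnsembleWeights(0.5, 0.5), np.zeros(3), np.zeros(4))

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            EnsembleWeights(0.7, 0.7)
        with pytest.raises(ValueError):
            EnsembleWeights(-0.1, 1.1)


def test_locus_sample_choice_barely_moves_metrics(tiny_split):
    """Prediction quality is insensitive to which random locus subset is used."""
    from maizegxe.evaluation import rmse as _rmse
    from maizegxe.genotype import sample_loci

    train_f, test_f = tiny_split["train_f"], tiny_split["test_f"]
    dosages = tiny_split["dosages"]
    y_tr, y_te = tiny_split["y_train"], tiny_split["y_test"]
    base_cols = ["planting_doy", "year", "sh_mean", "hybrid_mean", "trend_pred"]
    scores = []
    for seed in (0, 1, 2):
        loci = sample_loci(list(dosages.columns), max(4, dosages.shape[1] // 2), seed=seed)
        Xtr = np.hstack([train_f[base_cols], dosages.loc[train_f["Hybrid"], loci]])
        Xte = np.hstack([test_f[base_cols], dosages.loc[test_f["Hybrid"], loci]])
        model = fit_baseline("lasso", Xtr, y_tr)
        scores.append(_rmse(y_te, model.predict(Xte)))
    assert max(scores) - min(scores) < 0.5
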