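"""End-to-end orchestration: simulate → preprocess → features → train →
evaluate → classify.

The temporal split is strict: the test year never contributes to imputation
statistics, engineered features, model fits, or ensemble weight selection.
Ensemble weights are chosen on a held-out validation year (the last training
year), after which both ensemble members are refitted on the full training
period.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import build_class_matrix, render_heatmap, summarize_hybrid_yields
from .config import ClassRule, EnsembleWeights, LocusFilterParams, SyntheticConfig
from .evaluation import evaluate_by_treatment
from .features import attach_yield_features, fit_yield_features
from .genotype import prepare_genotypes
from .models import (
    BaselineConfig,
    CNNConfig,
    CNNRegressor,
    assemble_multimodal_inputs,
    build_multimodal,
    build_single_modal,
    ensemble_predict,
    fit_baseline,
    fit_meta_encoders,
    flatten_inputs,
    grid_search_ensemble_weights,
    oversample_treatments,
    small_cnn_config,
    train_xgb_yield_features,
    xgb_feature_frame,
)
from .preprocess import preprocess
from .synthetic import generate_dataset

ALL_MODELS = ("lasso", "rf", "xgb", "cnn", "multimodal", "ensemble")


@dataclass
class PipelineConfig:
    """Run settings: data source, temporal split, models, seeds, output."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    test_year: int | None = None          # default: last year of the data
    train_cutoff: int | None = None       # default: test_year - 1
    models: tuple[str, ...] = ALL_MODELS
    cnn: CNNConfig | None = None          # default: reduced-size preset
    baselines: BaselineConfig = field(default_factory=BaselineConfig)
    locus_filter: LocusFilterParams = field(default_factory=LocusFilterParams)
    class_rule: ClassRule = field(default_factory=ClassRule)
    oversample_per_treatment: int = 4000
    oversample_late_relabel: int = 1000
    xgb_n_trees_yield: int = 300          # trees for the yield-feature member
    baseline_n_trees: int | None = None   # override for quick runs
    seed: int = 0
    out_dir: str | Path = "runs"

    def resolve_years(self) -> tuple[int, int]:
        test_year = self.test_year if self.test_year is not None else self.synthetic.years[1]
        cutoff = self.train_cutoff if self.train_cutoff is not None else test_year - 1
        if cutoff >= test_year:
            raise ValueError(f"train cutoff {cutoff} must precede test year {test_year}")
        if not (self.synthetic.years[0] <= test_year <= self.synthetic.years[1]):
            raise ValueError(f"test year {test_year} outside data span {self.synthetic.years}")
        return cutoff, test_year


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory.

    Writes feature tables, per-model predictions, the metrics report, the
    hybrid class matrix (CSV + PNG), and a manifest of seeds and versions.
    """
    t0 = time.time()
    cutoff, test_year = config.resolve_years()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}

    def tic(stage):
        stage_times[stage] = time.time()

    def toc(stage):
        stage_times[stage] = round(time.time() - stage_times[stage], 2)

    # --- simulate --------------------------------------------------------
    tic("simulate")
    raw = generate_dataset(config.synthetic)
    toc("simulate")

    # --- genotype + preprocess ------------------------------------------
    tic("preprocess")
    calls = raw.genotype_table
    dosages, geno_report = prepare_genotypes(calls, config.locus_filter)
    merged = preprocess(raw, dosages)
    frame = merged.frame
    toc("preprocess")

    train = frame[frame["year"] <= cutoff].reset_index(drop=True)
    test = frame[frame["year"] == test_year].reset_index(drop=True)
    if train.empty or test.empty:
        raise ValueError("temporal split produced an empty train or test set")

    # --- features (training period only) --------------------------------
    tic("features")
    feats = fit_yield_features(train)
    train_f = attach_yield_features(train, feats)
    test_f = attach_yield_features(test, feats)
    train_f.to_csv(out / "train_features.csv", index=False)
    test_f.to_csv(out / "test_features.csv", index=False)
    toc("features")

    encoders = fit_meta_encoders(train_f)
    mm_train, y_train = assemble_multimodal_inputs(train_f, merged.weather, dosages, encoders)
    mm_test, y_test = assemble_multimodal_inputs(test_f, merged.weather, dosages, encoders)
    X_train, X_test = flatten_inputs(mm_train), flatten_inputs(mm_test)

    cnn_cfg = config.cnn or small_cnn_config(seed=config.seed)
    nt = {"n_estimators": config.baseline_n_trees} if config.baseline_n_trees else {}

    # --- train + evaluate ------------------------------------------------
    tic("train")
    predictions: dict[str, np.ndarray] = {}
    for name in config.models:
        if name in ("lasso", "rf", "xgb"):
            model = fit_baseline(name, X_train, y_train, config.baselines,
                                 seed=config.seed, **({} if name == "lasso" else nt))
            predictions[name] = model.predict(X_test)
        elif name == "cnn":
            net = build_single_modal(X_train.shape[1], cnn_cfg)
            reg = CNNRegressor(net, cnn_cfg).fit(X_train, y_train)
            predictions[name] = reg.predict(X_test)
        elif name == "multimodal":
            net = build_multimodal(mm_train, cnn_cfg)
            reg = CNNRegressor(net, cnn_cfg, multimodal=True).fit(mm_train, y_train)
            predictions[name] = reg.predict(mm_test)
        elif name == "ensemble":
            predictions[name] = _fit_ensemble(
                config, cnn_cfg, encoders, merged, dosages, train_f, test_f,
                mm_train, mm_test, y_train, cutoff, out,
            )
        else:
            raise ValueError(f"unknown model {name!r}")
    toc("train")

    # --- report ----------------------------------------------------------
    tic("evaluate")
    rows = []
    for name, pred in predictions.items():
        rep = evaluate_by_treatment(y_test, pred, test_f["treatment"])
        frame_rep = rep.to_frame()
        frame_rep.insert(0, "model", name)
        rows.append(frame_rep)
        pd.DataFrame({"Env": test_f["Env"], "Hybrid": test_f["Hybrid"],
                      "observed": y_test, "predicted": pred}).to_csv(
            out / f"predictions_{name}.csv", index=False)
    metrics = pd.concat(rows, ignore_index=True)
    metrics.to_csv(out / "metrics.csv", index=False)
    toc("evaluate")

    # --- classify --------------------------------------------------------
    tic("classify")
    stats = summarize_hybrid_yields(frame)
    matrix = build_class_matrix(stats, config.class_rule)
    matrix.to_csv(out / "class_matrix.csv")
    render_heatmap(matrix, out / "class_matrix.png")
    toc("classify")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "train_cutoff": cutoff,
        "test_year": test_year,
        "models": list(config.models),
        "n_train": int(len(train_f)),
        "n_test": int(len(test_f)),
        "genotype_report": {k: v for k, v in geno_report.items() if k != "dropped_missing"},
        "stage_seconds": stage_times,
        "total_seconds": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _fit_ensemble(config, cnn_cfg, encoders, merged, dosages, train_f, test_f,
                  mm_train, mm_test, y_train, cutoff, out) -> np.ndarray:
    """Weighted CNN-DNN + yield-feature-XGBoost ensemble.

    Weights come from a 0.1-step grid search on the last training year, with
    both members fitted on the earlier years only; the members are then
    refitted on the whole training period for test prediction.
    """
    inner = train_f[train_f["year"] < cutoff].reset_index(drop=True)
    holdout = train_f[train_f["year"] == cutoff].reset_index(drop=True)
    if inner.empty or holdout.empty:
        weights = EnsembleWeights(w_xgb=0.1, w_cnn=0.9)
    else:
        mm_inner, y_inner = assemble_multimodal_inputs(inner, merged.weather, dosages, encoders)
        mm_hold, y_hold = assemble_multimodal_inputs(holdout, merged.weather, dosages, encoders)
        net = build_multimodal(mm_inner, cnn_cfg)
        cnn_val = CNNRegressor(net, cnn_cfg, multimodal=True).fit(mm_inner, y_inner).predict(mm_hold)
        aug = oversample_treatments(inner, config.oversample_per_treatment,
                                    config.oversample_late_relabel, seed=config.seed)
        xgb_val = train_xgb_yield_features(
            aug, encoders, config.baselines, n_trees=config.xgb_n_trees_yield,
            seed=config.seed).predict(xgb_feature_frame(holdout, encoders))
        weights = grid_search_ensemble_weights(xgb_val, cnn_val, y_hold)
    (out / "ensemble_weights.json").write_text(
        json.dumps({"w_xgb": weights.w_xgb, "w_cnn": weights.w_cnn}))

    net = build_multimodal(mm_train, cnn_cfg)
    cnn_pred = CNNRegressor(net, cnn_cfg, multimodal=True).fit(mm_train, y_train).predict(mm_test)
    aug = oversample_treatments(train_f, config.oversample_per_treatment,
                                config.oversample_late_relabel, seed=config.seed)
    xgb_model = train_xgb_yield_features(aug, encoders, config.baselines,
                                         n_trees=config.xgb_n_trees_yield, seed=config.seed)
    xgb_pred = xgb_model.predict(xgb_feature_frame(test_f, encoders))
    return ensemble_predict(weights, xgb_pred, cnn_pred)


def write_report(run_dir: str | Path) -> str:
    """Aligned-text model comparison from a completed run, sorted by RMSE."""
    run_dir = Path(run_dir)
    metrics_path = run_dir / "metrics.csv"
    if not metrics_path.exists():
        raise FileNotFoundError(f"no metrics file in {run_dir}")
    metrics = pd.read_csv(metrics_path)
    overall = metrics[metrics["group"] == "overall"].sort_values("rmse")
    lines = ["Model comparison (test year)", "=" * 64,
             f"{'model':<12}{'RMSE':>8}{'RRMSE %':>10}{'MAPE %':>9}{'r':>8}{'n':>7}"]
    for _, row in overall.iterrows():
        r = f"{row['pearson']:.2f}" if pd.notna(row["pearson"]) else "n/a"
        lines.append(f"{row['model']:<12}{row['rmse']:>8.3f}{100 * row['rrmse']:>10.1f}"
                     f"{100 * row['mape']:>9.1f}{r:>8}{int(row['n']):>7}")
    lines.append("")
    lines.append("Per-treatment breakdown")
    lines.append("-" * 64)
    per = metrics[metrics["group"] != "overall"]
    for model in overall["model"]:
        sub = per[per["model"] == model]
        for _, row in sub.iterrows():
            lines.append(f"{model:<12}{row['group']:<16}{row['rmse']:>8.3f}{int(row['n']):>7}")
    text = "\n".join(lines)
    (run_dir / "report.txt").write_text(text)
    return text
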