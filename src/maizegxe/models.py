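"""Model families for G×E×M yield prediction.

Five families are provided: LASSO, random forest and XGBoost baselines on
the flat feature matrix (scikit-learn / xgboost, with the grid-searched
hyperparameters as defaults); a single-modal CNN-DNN over the concatenated
flat vector; and the multimodal CNN-DNN with six input branches (weather,
soil, genotype, metadata with embeddings, crop-simulator soil fields,
crop-simulator phenology). The multimodal network is ensembled with an
XGBoost model trained on oversampled metadata + engineered yield features,
combining predictions by a convex weight pair found by a 0.1-step grid
search (0.1 XGBoost / 0.9 CNN-DNN in the reference configuration).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso
from xgboost import XGBRegressor

from .config import EnsembleWeights
from .features import YIELD_FEATURE_COLS
from .nn import (
    Adam,
    AvgPool1D,
    AvgPool2D,
    Conv1D,
    Conv2D,
    Dense,
    EmbedConcat,
    Flatten,
    MultiBranch,
    Reshape,
    Sequential,
    elu,
)
from .synthetic import ENVSIM_SOIL_GROUPS, SOIL_FEATURES, WEATHER_FEATURES, envsim_columns

__all__ = [
    "elu", "CNNConfig", "BaselineConfig", "MultimodalInputs",
    "build_single_modal", "build_multimodal", "CNNRegressor",
    "oversample_treatments", "train_xgb_yield_features", "fit_baseline",
    "grid_search_ensemble_weights", "ensemble_predict",
    "assemble_multimodal_inputs", "flatten_inputs", "XGB_FEATURE_COLS",
    "fit_meta_encoders", "small_cnn_config", "xgb_feature_frame",
]


@dataclass
class CNNConfig:
    """Architecture and training settings for the CNN-DNN models.

    Filter counts default to the 32→16 pattern with kernel size 5 and
    pooling size 2; small 2D grids (the 10x9 simulator fields) use 3x3
    kernels. The two head dense layers carry L1 regularization; every layer
    is ELU-activated except the linear output.
    """

    filters1: int = 32
    filters2: int = 16
    kernel1d: int = 5
    kernel2d: tuple[int, int] = (5, 5)
    kernel2d_small: tuple[int, int] = (3, 3)
    pool: int = 2
    branch_dense: int = 16
    head_units: tuple[int, int] = (64, 16)
    l1: float = 1e-4
    elu_alpha: float = 1.0
    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.elu_alpha <= 0:
            raise ValueError("ELU alpha must be > 0")
        for name in ("filters1", "filters2", "kernel1d", "pool", "branch_dense",
                     "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0 or self.l1 < 0:
            raise ValueError("learning_rate must be > 0 and l1 >= 0")


def small_cnn_config(**overrides) -> CNNConfig:
    """Reduced-size preset for small synthetic cohorts."""
    base = CNNConfig(filters1=8, filters2=4, head_units=(32, 8), epochs=60, batch_size=32)
    return replace(base, **overrides)


@dataclass
class BaselineConfig:
    """Grid-searched hyperparameters of the three baselines."""

    lasso_penalty: float = 0.05
    rf_max_depth: int = 15
    rf_max_features: str = "sqrt"
    rf_min_samples_split: int = 15
    rf_n_trees: int = 400
    xgb_max_depth: int = 5
    xgb_eta: float = 0.05
    xgb_subsample: float = 0.75
    xgb_n_trees: int = 4000


@dataclass
class MultimodalInputs:
    """The six shaped blocks consumed by the multimodal network."""

    weather: np.ndarray          # (n, 48, 16)
    soil: np.ndarray             # (n, 23)
    genotype: np.ndarray         # (n, n_loci)
    metadata: np.ndarray         # (n, n_cat + n_num); first n_cat cols are codes
    envsim_soil: list[np.ndarray]  # 7 arrays, (n, 10, 9) except Flow (n, 9, 9)
    envsim_pheno: np.ndarray     # (n, n_pheno)
    meta_cardinalities: list[int] = field(default_factory=list)
    n_meta_numeric: int = 0

    def __post_init__(self) -> None:
        n = self.weather.shape[0]
        blocks = [self.soil, self.genotype, self.metadata, self.envsim_pheno, *self.envsim_soil]
        if any(b.shape[0] != n for b in blocks):
            raise ValueError("inconsistent row counts across input blocks")
        if len(self.envsim_soil) != len(ENVSIM_SOIL_GROUPS):
            raise ValueError(f"expected {len(ENVSIM_SOIL_GROUPS)} simulator soil groups")
        if np.isnan(self.weather).any():
            raise ValueError("weather block contains missing cells")

    @property
    def n(self) -> int:
        return int(self.weather.shape[0])

    def as_list(self) -> list:
        return [
            self.weather[..., None],
            self.soil[..., None],
            self.genotype[..., None],
            self.metadata,
            [g[..., None] for g in self.envsim_soil],
            self.envsim_pheno[..., None],
        ]


def _conv1d_block(c: CNNConfig, length: int, rng: np.random.Generator,
                  with_dense: bool = True) -> Sequential:
    """1D branch: two convolutions, average pooling, flatten, dense."""
    k = min(c.kernel1d, max(1, length - 1))
    layers: list = [
        Conv1D(1, c.filters1, k, alpha=c.elu_alpha, rng=rng),
        Conv1D(c.filters1, c.filters2, k, alpha=c.elu_alpha, rng=rng),
        AvgPool1D(c.pool),
        Flatten(),
    ]
    out_len = ((length - 2 * (k - 1)) // c.pool) * c.filters2
    if with_dense:
        layers.append(Dense(out_len, c.branch_dense, alpha=c.elu_alpha, rng=rng))
    return Sequential(layers)


def _conv2d_block(c: CNNConfig, shape: tuple[int, int], kernel: tuple[int, int],
                  rng: np.random.Generator) -> Sequential:
    h, w = shape
    kh, kw = min(kernel[0], h), min(kernel[1], w)
    ho, wo = h - 2 * (kh - 1), w - 2 * (kw - 1)
    layers: list = [
        Conv2D(1, c.filters1, (kh, kw), alpha=c.elu_alpha, rng=rng),
        Conv2D(c.filters1, c.filters2, (kh, kw), alpha=c.elu_alpha, rng=rng),
        AvgPool2D(c.pool),
        Flatten(),
    ]
    out = (ho // c.pool) * (wo // c.pool) * c.filters2
    layers.append(Dense(out, c.branch_dense, alpha=c.elu_alpha, rng=rng))
    return Sequential(layers)


def build_single_modal(input_width: int, config: CNNConfig | None = None) -> Sequential:
    """Eight-layer single-modal CNN-DNN over a flat input vector.

    Input -> two 1D convolutions (32 then 16 filters, kernel 5) -> average
    pooling -> two further 1D convolutions -> flatten -> three dense layers,
    the last a scalar linear output.
    """
    c = config or CNNConfig()
    rng = np.random.default_rng(c.seed)
    k = c.kernel1d
    len1 = input_width - (k - 1)
    len2 = len1 - (k - 1)
    len_pool = len2 // c.pool
    f3, f4 = max(c.filters2 // 2, 1), max(c.filters2 // 2, 1)
    len3 = len_pool - (k - 1)
    len4 = len3 - (k - 1)
    if len4 < 1:
        raise ValueError(
            f"input width {input_width} too small for four kernel-{k} convolutions"
        )
    flat = len4 * f4
    return Sequential([
        Reshape((input_width, 1)),
        Conv1D(1, c.filters1, k, alpha=c.elu_alpha, rng=rng),
        Conv1D(c.filters1, c.filters2, k, alpha=c.elu_alpha, rng=rng),
        AvgPool1D(c.pool),
        Conv1D(c.filters2, f3, k, alpha=c.elu_alpha, rng=rng),
        Conv1D(f3, f4, k, alpha=c.elu_alpha, rng=rng),
        Flatten(),
        Dense(flat, c.head_units[0], alpha=c.elu_alpha, rng=rng),
        Dense(c.head_units[0], c.head_units[1], alpha=c.elu_alpha, rng=rng),
        Dense(c.head_units[1], 1, activation="linear", rng=rng),
    ])


def build_multimodal(inputs: MultimodalInputs, config: CNNConfig | None = None) -> MultiBranch:
    """Six-branch multimodal CNN-DNN.

    Branches: weather (n,48,16) through two 2D convolutions; soil and
    genotype through 1D convolution blocks; metadata through embeddings
    concatenated with numerics then two 1D convolutions; the crop-simulator
    soil block as 7 parallel 2D sub-blocks concatenated; simulator phenology
    through a 1D block. Branch outputs concatenate into two L1-regularized
    dense layers and a linear output.
    """
    c = config or CNNConfig()
    rng = np.random.default_rng(c.seed)

    weather = _conv2d_block(c, inputs.weather.shape[1:3], c.kernel2d, rng)
    soil = _conv1d_block(c, inputs.soil.shape[1], rng)
    genotype = _conv1d_block(c, inputs.genotype.shape[1], rng)

    embed = EmbedConcat(inputs.meta_cardinalities, inputs.n_meta_numeric, rng=rng)
    meta_len = embed.out_width
    km = min(3, meta_len - 1)
    meta_conv = Sequential([
        embed,
        Reshape((meta_len, 1)),
        Conv1D(1, c.filters2, km, alpha=c.elu_alpha, rng=rng),
        Conv1D(c.filters2, max(c.filters2 // 2, 1), km, alpha=c.elu_alpha, rng=rng),
        Flatten(),
    ])

    envsim_blocks = [
        (grp, _conv2d_block(c, arr.shape[1:3], c.kernel2d_small, rng))
        for grp, arr in zip(ENVSIM_SOIL_GROUPS, inputs.envsim_soil)
    ]
    envsim = MultiBranch(envsim_blocks, head=Sequential([]))
    pheno = _conv1d_block(c, inputs.envsim_pheno.shape[1], rng)

    branches = [
        ("weather", weather),
        ("soil", soil),
        ("genotype", genotype),
        ("metadata", meta_conv),
        ("envsim_soil", envsim),
        ("envsim_pheno", pheno),
    ]
    width = 0
    for (_, b), x in zip(branches, inputs.as_list()):
        probe = [xi[:1] for xi in x] if isinstance(x, list) else x[:1]
        width += b.forward(probe).shape[1]
    head = Sequential([
        Dense(width, c.head_units[0], alpha=c.elu_alpha, l1=c.l1, rng=rng),
        Dense(c.head_units[0], c.head_units[1], alpha=c.elu_alpha, l1=c.l1, rng=rng),
        Dense(c.head_units[1], 1, activation="linear", rng=rng),
    ])
    return MultiBranch(branches, head)


def _standardize_block(x, stats=None):
    """Mean/std standardization; constant columns pass through centered."""
    if isinstance(x, list):
        if stats is None:
            stats = [None] * len(x)
        pairs = [_standardize_block(xi, s) for xi, s in zip(x, stats)]
        return [p[0] for p in pairs], [p[1] for p in pairs]
    if stats is None:
        mu = x.mean(axis=0, keepdims=True)
        sd = x.std(axis=0, keepdims=True)
        sd = np.where(sd < 1e-9, 1.0, sd)
        stats = (mu, sd)
    mu, sd = stats
    return (x - mu) / sd, stats


class CNNRegressor:
    """Training/prediction wrapper around a built network.

    Standardizes every numeric input block and the target on ``fit`` (storing
    the statistics for prediction), then minimizes mean squared error plus
    the network's L1 penalty with Adam over shuffled mini-batches. Fully
    deterministic for a fixed config seed.
    """

    def __init__(self, net, config: CNNConfig, multimodal: bool = False):
        self.net = net
        self.config = config
        self.multimodal = multimodal
        self._input_stats = None
        self._y_stats = None
        self.history: list[float] = []

    def _prep(self, X, fit: bool):
        if not self.multimodal:
            X = np.asarray(X, dtype=float)
            if fit:
                Xs, self._input_stats = _standardize_block(X)
            else:
                Xs, _ = _standardize_block(X, self._input_stats)
            return Xs
        blocks = X.as_list() if isinstance(X, MultimodalInputs) else X
        out, stats = [], []
        saved = self._input_stats if not fit else [None] * len(blocks)
        for i, block in enumerate(blocks):
            if i == 3:  # metadata: standardize only the numeric tail
                n_cat = len(X.meta_cardinalities)
                numeric = block[:, n_cat:]
                if fit:
                    num_s, st = _standardize_block(numeric)
                else:
                    num_s, st = _standardize_block(numeric, saved[i])
                out.append(np.concatenate([block[:, :n_cat], num_s], axis=1))
                stats.append(st)
            else:
                if fit:
                    b_s, st = _standardize_block(block)
                else:
                    b_s, st = _standardize_block(block, saved[i])
                out.append(b_s)
                stats.append(st)
        if fit:
            self._input_stats = stats
        return out

    @staticmethod
    def _take(X, idx):
        if isinstance(X, list):
            return [CNNRegressor._take(xi, idx) for xi in X]
        return X[idx]

    def fit(self, X, y: np.ndarray) -> "CNNRegressor":
        c = self.config
        rng = np.random.default_rng(c.seed + 1)
        Xs = self._prep(X, fit=True)
        y = np.asarray(y, dtype=float)
        mu, sd = float(y.mean()), float(y.std())
        sd = sd if sd > 1e-9 else 1.0
        self._y_stats = (mu, sd)
        ys = (y - mu) / sd

        n = len(ys)
        opt = Adam(self.net.all_params(), lr=c.learning_rate)
        for _ in range(c.epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, c.batch_size):
                idx = order[start:start + c.batch_size]
                xb = self._take(Xs, idx)
                yb = ys[idx]
                pred = self.net.forward(xb).ravel()
                err = pred - yb
                total += float((err ** 2).sum())
                grad = (2.0 * err / len(idx))[:, None]
                self.net.backward(grad)
                opt.step()
            self.history.append(total / n + self.net.l1_penalty())
        return self

    def predict(self, X) -> np.ndarray:
        Xs = self._prep(X, fit=False)
        mu, sd = self._y_stats
        return self.net.forward(Xs).ravel() * sd + mu


# ---------------------------------------------------------------------------
# input assembly
# ---------------------------------------------------------------------------

META_CATEGORICALS = ["location", "treatment"]
META_NUMERICS = ["planting_doy", "year"] + YIELD_FEATURE_COLS


def fit_meta_encoders(frame: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Label-encode categorical metadata; index 0 is reserved for unseen."""
    return {
        col: {v: i + 1 for i, v in enumerate(sorted(frame[col].astype(str).unique()))}
        for col in META_CATEGORICALS
    }


def assemble_multimodal_inputs(
    frame: pd.DataFrame,
    weather: dict[str, np.ndarray],
    genotype: pd.DataFrame,
    encoders: dict[str, dict[str, int]],
) -> tuple[MultimodalInputs, np.ndarray]:
    """Shape a preprocessed, feature-attached frame into the six model blocks."""
    n = len(frame)
    wx = np.stack([weather[e] for e in frame["Env"]])
    soil = frame[SOIL_FEATURES].to_numpy(dtype=float)
    geno = genotype.loc[frame["Hybrid"]].to_numpy(dtype=float)

    codes = np.column_stack([
        frame[col].astype(str).map(lambda v, m=encoders[col]: m.get(v, 0)).to_numpy(dtype=float)
        for col in META_CATEGORICALS
    ])
    numerics = frame[META_NUMERICS].to_numpy(dtype=float)
    metadata = np.concatenate([codes, numerics], axis=1)
    cardinalities = [len(encoders[c]) + 1 for c in META_CATEGORICALS]

    soil_groups = []
    from .synthetic import ENVSIM_DEPTHS, ENVSIM_FLOW_DEPTHS, ENVSIM_STAGES
    for grp in ENVSIM_SOIL_GROUPS:
        depths = ENVSIM_FLOW_DEPTHS if grp == "Flow" else ENVSIM_DEPTHS
        cols = [f"{grp}_d{d+1}_s{s+1}" for d in range(depths) for s in range(ENVSIM_STAGES)]
        soil_groups.append(frame[cols].to_numpy(dtype=float).reshape(n, depths, ENVSIM_STAGES))
    _, pheno_cols = envsim_columns()
    pheno = frame[pheno_cols].to_numpy(dtype=float)

    mm = MultimodalInputs(
        weather=wx, soil=soil, genotype=geno, metadata=metadata,
        envsim_soil=soil_groups, envsim_pheno=pheno,
        meta_cardinalities=cardinalities, n_meta_numeric=numerics.shape[1],
    )
    y = frame["yield"].to_numpy(dtype=float) if "yield" in frame else np.full(n, np.nan)
    return mm, y


def flatten_inputs(mm: MultimodalInputs) -> np.ndarray:
    """Concatenate all blocks into one flat vector per row (single-modal input)."""
    parts = [
        mm.weather.reshape(mm.n, -1),
        mm.soil,
        mm.genotype,
        mm.metadata,
        *[g.reshape(mm.n, -1) for g in mm.envsim_soil],
        mm.envsim_pheno,
    ]
    return np.concatenate(parts, axis=1)


# ---------------------------------------------------------------------------
# oversampling and the yield-feature XGBoost
# ---------------------------------------------------------------------------

def oversample_treatments(
    training: pd.DataFrame,
    per_treatment: int = 4000,
    late_relabel: int = 1000,
    seed: int = 0,
    treatment_col: str = "treatment",
    exclude: tuple[str, ...] = ("standard", "late planting"),
    late_label: str = "late planting",
) -> pd.DataFrame:
    """Rebalance treatments by resampling with replacement.

    For each observed treatment outside ``exclude``, append ``per_treatment``
    resampled rows, plus ``late_relabel`` resampled rows relabeled as late
    planting (a scenario absent from real training data). Original rows are
    returned untouched at the front; the appended count is exactly
    ``len(eligible) * (per_treatment + late_relabel)``.
    """
    rng = np.random.default_rng(seed)
    eligible = sorted(set(training[treatment_col].dropna()) - set(exclude))
    if not eligible:
        return training.copy()
    chunks = [training]
    for tr in eligible:
        pool = training[training[treatment_col] == tr]
        idx = rng.integers(0, len(pool), size=per_treatment)
        chunks.append(pool.iloc[idx])
        idx2 = rng.integers(0, len(pool), size=late_relabel)
        relabeled = pool.iloc[idx2].copy()
        relabeled[treatment_col] = late_label
        chunks.append(relabeled)
    return pd.concat(chunks, ignore_index=True)


XGB_FEATURE_COLS = ["planting_doy", "year"] + YIELD_FEATURE_COLS
FORBIDDEN_XGB_PREFIXES = tuple(WEATHER_FEATURES) + tuple(SOIL_FEATURES) + ("locus_",)


def xgb_feature_frame(rows: pd.DataFrame, encoders: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Restricted feature matrix: metadata plus engineered yield features only."""
    missing = [c for c in XGB_FEATURE_COLS if c not in rows.columns]
    if missing:
        raise KeyError(f"missing yield-feature columns: {missing}")
    out = rows[XGB_FEATURE_COLS].copy()
    for col in META_CATEGORICALS:
        out[col + "_code"] = rows[col].astype(str).map(lambda v, m=encoders[col]: m.get(v, 0))
    assert not any(c.startswith(FORBIDDEN_XGB_PREFIXES) for c in out.columns)
    return out


def train_xgb_yield_features(
    augmented: pd.DataFrame,
    encoders: dict[str, dict[str, int]],
    config: BaselineConfig | None = None,
    n_trees: int | None = None,
    seed: int = 0,
) -> XGBRegressor:
    """Gradient-boosted regressor on the oversampled, feature-restricted set."""
    c = config or BaselineConfig()
    X = xgb_feature_frame(augmented, encoders)
    y = augmented["yield"].to_numpy(dtype=float)
    model = XGBRegressor(
        max_depth=c.xgb_max_depth,
        learning_rate=c.xgb_eta,
        subsample=c.xgb_subsample,
        n_estimators=n_trees or c.xgb_n_trees,
        tree_method="exact",
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return model


def fit_baseline(
    name: str,
    X: np.ndarray,
    y: np.ndarray,
    config: BaselineConfig | None = None,
    seed: int = 0,
    **overrides,
):
    """Fit one of the flat-feature baselines with the reference hyperparameters."""
    c = config or BaselineConfig()
    if name == "lasso":
        model = Lasso(alpha=overrides.get("alpha", c.lasso_penalty), max_iter=10000)
    elif name == "rf":
        model = RandomForestRegressor(
            max_depth=overrides.get("max_depth", c.rf_max_depth),
            max_features=overrides.get("max_features", c.rf_max_features),
            min_samples_split=overrides.get("min_samples_split", c.rf_min_samples_split),
            n_estimators=overrides.get("n_estimators", c.rf_n_trees),
            random_state=seed,
            n_jobs=1,
        )
    elif name == "xgb":
        model = XGBRegressor(
            max_depth=overrides.get("max_depth", c.xgb_max_depth),
            learning_rate=overrides.get("eta", c.xgb_eta),
            subsample=overrides.get("subsample", c.xgb_subsample),
            n_estimators=overrides.get("n_estimators", c.xgb_n_trees),
            tree_method="exact",
            random_state=seed,
            n_jobs=1,
        )
    else:
        raise ValueError(f"unknown baseline {name!r}; expected lasso|rf|xgb")
    model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    return model


# ---------------------------------------------------------------------------
# ensembling
# ---------------------------------------------------------------------------

def ensemble_predict(w: EnsembleWeights, pred_xgb: np.ndarray, pred_cnn: np.ndarray) -> np.ndarray:
    pred_xgb, pred_cnn = np.asarray(pred_xgb, float), np.asarray(pred_cnn, float)
    if pred_xgb.shape != pred_cnn.shape:
        raise ValueError("prediction vectors differ in length")
    return w.w_xgb * pred_xgb + w.w_cnn * pred_cnn


def grid_search_ensemble_weights(
    pred_xgb: np.ndarray,
    pred_cnn: np.ndarray,
    y_val: np.ndarray,
    step: float = 0.1,
) -> EnsembleWeights:
    """Scan convex weight pairs in ``step`` increments, minimizing validation RMSE.

    Ties resolve toward the larger CNN weight.
    """
    pred_xgb, pred_cnn, y_val = (np.asarray(a, float) for a in (pred_xgb, pred_cnn, y_val))
    if not (len(pred_xgb) == len(pred_cnn) == len(y_val)):
        raise ValueError("prediction/validation vectors differ in length")
    n_steps = int(round(1.0 / step))
    best, best_rmse = None, np.inf
    for i in range(n_steps + 1):  # w_xgb ascending => ties keep larger w_cnn
        w_xgb = i * step
        blend = w_xgb * pred_xgb + (1.0 - w_xgb) * pred_cnn
        rmse = float(np.sqrt(np.mean((blend - y_val) ** 2)))
        if rmse < best_rmse - 1e-12:
            best, best_rmse = w_xgb, rmse
    return EnsembleWeights(w_xgb=round(best, 10), w_cnn=round(1.0 - best, 10))
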