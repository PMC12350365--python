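"""Configuration objects shared across the pipeline.

Every stage of the pipeline is driven by a small dataclass so that runs are
fully reproducible from a config file plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: The eight agronomic treatment classes observed in G2F-style trials.
DEFAULT_TREATMENTS: tuple[str, ...] = (
    "standard",
    "drought",
    "irrigated",
    "disease trial",
    "early planting",
    "late planting",
    "late stressed",
    "dryland",
)

#: Default probabilities for genotype call strings. The four diploid biallelic
#: calls carry almost all of the mass; rare multi-allelic calls together stay
#: below 5% of cells.
DEFAULT_CALL_MIX: dict[str, float] = {
    "0/0": 0.52,
    "0/1": 0.16,
    "1/0": 0.16,
    "1/1": 0.13,
    "2/0": 0.006,
    "0/2": 0.006,
    "2/1": 0.005,
    "1/2": 0.005,
    "2/2": 0.004,
    "3/0": 0.004,
}


@dataclass
class EffectSizes:
    """Ground-truth effect sizes injected into synthetic yields (Mg/ha).

    Parameters
    ----------
    state_sd
        Standard deviation of the per-state additive yield effect.
    locus_effect
        Absolute additive effect per unit dosage at each causal locus.
    n_causal_loci
        Number of loci given a nonzero effect.
    planting_penalty_per_day
        Yield lost per day of planting beyond the planting window.
    treatment_offsets
        Additive offset per treatment class relative to standard.
    noise_sd
        Standard deviation of the Gaussian residual.
    """

    state_sd: float = 1.5
    locus_effect: float = 0.3
    n_causal_loci: int = 8
    planting_penalty_per_day: float = 0.05
    treatment_offsets: dict[str, float] = field(
        default_factory=lambda: {
            "standard": 0.0,
            "drought": -2.5,
            "irrigated": 0.5,
            "disease trial": -1.5,
            "early planting": -0.5,
            "late planting": 0.0,  # penalised through planting date instead
            "late stressed": -1.8,
            "dryland": -1.0,
        }
    )
    noise_sd: float = 1.0


@dataclass
class SyntheticConfig:
    """Shape and effect parameters for the synthetic six-table dataset.

    The defaults are a reduced-scale stand-in for a multi-state, multi-year
    hybrid trial network: a handful of states with a few locations each,
    several trial years, and a cohort of hybrids genotyped at a modest number
    of loci. Baseline yield of 9.44 Mg/ha matches a typical training-period
    mean for US maize trials.
    """

    n_states: int = 4
    envs_per_state: int = 2
    years: tuple[int, int] = (2018, 2021)
    n_hybrids: int = 60
    n_loci: int = 80
    n_days: int = 365
    hybrids_per_env: int = 30
    treatment_classes: tuple[str, ...] = DEFAULT_TREATMENTS
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {
            "metadata": 0.05,
            "soil": 0.05,
            "envsim": 0.03,
            "genotype_loci": 0.15,  # fraction of loci that are missing-prone
        }
    )
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    baseline_yield: float = 9.44
    planting_window: tuple[int, int] = (110, 140)
    missing_marker: str = "./."
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_states": self.n_states,
            "envs_per_state": self.envs_per_state,
            "n_hybrids": self.n_hybrids,
            "n_loci": self.n_loci,
            "n_days": self.n_days,
            "hybrids_per_env": self.hybrids_per_env,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.years[0] > self.years[1]:
            raise ValueError(f"years range is inverted: {self.years}")
        for table, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {table} not in [0, 1]: {rate}")
        if self.effect_sizes.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class LocusFilterParams:
    """Parameters of the informative-locus selection rule.

    The reference cohort had 4,928 hybrids and used absolute thresholds of
    "fewer than 4,000 hybrids at dosage 0" and "at least 1,000 hybrids at
    dosage 0.5"; the defaults re-express those as fractions so the rule scales
    to any cohort size.
    """

    max_zero_fraction: float = 4000 / 4928
    min_het_fraction: float = 1000 / 4928
    forbid_other_code: bool = True
    n_sample: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_zero_fraction", "min_het_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.n_sample < 1:
            raise ValueError("n_sample must be >= 1")


@dataclass
class ClassRule:
    """Thresholds of the empirical yield-class rule (Mg/ha).

    ``t_low``/``t_high`` split the yield scale into low/moderate/high regions;
    ``wide_span`` is the minimum max-min spread for the "wide range" class.
    ``use_mean`` substitutes the mean for the median in the central branches.
    """

    t_low: float = 6.0
    t_high: float = 10.0
    wide_span: float = 8.0
    use_mean: bool = False

    def __post_init__(self) -> None:
        if not self.t_low < self.t_high:
            raise ValueError("t_low must be < t_high")
        if self.wide_span <= 0:
            raise ValueError("wide_span must be > 0")


@dataclass
class EnsembleWeights:
    """Convex weights combining XGBoost and CNN-DNN predictions."""

    w_xgb: float
    w_cnn: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_xgb <= 1.0 and 0.0 <= self.w_cnn <= 1.0):
            raise ValueError("weights must lie in [0, 1]")
        if abs(self.w_xgb + self.w_cnn - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
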