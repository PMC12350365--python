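import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from maizegxe import SyntheticConfig
from maizegxe.features import attach_yield_features, fit_yield_features
from maizegxe.genotype import prepare_genotypes
from maizegxe.models import assemble_multimodal_inputs, fit_meta_encoders, flatten_inputs
from maizegxe.preprocess import preprocess
from maizegxe.synthetic import generate_dataset

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


TINY = SyntheticConfig(
    n_states=3,
    envs_per_state=1,
    years=(2019, 2021),
    n_hybrids=40,
    n_loci=50,
    hybrids_per_env=12,
    seed=42,
)


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    return TINY


@pytest.fixture(scope="session")
def tiny_raw(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_merged(tiny_raw):
    dosages, _ = prepare_genotypes(tiny_raw.genotype_table)
    return preprocess(tiny_raw, dosages), dosages


@pytest.fixture(scope="session")
def tiny_split(tiny_merged):
    """Feature-attached train/test frames plus shaped inputs for the tiny cohort."""
    merged, dosages = tiny_merged
    frame = merged.frame
    train = frame[frame["year"] <= 2020].reset_index(drop=True)
    test = frame[frame["year"] == 2021].reset_index(drop=True)
    feats = fit_yield_features(train)
    train_f = attach_yield_features(train, feats)
    test_f = attach_yield_features(test, feats)
    encoders = fit_meta_encoders(train_f)
    mm_train, y_train = assemble_multimodal_inputs(train_f, merged.weather, dosages, encoders)
    mm_test, y_test = assemble_multimodal_inputs(test_f, merged.weather, dosages, encoders)
    return {
        "merged": merged,
        "dosages": dosages,
        "train_f": train_f,
        "test_f": test_f,
        "encoders": encoders,
        "mm_train": mm_train,
        "mm_test": mm_test,
        "y_train": y_train,
        "y_test": y_test,
        "X_train": flatten_inputs(mm_train),
        "X_test": flatten_inputs(mm_test),
        "feats": feats,
    }


def make_trait_frame(rows: list[tuple]) -> pd.DataFrame:
    """(hybrid, treatment, yield) tuples -> trait frame."""
    return pd.DataFrame(rows, columns=["Hybrid", "treatment", "yield"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
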