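"""Shared fixtures: small synthetic cohorts and a tiny trainable spec."""

import numpy as np
import pytest

from ecglite.architecture import LayerDescriptor, ModelSpec
from ecglite.preprocess import PreprocessConfig, run_preprocessing
from ecglite.synthetic import SynthConfig, cohort_to_segment_table, synth_cohort


@pytest.fixture(scope="session")
def tiny_spec() -> ModelSpec:
    """A small but structurally complete CNN (fast to train in tests)."""
    return ModelSpec(
        name="tiny", input_len=100, input_channels=1, n_classes=2,
        layers=(
            LayerDescriptor(kind="conv1d", filters=4, kernel_size=7),
            LayerDescriptor(kind="maxpool1d", pool_size=2, stride=2),
            LayerDescriptor(kind="conv1d", filters=8, kernel_size=5),
            LayerDescriptor(kind="maxpool1d", pool_size=2, stride=2),
            LayerDescriptor(kind="flatten"),
            LayerDescriptor(kind="dropout", rate=0.2),
            LayerDescriptor(kind="dense", units=8, activation="relu"),
            LayerDescriptor(kind="dense", units=2, activation="none"),
            LayerDescriptor(kind="softmax"),
        ),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Four-patient NSR/AF cohort, 60-s records."""
    cfg = SynthConfig(duration_s=60.0)
    return synth_cohort(4, {"NSR": 0.5, "AF": 0.5}, cfg, seed=3)


@pytest.fixture(scope="session")
def small_binary_ws(small_cohort):
    """Binary window set from the small cohort's 30-s segment table."""
    table = cohort_to_segment_table(small_cohort)
    return run_preprocessing(table, PreprocessConfig(), mode="binary")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
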