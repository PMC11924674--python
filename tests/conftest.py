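"""Shared fixtures: one default synthetic survey, conditioned and gated."""

import numpy as np
import pytest

from endoraman import (
    GeneratorConfig,
    default_calibration,
    gate,
    generate_raw,
    preprocess_dataset,
)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def calib(default_config):
    return default_calibration(default_config)


@pytest.fixture(scope="session")
def raw_ds(default_config):
    return generate_raw(default_config)


@pytest.fixture(scope="session")
def processed_ds(raw_ds, calib):
    return preprocess_dataset(raw_ds, calib)


@pytest.fixture(scope="session")
def gated_ds(processed_ds):
    kept, _ = gate(processed_ds)
    return kept


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
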