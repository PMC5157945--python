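import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from nmoa import DesignSpec, GroundTruth, ModelConfig, demo_model_config


@pytest.fixture(scope="session")
def demo_config() -> ModelConfig:
    return demo_model_config()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_design() -> DesignSpec:
    return DesignSpec(n_subjects=1, n_sessions=1)


@pytest.fixture(scope="session")
def response_gain_truth() -> GroundTruth:
    """Pure response-gain generator: d'max differs, c50 identical."""
    return GroundTruth(
        curves={
            ("narrow", "valid"): (2.8, 0.25),
            ("narrow", "invalid"): (2.0, 0.25),
            ("broad", "valid"): (2.6, 0.25),
            ("broad", "invalid"): (2.0, 0.25),
        },
        exponent=1.5,
    )


@pytest.fixture(scope="session")
def coherence_gain_truth() -> GroundTruth:
    """Pure coherence-gain generator: c50 differs, d'max identical."""
    return GroundTruth(
        curves={
            ("narrow", "valid"): (2.4, 0.15),
            ("narrow", "invalid"): (2.4, 0.30),
            ("broad", "valid"): (2.4, 0.20),
            ("broad", "invalid"): (2.4, 0.30),
        },
        exponent=1.5,
    )
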