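import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from txnsim import (
    KineticParameters,
    ProbeSpec,
    VALIDATION_GROUND_TRUTH,
    generate_synthetic_target,
    make_turn_on_protocol,
)


@pytest.fixture(scope="session")
def ground_truth() -> KineticParameters:
    """The bursty-promoter parameter set used for synthetic validation."""
    return VALIDATION_GROUND_TRUTH


@pytest.fixture(scope="session")
def full_probe() -> ProbeSpec:
    return ProbeSpec(0.0, 1.0)


@pytest.fixture(scope="session")
def turn_on_protocol():
    return make_turn_on_protocol(t_end=15.0)


@pytest.fixture(scope="session")
def validation_target(ground_truth, turn_on_protocol, full_probe):
    """2,000-cell synthetic turn-on target shared by the recovery tests."""
    return generate_synthetic_target(
        ground_truth, turn_on_protocol, full_probe, n_cells=2000, seed=11
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
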