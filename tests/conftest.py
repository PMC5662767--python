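import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from smoscreen import PopulationConfig, fit_gate, simulate_well


@pytest.fixture(scope="session")
def pop_config() -> PopulationConfig:
    """Default population model, 4000 events/well."""
    return PopulationConfig(seed=0)


@pytest.fixture(scope="session")
def clean_config() -> PopulationConfig:
    """Debris-free population for gating-independent checks."""
    return PopulationConfig(debris_fraction=0.0, seed=0)


@pytest.fixture(scope="session")
def control_gate(clean_config):
    """Wide gate (99% coverage) fitted on a debris-free unstimulated well."""
    ctrl = simulate_well(clean_config, 0.0, seed=101, well_id="ctrl")
    return fit_gate(ctrl, coverage_quantile=0.99)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
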