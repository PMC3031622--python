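import numpy as np
import pytest
from hypothesis import settings

from cogassoc.cohort import CohortConfig

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    """The study-design defaults (46/73/67, MAF 0.067)."""
    return CohortConfig(seed=0)


@pytest.fixture(scope="session")
def null_config() -> CohortConfig:
    """Same design but every carrier effect switched off."""
    zero4 = (0.0, 0.0, 0.0, 0.0)
    return CohortConfig(
        carrier_effect_sensitivity=zero4,
        carrier_effect_false_alarms=zero4,
        carrier_effects_other={},
        seed=0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
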