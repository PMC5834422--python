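import numpy as np
import pytest

from sibilant_ef.spectral import SpectralConfig
from sibilant_ef.synthetic_data import CohortSpec, synth_cohort


@pytest.fixture(scope="session")
def spectral_config() -> SpectralConfig:
    return SpectralConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-child cohort, enough to exercise every pipeline stage quickly."""
    return synth_cohort(CohortSpec(n_children=6, seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
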