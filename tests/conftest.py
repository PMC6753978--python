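import numpy as np
import pytest

from neutralfire import SpeciesFrequencyDistribution, generate_metacommunity


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def two_species():
    """Balanced two-species pool for binomial checks."""
    return SpeciesFrequencyDistribution(("A", "B"), np.array([50, 50]), 10)


@pytest.fixture(scope="session")
def skewed_meta():
    """A right-skewed log-series metacommunity at census scale (123 spp, 7000 cells)."""
    return generate_metacommunity(123, 20.0, 7000, np.random.default_rng(7))
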