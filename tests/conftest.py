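import numpy as np
import pytest

from benthicflux.physchem import DiffusivityRegistry, SedimentProperties


@pytest.fixture
def props() -> SedimentProperties:
    return SedimentProperties(porosity=0.85, solid_density=2.6, salinity=30.0, temperature=4.0)


@pytest.fixture
def fresh_props() -> SedimentProperties:
    """Freshwater, so D0 has no viscosity correction (cleaner hand arithmetic)."""
    return SedimentProperties(porosity=0.85, solid_density=2.6, salinity=0.0, temperature=4.0)


@pytest.fixture(scope="session")
def registry() -> DiffusivityRegistry:
    return DiffusivityRegistry.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
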