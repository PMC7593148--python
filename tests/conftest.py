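import numpy as np
import pytest

from chronoecol import SimConfig, SpeciesConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_species_config():
    """Small antiphase two-species world, no evolution, no stabilization."""
    return SimConfig(
        species=[
            SpeciesConfig(n0=40, amplitude0=1.0, phase0=0.0, k=0.5),
            SpeciesConfig(n0=40, amplitude0=1.0, phase0=180.0, k=0.5),
        ],
        stabilize=False,
        horizon_days=100,
    )


@pytest.fixture
def single_species_config():
    return SimConfig(
        species=[SpeciesConfig(n0=60, amplitude0=0.0, phase0=0.0, k=1.0)],
        stabilize=True,
        horizon_days=50,
    )
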