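import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import amorphquant as aq

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def nir_cfg():
    return aq.SimulationConfig(modality=aq.Modality.NIR, seed=7)


@pytest.fixture
def raman_cfg():
    return aq.SimulationConfig(modality=aq.Modality.RAMAN, seed=7)


@pytest.fixture
def noiseless_nir_cfg():
    return aq.SimulationConfig(
        modality=aq.Modality.NIR, noise=aq.NoiseModel.noiseless(), seed=7
    )


@pytest.fixture
def noiseless_raman_cfg():
    return aq.SimulationConfig(
        modality=aq.Modality.RAMAN, noise=aq.NoiseModel.noiseless(), seed=7
    )


@pytest.fixture
def blend_20pct():
    """20% w/w drug (half crystalline, half amorphous) in 77% HPC + 3% colourant."""
    return aq.MixtureComposition(10.0, 10.0, 77.0, 3.0)
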