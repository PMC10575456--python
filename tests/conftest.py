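import numpy as np
import pytest

from wheatcgi.synthetic import SimConfig, simulate_field


def noise_free_config(seed: int = 3, **kwargs) -> SimConfig:
    """A campaign with every tunable noise source switched off."""
    return SimConfig(
        seed=seed,
        noise_sd_reflectance=0.0,
        noise_sd_ground={"AGB": 0.0, "SPAD": 0.0, "LWC": 0.0},
        **kwargs,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default-noise campaign shared across read-only tests."""
    return simulate_field(SimConfig(seed=11))


@pytest.fixture(scope="session")
def noise_free_dataset():
    return simulate_field(noise_free_config(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
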