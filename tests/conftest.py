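import numpy as np
import pytest

from p53pulse import GeneratorConfig, TemperatureProtocol, generate_experiment


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def clean_config() -> GeneratorConfig:
    """Generator settings with all technical artifacts switched off."""
    return GeneratorConfig(
        noise_sd=0.0, spike_rate=0.0, shift_rate=0.0, division_rate_24h_37=0.0,
        division_rate_irradiated=0.0,
    )


@pytest.fixture(scope="session")
def pulsatile_experiment(default_config):
    """Irradiated 37 °C population with default artifacts (30 cells)."""
    exp, truth = generate_experiment(
        default_config,
        TemperatureProtocol.constant(37.0),
        dose_gy=10.0,
        n_cells=30,
        seed=101,
        experiment_id="t37",
    )
    return exp, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
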