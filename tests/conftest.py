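import pandas as pd
import pytest

from dielmetab import OpenWaterMetabolism, SimulationConfig, simulate_deployment
from dielmetab.synthetic import DEFAULT_STATION


@pytest.fixture(scope="session")
def station():
    return DEFAULT_STATION


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free 10-day deployment: (sonde, met, truth)."""
    cfg = SimulationConfig(seed=11, obs_noise_sd=0.0, advection_noise_sd=0.0)
    return simulate_deployment(cfg)


@pytest.fixture(scope="session")
def clean_fit(clean_sim, station):
    sonde, met, _ = clean_sim
    return OpenWaterMetabolism.from_records(sonde, met, station).fit()
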