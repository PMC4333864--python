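import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")

from methanotherm import thermo
from methanotherm.synthetic import ScenarioConfig, build_default_scenario, simulate_dataset


@pytest.fixture(scope="session")
def default_config() -> ScenarioConfig:
    return build_default_scenario()


@pytest.fixture(scope="session")
def noise_free_config() -> ScenarioConfig:
    return build_default_scenario(
        noise_gas=0.0, noise_qpcr=0.0, noise_delta_permil=0.0, replicates=1
    )


@pytest.fixture(scope="session")
def noisy_dataset(default_config):
    return simulate_dataset(default_config, seed=12345)


def two_regime_rate(temperature_C, e_low=3.9, e_high=1.1, t_break=17.5,
                    rate_at_ref=11.884, ref_temp=35.0,
                    boltzmann=thermo.BOLTZMANN_EV_PER_K):
    """Exact two-regime Arrhenius rate, continuous at the break (test oracle)."""
    x = -1.0 / (boltzmann * (temperature_C + 273.15))
    x_ref = -1.0 / (boltzmann * (ref_temp + 273.15))
    x_b = -1.0 / (boltzmann * (t_break + 273.15))
    m_high = math.log(rate_at_ref) - e_high * x_ref
    if temperature_C > t_break:
        return math.exp(e_high * x + m_high)
    return math.exp(e_low * x + m_high + (e_high - e_low) * x_b)
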