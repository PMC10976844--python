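import numpy as np
import pandas as pd
import pytest

from odee.synthetic import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture
def sim_config():
    """Small-population config for fast unit tests."""
    return SimConfig(seed=7, n_individuals=40, years=10)


@pytest.fixture
def capture_table(sim_config):
    from odee.synthetic import simulate_population

    captures, truth = simulate_population(sim_config)
    return captures, truth


def make_deployment(counts, rate_hz=25.0, start="2019-05-10 12:00:00",
                    adc_basis=2 ** 14):
    """Assemble an AccelDeployment from a raw (3, n) count array."""
    from odee.accelerometry import AccelDeployment

    return AccelDeployment(
        individual_id="T000",
        season="spring",
        start=pd.Timestamp(start),
        rate_hz=rate_hz,
        counts=np.asarray(counts),
        adc_basis=adc_basis,
    )
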