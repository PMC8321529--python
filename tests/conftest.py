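import numpy as np
import pytest

from dupfate import synthio


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    return synthio.SimulationConfig(
        n_families=10,
        n_reads=200,
        duplicon_length=1000,
        read_length=50,
        genome_length=100_000,
        n_sd_intervals=4,
        sd_length=2_000,
        seed=7,
    )
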