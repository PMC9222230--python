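import numpy as np
import pytest

from tensordx.feature_extraction import run_td_pipeline
from tensordx.geo_io import normalize
from tensordx.synthetic_data import SimulationConfig, generate_dataset

PLANTED_CONFIG = SimulationConfig(n_probes=2000, frac_deg=0.1, effect_size=3.0,
                                  noise_sd=1.0, seed=7)
NULL_CONFIG = SimulationConfig(n_probes=2000, frac_deg=0.1, effect_size=0.0,
                               noise_sd=1.0, seed=3)


@pytest.fixture(scope="session")
def planted_dataset():
    return generate_dataset(PLANTED_CONFIG)


@pytest.fixture(scope="session")
def planted_normalized(planted_dataset):
    tensor, truth = planted_dataset
    return normalize(tensor), truth


@pytest.fixture(scope="session")
def planted_run(planted_normalized):
    tensor, truth = planted_normalized
    stat_table, report = run_td_pipeline(tensor)
    return stat_table, report, truth


@pytest.fixture(scope="session")
def null_dataset():
    return generate_dataset(NULL_CONFIG)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
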