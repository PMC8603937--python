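import numpy as np
import pytest

from mrcoarse.data import ModelParams
from mrcoarse.sim import simulate_individual


@pytest.fixture(scope="session")
def single_snp_params() -> ModelParams:
    """One strong instrument, unit-variance normal environment, confounding."""
    return ModelParams(alpha=[0.5], beta=1.0, confounding=0.5)


@pytest.fixture(scope="session")
def single_snp_data(single_snp_params):
    return simulate_individual(single_snp_params, 100_000, seed=101)


@pytest.fixture(scope="session")
def multi_snp_params() -> ModelParams:
    return ModelParams(
        alpha=[0.4, 0.3, 0.2],
        snp_freqs=[0.5, 0.3, 0.2],
        beta=1.0,
        confounding=0.5,
    )


@pytest.fixture(scope="session")
def multi_snp_data(multi_snp_params):
    return simulate_individual(multi_snp_params, 50_000, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
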