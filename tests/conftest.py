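import numpy as np
import pytest

from seqcea import (HealthState, SimulationConfig, default_catalogue,
                    enumerate_sequences, generate_param_catalogue)


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def param_catalogue(catalogue):
    return generate_param_catalogue(seed=1, catalogue=catalogue)


@pytest.fixture(scope="session")
def low_risk_sequences(catalogue):
    return enumerate_sequences(catalogue, HealthState.mCSPC_low)


@pytest.fixture(scope="session")
def nmcspc_sequences(catalogue):
    return enumerate_sequences(catalogue, HealthState.nmCSPC)


@pytest.fixture
def small_config():
    return SimulationConfig(n_patients=2_000, horizon=120, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
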