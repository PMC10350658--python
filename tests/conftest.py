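import numpy as np
import pytest

import algakin as ak


@pytest.fixture(scope="session")
def pretreat30_config():
    """Pretreatment run at the 30% w/w loading constants, default design."""
    return ak.SimulationConfig(
        model=ak.PRETREATMENT,
        rate_constants=ak.PRETREATMENT_BY_LOADING[30])


@pytest.fixture(scope="session")
def sacc55_config():
    """Saccharification run at the 55 degC constants, default design."""
    return ak.SimulationConfig(
        model=ak.SACCHARIFICATION,
        rate_constants=ak.SACCHARIFICATION_BY_TEMPERATURE[55])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230717)
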