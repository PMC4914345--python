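import warnings

import numpy as np
import pytest
from hypothesis import settings

from tfscreen import RunConfig, desk_config, run_primary_screen, simulate_screen

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def desk_data():
    """One small coherent synthetic screen shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_screen(desk_config(seed=11))


@pytest.fixture(scope="session")
def desk_result(desk_data):
    """Primary-screen result on the shared synthetic screen."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_primary_screen(
            RunConfig(seed=11, n_control_genes=200), data=desk_data
        )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
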