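import numpy as np
import pytest

import polymerkin as pk
from polymerkin.integrate import SolverConfig


@pytest.fixture(scope="session")
def quiet_solver():
    """Default solver with the truncation guard silenced (several fixtures
    deliberately run mass into the absorbing top species)."""
    return SolverConfig(truncation_warn=False)


@pytest.fixture(scope="session")
def equal_rates():
    return pk.equal_step_rates(k=12.9, km=2.2)


@pytest.fixture(scope="session")
def atp_rates():
    return pk.atp_hydrolysis_rates()


@pytest.fixture(scope="session")
def minute_grid():
    """30-s output grid over 15 minutes."""
    return np.arange(0.0, 901.0, 30.0)
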