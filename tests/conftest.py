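import pytest

from millitherm import (
    LPMParams,
    ThermalSystem,
    load_test_runs,
    load_training_runs,
)


@pytest.fixture(scope="session")
def training_runs():
    return load_training_runs()


@pytest.fixture(scope="session")
def test_runs():
    return load_test_runs()


@pytest.fixture
def run1_params():
    """Directly fitted parameters of the slowest-heating corner run."""
    return LPMParams(q_gen=755.2, ua=47.79)


@pytest.fixture
def run1_system():
    return ThermalSystem(mcp=465.6, t_ch=6.1, t_0=18.0)
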