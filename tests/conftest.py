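import pytest

from dechlor.core import BottleConfig, default_registry
from dechlor.scenarios import scenario_kd_table, scenario_params
from dechlor.simulator import simulate_microcosm


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def bottle():
    """Standard 160 mL / 100 mL liquid serum bottle, no sorbent."""
    return BottleConfig(sorbent_mass=0.0, sorbent_name="none")


@pytest.fixture(scope="session")
def kd_table():
    return scenario_kd_table()


@pytest.fixture(scope="session")
def char500_noisefree():
    """Noise-free Char500 arm, single replicate; reused by several suites."""
    params = scenario_params("Char500", noise_cv=0.0, n_replicates=1)
    return simulate_microcosm(params, seed=11)


@pytest.fixture(scope="session")
def char500_noisy():
    params = scenario_params("Char500", noise_cv=0.05, n_replicates=2)
    return simulate_microcosm(params, seed=11)
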