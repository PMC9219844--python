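import numpy as np
import pytest

from duomics.chem import default_adducts, default_compounds, default_observed_features
from duomics.simulate import SimulationConfig, simulate

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def registry():
    return default_compounds()


@pytest.fixture(scope="session")
def adducts():
    return default_adducts()


@pytest.fixture(scope="session")
def observed():
    return default_observed_features()


@pytest.fixture(scope="session")
def dataset():
    """One default-condition synthetic experiment, shared across tests."""
    return simulate(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced experiment for fast pipeline-level tests."""
    return simulate(SimulationConfig(seed=11, n_compounds=30, n_genes=200))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
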