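import numpy as np
import pytest

from rigidsite import synthetic_data as sd
from rigidsite.structure_io import catalytic_atom_set


@pytest.fixture(scope="session")
def toy_protein():
    return sd.generate_toy_protein(10, seed=1)


@pytest.fixture(scope="session")
def toy_catalytic_set(toy_protein):
    return catalytic_atom_set(toy_protein, sd.TOY_RESIDUE_MAP)


@pytest.fixture(scope="session")
def small_irf():
    # 512-channel axis keeps brute-force convolution oracles fast
    return sd.simulate_irf(40.0, channel_width_ps=8.0, n_channels=512)


@pytest.fixture(scope="session")
def standard_irf():
    return sd.simulate_irf(40.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
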