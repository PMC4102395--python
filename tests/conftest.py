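import numpy as np
import pytest

from p450kit.fixtures import make_gate_trajectory, make_helix, make_lipid_sheet, make_toy_heme


@pytest.fixture(scope="session")
def helix10():
    return make_helix(10)


@pytest.fixture(scope="session")
def toy_heme():
    return make_toy_heme(with_substrate=True)


@pytest.fixture(scope="session")
def toy_heme_bare():
    return make_toy_heme(with_substrate=False)


@pytest.fixture(scope="session")
def flat_sheet():
    return make_lipid_sheet(12, 12, spacing=4.0, z0=20.0)


@pytest.fixture(scope="session")
def gate_traj_small():
    return make_gate_trajectory(400, p_open=0.4, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
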