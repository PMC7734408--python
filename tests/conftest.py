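import numpy as np
import pytest

from isoanammox.io import read_reactor_train
from isoanammox.open_system import packaged_plant_train_path
from isoanammox.synthetic_data import experiment_a_like, generate_incubation


@pytest.fixture(scope="session")
def plant_train():
    """Packaged plant reactor train as a name->ReactorState dict."""
    return {r.name: r for r in read_reactor_train(packaged_plant_train_path())}


@pytest.fixture(scope="session")
def nt_anx(plant_train):
    return plant_train["NT"], plant_train["ANX"]


@pytest.fixture(scope="session")
def expA_noiseless():
    """Noiseless Experiment-A-like incubation (spec + series)."""
    spec = experiment_a_like(noise=False)
    return spec, generate_incubation(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20200131)
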