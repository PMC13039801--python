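import numpy as np
import pytest

from alfpot import MolecularGPR, label_configs, make_toy, sample_configs


@pytest.fixture(scope="session")
def chain5():
    return make_toy("chain5")


@pytest.fixture(scope="session")
def chain5_data(chain5):
    """Labeled chain5 configurations sampled on the toy surface."""
    g0, pes = chain5
    geoms = sample_configs(pes, g0, 160, T_eff=800, seed=1, stride=60)
    return label_configs(pes, geoms, seed=2)


@pytest.fixture(scope="session")
def chain5_fit(chain5_data):
    """A quick (non-optimized) MF5 fit used by force/serialization tests."""
    model = MolecularGPR(chain5_data[:120], mean_function="MF5")
    return model.fit(sigma_n2=1e-8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
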