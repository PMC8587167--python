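import numpy as np
import pytest

from setschenow.synthetic import make_paper_like_truth, simulate_experiment


@pytest.fixture(scope="session")
def cinnamic_truth():
    return make_paper_like_truth("hydroxycinnamic", seed=11)


@pytest.fixture(scope="session")
def benzoic_truth():
    return make_paper_like_truth("hydroxybenzoic", seed=11)


@pytest.fixture(scope="session")
def noiseless_dataset(cinnamic_truth):
    return simulate_experiment(
        cinnamic_truth, noise_rel=0.0, n_rep=1, seed=11, quantize=False
    )


@pytest.fixture(scope="session")
def noisy_dataset(cinnamic_truth):
    return simulate_experiment(cinnamic_truth, noise_rel=0.02, n_rep=3, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
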