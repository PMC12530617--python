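import numpy as np
import pytest

from moldiff import build_vocabulary, schedule_for_vocab, smiles_to_graph
from moldiff.noise import schedule_from_steps


@pytest.fixture(scope="session")
def vocab():
    # C/O chemistry with a negative charge in the corpus
    return build_vocabulary(["CCO", "CC(=O)[O-]", "C1CC1"])


@pytest.fixture(scope="session")
def schedule(vocab):
    return schedule_for_vocab(vocab, T=10)


@pytest.fixture()
def ethanol(vocab):
    return smiles_to_graph("CCO", vocab, 5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_schedule(rng, K: int, T: int):
    """A valid random (alpha, beta, gamma) schedule for oracle sweeps."""
    gamma = np.concatenate([[0.0], rng.uniform(0.05, 0.6, size=T)])
    uniform = np.concatenate([[0.0], rng.uniform(0.0, 0.3, size=T)]) * (1 - gamma)
    alpha = 1.0 - gamma - uniform
    return schedule_from_steps({"A": K, "C": K, "E": K}, alpha, uniform, gamma)
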