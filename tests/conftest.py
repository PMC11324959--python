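import numpy as np
import pytest

from striatonet.connectome import build_network
from striatonet.geometry import generate_synthetic_striatum


@pytest.fixture(scope="session")
def small_table():
    """80-neuron density-matched cloud (fast fixture for network tests)."""
    return generate_synthetic_striatum(80, seed=11)


@pytest.fixture(scope="session")
def small_net(small_table):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_network(small_table, k_msn=6, k_fs=20, seed=3)


def random_digraph(n: int, p: float, seed: int):
    """Random directed simple graph as a dense 0/1 array (test oracle input)."""
    rng = np.random.default_rng(seed)
    A = (rng.random((n, n)) < p).astype(int)
    np.fill_diagonal(A, 0)
    return A
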