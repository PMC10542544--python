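import numpy as np
import pytest

from velogrn.synthetic import make_benchmark, simulate_cells, simulate_truth


@pytest.fixture(scope="session")
def tiny_benchmark():
    """One simulated tiny experiment shared across read-only tests."""
    return make_benchmark("tiny", seed=0)


@pytest.fixture(scope="session")
def dense_simulation():
    """Noise-light, densely sampled kinetics for velocity/decay oracles."""
    truth, kin = simulate_truth(3, 20, seed=7)
    exp = simulate_cells(truth, kin, n=500, depth=5e4, seed=8)
    return exp


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
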