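import numpy as np
import pytest

from tssmotif.synthetic_data import SimulationParams, generate_genome, simulate_libraries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_simulation():
    """A 60-gene simulated dataset shared by read-only tests."""
    params = SimulationParams(n_genes=60, seed=901)
    genome, genes, truth = generate_genome(params)
    tap_plus, tap_minus = simulate_libraries(truth, genome, params)
    return params, genome, genes, truth, tap_plus, tap_minus
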