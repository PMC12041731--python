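import numpy as np
import pytest

from twinnet import GeneratorConfig, generate_pairs, make_chain_precision


def chain_data(rng, p, n, edge_weight, boost=1.0):
    """Draw n iid rows from the Gaussian with a chain-graph precision."""
    theta = make_chain_precision(p, edge_weight, boost)
    chol = np.linalg.cholesky(np.linalg.inv(theta))
    return rng.standard_normal((n, p)) @ chol.T, theta


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_twin_table():
    """40 pairs per stratum, 8 chain variables, correlated co-twins."""
    config = GeneratorConfig(
        p=8,
        n_pairs={("F", "MZ"): 40, ("F", "DZ"): 40,
                 ("M", "MZ"): 40, ("M", "DZ"): 40},
        h2=0.6, c2=0.2, seed=11)
    return generate_pairs(config)
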