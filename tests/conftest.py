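import numpy as np
import pandas as pd
import pytest

from cispqtl.simulate import SimTruth, simulate_genotypes, simulate_protein_trait


@pytest.fixture(scope="session")
def small_genotypes():
    """A modest LD-structured region shared across fast unit tests."""
    return simulate_genotypes(800, 120, rho=0.8, block_size=20, seed=11)


@pytest.fixture(scope="session")
def single_causal_region():
    """Region + trait with one strong causal variant and its truth."""
    G = simulate_genotypes(1500, 150, rho=0.8, block_size=20, seed=21)
    causal = 70
    truth = SimTruth({"p": [causal]}, {"p": [1.0]}, {"p": 0.3})
    y, realized = simulate_protein_trait(G, truth, seed=22, trait="p")
    return G, y, causal, realized


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def covariate_table():
    rng = np.random.default_rng(7)
    n = 400
    return pd.DataFrame(
        {
            "age": rng.uniform(40, 75, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "plate": [f"plate{p}" for p in rng.integers(0, 3, n)],
        }
    )
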