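import numpy as np
import pytest

from projack.io import load_psoriasis_table


@pytest.fixture(scope="session")
def psoriasis():
    return load_psoriasis_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def collect_delta_hats(mu, n, K, n_partitions, n_sims, seed, rho=0.0):
    """Per-simulation rank-ordered projack estimates, one row per matrix."""
    import projack as pj

    g = np.random.default_rng(seed)
    out = np.empty((n_sims, mu.size))
    for s in range(n_sims):
        C = pj.simulate_pseudo_matrix(mu, n, rho, g)
        out[s] = pj.projack(C, K=K, n_partitions=n_partitions, seed=g).delta_hat
    return out
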