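import numpy as np
import pytest

import likertnet as ln
from likertnet.community import Partition


def random_symmetric(n, rng):
    W = rng.random((n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return W


@pytest.fixture(scope="session")
def four_block_partition():
    labels = [f"item_{i + 1:02d}" for i in range(75)]
    ids = np.repeat([1, 2, 3, 4], [19, 19, 19, 18])
    return Partition.from_ids(labels, ids, algorithm="planted")


@pytest.fixture(scope="session")
def small_config():
    """A fast 3-condition generator config for smoke/determinism tests."""
    return ln.SyntheticConfig(n_items=20, n_participants_per_condition=60,
                              n_conditions=3, within_block_corr=0.55,
                              between_block_corr=0.1, seed=123)


@pytest.fixture(scope="session")
def default_tables():
    """Study-sized tables from the generator defaults (3 x ~160-172 x 75)."""
    tables, planted = ln.generate_ratings(ln.SyntheticConfig(seed=2024))
    return tables, planted


@pytest.fixture(scope="session")
def default_networks(default_tables):
    tables, _ = default_tables
    sims = {c: ln.cosine_similarity_matrix(t) for c, t in tables.items()}
    nets = {c: ln.binarize_network(ln.tmfg_filter(s)) for c, s in sims.items()}
    return sims, nets
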