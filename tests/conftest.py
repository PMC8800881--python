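import numpy as np
import pytest

import mokkenpy as mp


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def unidim_data():
    """Strongly unidimensional nonclustered sample (N=400, J=5)."""
    spec = mp.default_spec(n_groups=400, group_size=1, icc=0.0, n_items=5,
                           discrimination=2.0)
    matrix, _ = mp.simulate(spec, seed=101)
    return matrix


@pytest.fixture(scope="session")
def clustered_data():
    """Clustered sample with substantial within-group dependency."""
    spec = mp.default_spec(n_groups=30, group_size=20, icc=0.3, n_items=5)
    return mp.simulate(spec, seed=202)


def random_score_matrix(rng, n=None, j=None, max_cat=None):
    """A random nondegenerate integer score matrix."""
    n = n or int(rng.integers(10, 60))
    j = j or int(rng.integers(3, 7))
    max_cat = max_cat or int(rng.integers(1, 5))
    while True:
        scores = rng.integers(0, max_cat + 1, size=(n, j))
        if (scores.std(axis=0) > 0).all():
            return scores
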