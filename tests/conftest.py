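import numpy as np
import pytest

import ltmclust as L
from ltmclust.synthetic import random_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    """3 x 2 matrix with prevalences 2/3 and 1/3."""
    return L.SymptomMatrix(np.array([[1, 0], [0, 0], [1, 1]]), ["a", "b"])


@pytest.fixture
def small_model(rng):
    """A random 2-latent, 5-manifest tree small enough for the oracle."""
    return random_model(rng, n_latents=2, n_manifests=5)


@pytest.fixture
def one_block_model():
    """Planted single 2-state latent over 4 leaves, loading 0.6."""
    spec = L.independent_blocks_spec(1, 4, strength=0.6, n_records=100, seed=0)
    return L.make_planted_model(spec)
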