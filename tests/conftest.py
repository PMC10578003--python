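import numpy as np
import pytest

from chromaccess import synthio
from chromaccess.nn import LinearLogitModel


@pytest.fixture(scope="session")
def small_spec():
    """A miniature genome spec used across unit tests (fast to generate)."""
    return synthio.SyntheticGenomeSpec(n_chromosomes=3, chrom_length=200_000, seed=7)


@pytest.fixture(scope="session")
def small_genome(small_spec):
    return synthio.generate_genome(small_spec)


def random_onehot(rng, L, n=None):
    """Random one-hot sequence(s) of length L."""
    if n is None:
        codes = rng.integers(0, 4, L)
        x = np.zeros((4, L), dtype=np.uint8)
        x[codes, np.arange(L)] = 1
        return x
    codes = rng.integers(0, 4, (n, L))
    x = np.zeros((n, 4, L), dtype=np.uint8)
    x[np.arange(n)[:, None], codes, np.arange(L)[None, :]] = 1
    return x


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_linear_model(rng, L=50, tissues=("head", "testis"), scale=1.0):
    w = rng.normal(0, scale, size=(len(tissues), 4, L))
    b = rng.normal(0, 0.5, size=len(tissues))
    return LinearLogitModel(w, b, tissues=tissues)
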