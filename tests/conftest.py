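import numpy as np
import pytest

from phagraph import KmerEmbedding


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_embedding():
    """A small deterministic embedding table shared across encoder tests."""
    rng = np.random.default_rng(7)
    table = rng.normal(0, 0.1, size=(64, 8)).astype(np.float32)
    return KmerEmbedding(k=3, dim=8, m=2, table=table)


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))
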