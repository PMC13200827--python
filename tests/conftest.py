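import numpy as np
import pytest

from gradescape.signatures import toy_signatures
from gradescape.synthetic import make_reference


@pytest.fixture(scope="session")
def sigs():
    return toy_signatures()


@pytest.fixture(scope="session")
def genome():
    """A small deterministic genome shared across tests (2 x 50 kb, 100 genes)."""
    return make_reference(seed=1, n_chroms=2, chrom_length=50_000, n_genes=100)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
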