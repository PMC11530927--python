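import numpy as np
import pytest

from novolign.error_sim import ALPHABET
from novolign.fixtures import make_community, tryptic_digest


@pytest.fixture(scope="session")
def small_community():
    """3 families x 2 species, 12 proteins each; deterministic."""
    return make_community(3, 2, n_proteins=12, seed=7)


@pytest.fixture(scope="session")
def tryptic_pool(small_community):
    pool = []
    for _, seq, _ in small_community.proteins:
        pool.extend(tryptic_digest(seq, min_len=7, max_len=30))
    return pool


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_peptides(rng, n, min_len=7, max_len=25):
    letters = np.array(list(ALPHABET))
    out = []
    for _ in range(n):
        ln = int(rng.integers(min_len, max_len + 1))
        out.append("".join(letters[rng.integers(0, len(letters), ln)]))
    return out
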