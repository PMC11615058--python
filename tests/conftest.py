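import numpy as np
import pytest

from hicstage import synthetic as syn
from hicstage.genome import BinnedGenome
from hicstage.matrix import ContactMatrix


@pytest.fixture(scope="session")
def small_truth():
    """300-bin single-chromosome truth with plaid, TADs and coverage bias."""
    return syn.make_truth(n_bins=300, n_tads=6, n_peis=5, seed=11)


@pytest.fixture(scope="session")
def small_matrix(small_truth):
    return syn.simulate_matrix(small_truth, seed=21)


@pytest.fixture(scope="session")
def balanced_matrix(small_matrix):
    from hicstage.normalization import kr_normalize

    b, _ = kr_normalize(small_matrix)
    return b


@pytest.fixture()
def tiny_genome():
    return BinnedGenome({"chr1": 100_000, "chr2": 60_000}, 10_000)


def random_symmetric_matrix(n: int, seed: int, zeros: int = 0) -> np.ndarray:
    """Random positive symmetric matrix with optional planted zero pairs."""
    rng = np.random.default_rng(seed)
    m = rng.uniform(1.0, 10.0, size=(n, n))
    m = np.triu(m, 1)
    m = m + m.T
    if zeros:
        idx = rng.integers(0, n, size=(zeros, 2))
        for i, j in idx:
            if i != j:
                m[i, j] = m[j, i] = 0.0
    return m


def as_contact_matrix(dense: np.ndarray, bin_size: int = 20_000
                      ) -> ContactMatrix:
    g = BinnedGenome({"chr1": dense.shape[0] * bin_size}, bin_size)
    return ContactMatrix.from_dense(g, dense, raw=False)
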