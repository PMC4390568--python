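import numpy as np
import pytest

from hapsweep.genotypes import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_matrix(dosage, populations=None, chrom=None, pos=None):
    """Small GenotypeMatrix from a plain dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, s = dosage.shape
    if populations is None:
        populations = ["lineA"] * (n // 2) + ["lineB"] * (n - n // 2)
    if chrom is None:
        chrom = ["chr1"] * s
    if pos is None:
        pos = 1000 * (np.arange(s) + 1)
    return GenotypeMatrix(
        individuals=np.array([f"ind{i}" for i in range(n)], dtype=object),
        populations=np.array(populations, dtype=object),
        chrom=np.array(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * s, dtype=object),
        alt=np.array(["G"] * s, dtype=object),
        dosage=dosage,
    )


@pytest.fixture
def toy_matrix():
    return make_matrix(
        [[0, 1, 2, 0, 1],
         [1, 1, 2, 0, 0],
         [2, 0, 2, 1, 1],
         [0, 2, 2, 1, 0]],
    )
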