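import numpy as np
import pytest

from boostfilter.io import GenotypeMatrix, Phenotype


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_panel(rng):
    """60 HWE SNPs x 300 subjects, no phenotype association."""
    maf = rng.uniform(0.1, 0.5, 60)
    dos = rng.binomial(2, maf, size=(300, 60)).astype(float)
    return GenotypeMatrix(dos, [f"s{j}" for j in range(60)], ["1"] * 60,
                          np.arange(1, 61))


@pytest.fixture
def null_phenotype(rng, small_panel):
    return Phenotype(rng.normal(size=small_panel.n_subjects))


def make_matrix(dosages, chrom=None, pos=None):
    dosages = np.asarray(dosages, dtype=float)
    p = dosages.shape[1]
    return GenotypeMatrix(dosages, [f"s{j}" for j in range(p)],
                          chrom if chrom is not None else ["1"] * p,
                          pos if pos is not None else np.arange(1, p + 1))
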