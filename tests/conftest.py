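import numpy as np
import pytest

from slabgwas.genotype_io import GenotypeMatrix, MISSING, VariantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_genotype_matrix(dosages: np.ndarray, chromosomes=None) -> GenotypeMatrix:
    """Wrap a dosage array in a GenotypeMatrix with synthetic metadata."""
    n, m = dosages.shape
    if chromosomes is None:
        chromosomes = ["1"] * m
    variants = [
        VariantRecord(
            chromosome=str(chromosomes[j]),
            identifier=f"v{j}",
            position=j + 1,
            allele1="A",
            allele2="G",
        )
        for j in range(m)
    ]
    samples = [(f"F{i}", f"I{i}") for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


@pytest.fixture
def random_genotypes(rng):
    """3 x 7 genotype matrix including missing entries."""
    d = rng.integers(0, 3, size=(3, 7)).astype(np.int8)
    d[0, 2] = MISSING
    d[2, 5] = MISSING
    return make_genotype_matrix(d)
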