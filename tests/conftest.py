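import numpy as np
import pytest

from ataxmap.genotypes import GenotypeMatrix, MarkerMap
from ataxmap.pedigree import Pedigree, PedigreeEntry
from ataxmap.sim import make_toy_transcript


@pytest.fixture(scope="session")
def toy_gene():
    return make_toy_transcript()


@pytest.fixture
def nuclear_pedigree():
    """Sire + dam, two full sibs, and an offspring of the full sibs."""
    return Pedigree(
        [
            PedigreeEntry("s", None, None, "M", 0),
            PedigreeEntry("d", None, None, "F", 0),
            PedigreeEntry("c1", "s", "d", "M", 1),
            PedigreeEntry("c2", "s", "d", "F", 1),
            PedigreeEntry("g", "c1", "c2", "M", 2),
        ]
    )


def make_genotypes(codes, positions=None, chrom="chr1", samples=None):
    codes = np.asarray(codes, dtype=np.int8)
    n_samples, n_markers = codes.shape
    if positions is None:
        positions = np.arange(1, n_markers + 1) * 100_000
    markers = MarkerMap(
        ids=[f"m{i}" for i in range(n_markers)],
        chroms=np.array([chrom] * n_markers, dtype=object),
        positions=np.asarray(positions),
    )
    samples = samples or [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(samples=samples, markers=markers, codes=codes)


@pytest.fixture
def genotype_factory():
    return make_genotypes
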