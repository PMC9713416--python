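import numpy as np
import pytest

from recombreed import generate_founders
from recombreed.genmap import GeneticMap, make_chromosome


@pytest.fixture(scope="session")
def founders_small():
    """26 inbred founders on 5 chromosomes, the reduced desk scale."""
    return generate_founders(n_founders=26, n_chrom=5, mean_length=1.22,
                             snp_density=600, coupling_target=0.33, seed=11)


@pytest.fixture(scope="session")
def founders_tiny():
    """A very small panel for cheap structural tests."""
    return generate_founders(n_founders=8, n_chrom=2, mean_length=1.0,
                             snp_density=80, coupling_target=0.4, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def uniform_map():
    """Single 1.22 M chromosome with 100 evenly spaced loci."""
    pos = np.linspace(0.01, 1.21, 100)
    return GeneticMap([make_chromosome(pos, length=1.22, name="chr1")])
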