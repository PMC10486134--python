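import numpy as np
import pytest

from qbvgenomics.genome_io import Genome
from qbvgenomics.synthetic_data import generate_reference

# small, fast genome geometry reused across tests: 3 regions, 1,203-nt ORF
SMALL_KW = dict(
    utr5_len=40,
    cds_len=1203,
    utr3_len=60,
    region_lengths=(300, 600, 300),
    region_names=("R1", "R2", "R3"),
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_reference():
    """A 1,303-nt genome with a clean 1,203-nt ORF and 3-region partition."""
    return generate_reference(seed=11, **SMALL_KW)


@pytest.fixture
def random_genome(rng):
    def make(n=500, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        return Genome(id=f"g{n}", sequence="".join(r.choice(list("ACGT"), n)))

    return make
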