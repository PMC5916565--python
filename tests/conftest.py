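import numpy as np
import pytest

from hsnsig import default_models
from hsnsig.motifs import RegulatoryRegion
from hsnsig.simulate import GenomeSimSpec, simulate_genome


@pytest.fixture(scope="session")
def models():
    return default_models()


@pytest.fixture(scope="session")
def small_genome():
    """A 150-gene planted genome shared by read-only tests."""
    return simulate_genome(GenomeSimSpec(n_genes=150, seed=11))


def random_region(rng: np.random.Generator, length: int,
                  region_id: str = "r", gene_id: str = "g") -> RegulatoryRegion:
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    return RegulatoryRegion(region_id, gene_id, "upstream", seq)
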