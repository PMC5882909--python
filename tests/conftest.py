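import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from camtakit.evolution import SENSE_CODONS
from camtakit.synthetic import SimConfig, gen_annotated_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bundle():
    """Small synthetic genome bundle shared across tests."""
    cfg = SimConfig(seed=11, n_genes=8, chrom_length=200_000,
                    n_camta=3, n_non_tig=1)
    return gen_annotated_genome(cfg)


def random_codon_pairs(rng, n_codons):
    """A random gap-free sense-codon alignment."""
    idx_a = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    pairs = []
    for i in idx_a:
        a = SENSE_CODONS[i]
        if rng.random() < 0.5:
            b = a
        else:
            b = SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))]
        pairs.append((a, b))
    return pairs
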