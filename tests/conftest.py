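import numpy as np
import pytest

from agios.seqio import GeneSet, SequenceRecord
from agios.simulate import SENSE_CODONS


@pytest.fixture
def rng():
    return np.random.default_rng(20240401)


def random_cds(rng, n_codons: int) -> str:
    """Random stop-free CDS, uniform over sense codons."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def random_gene_set(rng, label: str, n_genes: int = 10, n_codons: int = 60) -> GeneSet:
    genes = [
        SequenceRecord(f"{label}_g{i:03d}", random_cds(rng, n_codons))
        for i in range(n_genes)
    ]
    return GeneSet(genome_label=label, genes=genes)


@pytest.fixture
def small_gene_set(rng):
    return random_gene_set(rng, "X", n_genes=8, n_codons=50)
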