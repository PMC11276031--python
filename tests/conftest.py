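import io

import pytest

from cubkit.codon_metrics import CodonCountTable, count_codons, pool_counts
from cubkit.sequence_io import GeneRecord
from cubkit.synthetic_cds import GenomeSpec, generate_genome


def make_gene(gid: str, interior: str) -> GeneRecord:
    """A valid gene record: AUG + interior codons + UAA."""
    return GeneRecord(gid, "AUG" + interior + "UAA")


@pytest.fixture
def toy_gene() -> GeneRecord:
    # Phe x4 biased 3:1, Ala x4 split evenly between GCU/GCA
    return make_gene("toy", "UUU" * 3 + "UUC" + "GCU" * 2 + "GCA" * 2)


@pytest.fixture
def uniform_counts() -> CodonCountTable:
    """Exactly uniform usage: every sense codon 5 times."""
    from cubkit.genetics import SENSE_CODONS

    return CodonCountTable({c: 5 for c in SENSE_CODONS})


@pytest.fixture(scope="session")
def uniform_genome():
    """200 genes with uniform synonymous usage, seeded."""
    genes, truth = generate_genome(
        GenomeSpec(n_genes=200, min_codons=500, max_codons=502), seed=3
    )
    return genes, truth


@pytest.fixture(scope="session")
def uniform_genome_pooled(uniform_genome):
    genes, _ = uniform_genome
    return pool_counts(count_codons(g) for g in genes)


def fasta_io(text: str) -> io.StringIO:
    return io.StringIO(text)
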