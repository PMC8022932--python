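import pytest

from screenvar.reference_io import GeneModel, GenomeSequence
from screenvar.synthetic_cohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_sim():
    """Desk-scale default cohort: 15 lines, 50 universal background, 10
    recurrent decoys, synonymous decoys, 20% filter-failing fraction."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """Compact cohort for quick stage tests."""
    return simulate_cohort(
        SimulationConfig(
            seed=7, n_lines=4, genome_length=40_000, n_genes=8,
            n_background_universal=10, n_recurrent_decoys=2,
            n_private_per_line=40, n_synonymous_decoys_per_line=2,
        )
    )


@pytest.fixture
def toy_genome():
    """60 bp contig holding one 30 bp plus-strand ORF (positions 21-50):
    ATG + 8 codons + TAA, flanked by padding."""
    cds = "ATG" + "GCTTGGAAACCTGACGAATTAGCA"[:24] + "TAA"
    assert len(cds) == 30
    seq = "A" * 20 + cds + "C" * 10
    return GenomeSequence({"chr1": seq})


@pytest.fixture
def toy_gene():
    return GeneModel(
        gene_id="G1", contig="chr1", strand="+",
        cds_segments=[(21, 50)], utr5_segments=[(15, 20)],
        utr3_segments=[(51, 56)],
    )
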