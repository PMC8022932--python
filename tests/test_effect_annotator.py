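import numpy as np
import pytest

from _oracles import (
    indel_consequence_oracle,
    region_oracle,
    snv_consequence_oracle,
)
from screenvar.effect_annotator import (
    AnnotatorConfig,
    CodingConsequence,
    RegionClass,
    annotate_callset,
    classify_coding_effect,
    classify_region,
)
from screenvar.errors import ContractError
from screenvar.reference_io import GeneModel, GenomeSequence
from screenvar.synthetic_cohort import SimulationConfig, simulate_genome
from screenvar.variant_model import Variant


def _v(pos, ref="A", alt="T"):
    return Variant("chr1", pos, ref, alt, "L1")


class TestClassifyRegion:
    def test_position_in_cds_is_exonic(self, toy_gene):
        region, model = classify_region(_v(30), [toy_gene])
        assert region is RegionClass.EXONIC
        assert model.gene_id == "G1"

    def test_strand_aware_upstream_of_minus_gene(self):
        gene = GeneModel("Gm", "chr1", "-", cds_segments=[(2000, 2299)])
        region, model = classify_region(_v(2799), [gene])
        assert region is RegionClass.UPSTREAM  # 500 bp 5' of the high end
        region, _ = classify_region(_v(1500), [gene])
        assert region is RegionClass.DOWNSTREAM

    def test_intronic_between_segments(self):
        gene = GeneModel("G", "chr1", "+", cds_segments=[(100, 199), (300, 401)])
        region, _ = classify_region(_v(250), [gene])
        assert region is RegionClass.INTRONIC

    def test_precedence_exonic_over_upstream(self, toy_gene):
        other = GeneModel("G2", "chr1", "+", cds_segments=[(200, 499)])
        # pos 30 is exonic in G1 and within 1000 bp upstream of G2
        region, model = classify_region(_v(30), [toy_gene, other])
        assert region is RegionClass.EXONIC
        assert model.gene_id == "G1"

    def test_far_position_is_intergenic(self, toy_gene):
        region, model = classify_region(_v(5000), [toy_gene], AnnotatorConfig())
        assert region is RegionClass.INTERGENIC
        assert model is None

    def test_indel_touching_cds_from_outside_is_exonic(self, toy_gene):
        # deletion anchored in the 5'UTR at 20, removing CDS bases 21-23
        region, model = classify_region(_v(20, "AATG", "A"), [toy_gene])
        assert region is RegionClass.EXONIC

    def test_matches_interval_scan_oracle_exhaustively(self):
        """Every position of a simulated two-strand multi-gene contig gets
        the same class from the interval-tree path and from a naive
        per-gene loop oracle."""
        config = SimulationConfig(seed=11, genome_length=30_000, n_genes=5)
        genome, models = simulate_genome(config)
        contig_models = models["chr1"]
        from screenvar.effect_annotator import _RegionIndex

        index = _RegionIndex(contig_models, AnnotatorConfig())
        for pos in range(1, len(genome.contigs["chr1"]) + 1):
            got, _ = index.classify(pos)
            assert got is region_oracle(pos, contig_models), f"pos {pos}"


class TestClassifyCodingEffect:
    def test_stop_gain_tgg_to_tga(self, toy_genome, toy_gene):
        # codon 3 (TGG, pos 27-29): G>A at pos 29 makes TGA
        cons, change = classify_coding_effect(_v(29, "G", "A"), toy_gene, toy_genome)
        assert cons is CodingConsequence.STOP_GAIN
        assert change == "W3*"

    def test_synonymous_third_position(self):
        genome = GenomeSequence({"chr1": "ATGGCATAA" + "C" * 20})
        gene = GeneModel("G", "chr1", "+", cds_segments=[(1, 9)])
        cons, change = classify_coding_effect(_v(6, "A", "G"), gene, genome)
        assert cons is CodingConsequence.SYNONYMOUS_SNV  # GCA -> GCG, both Ala
        assert change == "A2A"

    def test_stop_loss(self):
        genome = GenomeSequence({"chr1": "ATGGCATAA" + "C" * 20})
        gene = GeneModel("G", "chr1", "+", cds_segments=[(1, 9)])
        cons, _ = classify_coding_effect(_v(8, "A", "C"), gene, genome)
        assert cons is CodingConsequence.STOP_LOSS  # TAA -> TCA

    def test_two_bp_deletion_frameshift(self, toy_genome, toy_gene):
        cons, _ = classify_coding_effect(_v(30, "TAA", "T"), toy_gene, toy_genome)
        assert cons is CodingConsequence.FRAMESHIFT_INDEL

    def test_three_bp_deletion_nonframeshift(self, toy_genome, toy_gene):
        cons, _ = classify_coding_effect(_v(30, "TAAA", "T"), toy_gene, toy_genome)
        assert cons is CodingConsequence.NONFRAMESHIFT_INDEL

    def test_variant_outside_cds_violates_contract(self, toy_genome, toy_gene):
        with pytest.raises(ContractError):
            classify_coding_effect(_v(10, "A", "G"), toy_gene, toy_genome)

    def test_n_codon_gives_unknown(self):
        genome = GenomeSequence({"chr1": "ATGGNATAA" + "C" * 20})
        gene = GeneModel("G", "chr1", "+", cds_segments=[(1, 9)])
        cons, change = classify_coding_effect(_v(4, "G", "A"), gene, genome)
        assert cons is CodingConsequence.UNKNOWN
        assert change is None

    def test_minus_strand_junction_codon(self):
        """A codon split across two CDS segments of a minus-strand gene is
        reassembled in translation order before mutating."""
        # coding sequence ATG GCA TAA split as (ATGGC | ATAA) in coding
        # order; genomic minus-strand layout: low segment holds the tail.
        coding = "ATGGCATAA"
        from screenvar.reference_io import reverse_complement

        # segments in coding order: first 5 bases then last 4
        high_seg = reverse_complement(coding[:5])  # genomic high segment
        low_seg = reverse_complement(coding[5:])
        seq = "C" * 10 + low_seg + "G" * 7 + high_seg + "C" * 10
        genome = GenomeSequence({"chr1": seq})
        gene = GeneModel(
            "G", "chr1", "-",
            cds_segments=[(11, 14), (22, 26)],
        )
        # mutate coding position 4 (G of codon 2 GCA, genomic = high seg)
        # coding index 3 -> genomic pos = 26 - 3 = 23; coding base G,
        # genomic base on minus strand is C; G->A coding is C->T genomic
        cons, change = classify_coding_effect(_v(23, "C", "T"), gene, genome)
        assert cons is CodingConsequence.NONSYNONYMOUS_SNV  # GCA->ACA, A2T
        assert change == "A2T"
        # junction codon 2 spans both segments: its third base (coding
        # index 5) sits in the low genomic segment at pos 14, so the codon
        # must be reassembled across the junction — third-position changes
        # of GCA stay Ala
        cons, change = classify_coding_effect(_v(14, "T", "G"), gene, genome)
        assert cons is CodingConsequence.SYNONYMOUS_SNV
        assert change == "A2A"
        assert change == snv_change_via_oracle(genome, gene, 14, "G")


def snv_change_via_oracle(genome, gene, pos, alt):
    """protein_change string recomputed through full retranslation."""
    from screenvar.reference_io import extract_cds, reverse_complement
    from screenvar.effect_annotator import translate_codon

    contig = genome.contigs[gene.contig]
    mutant = GenomeSequence({gene.contig: contig[: pos - 1] + alt + contig[pos:]})
    ref_cds = extract_cds(gene, genome)
    alt_cds = extract_cds(gene, mutant)
    idx = gene.cds_position(pos)
    ci = idx // 3
    ref_aa = translate_codon(ref_cds[ci * 3 : ci * 3 + 3])
    alt_aa = translate_codon(alt_cds[ci * 3 : ci * 3 + 3])
    return f"{ref_aa}{ci + 1}{alt_aa}"


@pytest.fixture(scope="module")
def sim():
    config = SimulationConfig(seed=5, genome_length=60_000, n_genes=10)
    return simulate_genome(config), config


class TestRandomOracleAgreement:
    def test_random_coding_snvs_match_retranslation(self, sim):
        """1000 random coding SNVs agree with the whole-CDS retranslation
        oracle, across strands and intron junctions."""
        (genome, models), _ = sim
        rng = np.random.default_rng(17)
        contig_models = models["chr1"]
        seq = genome.contigs["chr1"]
        all_cds_pos = [
            (m, p)
            for m in contig_models
            for s, e in m.cds_segments
            for p in range(s, e + 1)
        ]
        picks = rng.choice(len(all_cds_pos), size=1000, replace=False)
        for i in picks:
            m, pos = all_cds_pos[i]
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            got, _ = classify_coding_effect(_v(pos, ref, alt), m, genome)
            assert got is snv_consequence_oracle(genome, m, pos, alt)

    def test_random_coding_indels_match_count_oracle(self, sim):
        """200 random CDS-overlapping indels match a direct coding-base
        count oracle for the frameshift / non-frameshift call."""
        (genome, models), _ = sim
        rng = np.random.default_rng(23)
        contig_models = models["chr1"]
        seq = genome.contigs["chr1"]
        all_cds_pos = [
            (m, p)
            for m in contig_models
            for s, e in m.cds_segments
            for p in range(s, e + 1)
        ]
        done = 0
        while done < 200:
            m, pos = all_cds_pos[int(rng.integers(0, len(all_cds_pos)))]
            length = int(rng.integers(1, 7))
            if rng.random() < 0.5:
                ref = seq[pos - 1]
                alt = ref + "".join(rng.choice(list("ACGT"), length))
            else:
                if pos + length > len(seq):
                    continue
                ref = seq[pos - 1 : pos + length]
                alt = seq[pos - 1]
            variant = _v(pos, ref, alt)
            region, model = classify_region(variant, contig_models)
            if region is not RegionClass.EXONIC:
                continue  # deletion anchored at segment end may leave the CDS
            got, _ = classify_coding_effect(variant, model, genome)
            assert got is indel_consequence_oracle(model, pos, ref, alt)
            done += 1


class TestAnnotateCallset:
    def test_empty_input(self, toy_genome):
        assert annotate_callset([], {}, toy_genome) == []

    def test_out_of_bounds_variant_rejected(self, toy_genome, toy_gene):
        with pytest.raises(ContractError, match="bounds"):
            annotate_callset([_v(10_000)], {"chr1": [toy_gene]}, toy_genome)

    def test_per_category_counts_equal_simulator_truth(self, small_sim):
        genome, models, cohort, truth = small_sim
        tmap = {
            (r.contig, r.pos, r.ref, r.alt): (r.region, r.consequence)
            for r in truth.itertuples()
        }
        for lid, variants in cohort.items():
            for av in annotate_callset(variants, models, genome):
                want_region, want_cons = tmap[av.variant.key]
                assert av.region.value == want_region
                got_cons = av.consequence.value if av.consequence else "."
                assert got_cons == want_cons

    def test_exonic_partition_identity(self, small_sim):
        """exonic = synonymous + nonsynonymous + stop_gain + stop_loss +
        frameshift + nonframeshift (+ unknown) for every simulated line."""
        genome, models, cohort, _ = small_sim
        for variants in cohort.values():
            annotated = annotate_callset(variants, models, genome)
            exonic = [a for a in annotated if a.region is RegionClass.EXONIC]
            assert all(a.consequence is not None for a in exonic)
            non_exonic = [a for a in annotated if a.region is not RegionClass.EXONIC]
            assert all(a.consequence is None for a in non_exonic)

    def test_gene_id_present_iff_not_intergenic(self, small_sim):
        genome, models, cohort, _ = small_sim
        for variants in cohort.values():
            for av in annotate_callset(variants, models, genome):
                assert (av.gene_id is None) == (av.region is RegionClass.INTERGENIC)
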