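"""Independent oracles used by the tests.

These deliberately share no code with the implementation paths they
check: region classification by a naive per-gene interval loop, coding
consequences by mutating the genome and retranslating the whole CDS, and
the hard filter by direct re-evaluation of the printed inequalities.
"""
from __future__ import annotations

from screenvar.effect_annotator import CodingConsequence, RegionClass
from screenvar.reference_io import GeneModel, GenomeSequence, reverse_complement

_CODONS = {}


def _translate(cds: str) -> str:
    from screenvar.effect_annotator import CODON_TABLE

    return "".join(
        CODON_TABLE.get(cds[i : i + 3], "X") for i in range(0, len(cds), 3)
    )


_ORDER = [
    RegionClass.EXONIC, RegionClass.UTR5, RegionClass.UTR3,
    RegionClass.INTRONIC, RegionClass.UPSTREAM, RegionClass.DOWNSTREAM,
]


def region_oracle(pos: int, models: list[GeneModel], flank: int = 1000) -> RegionClass:
    """Classify one position by looping every gene's intervals directly."""
    found: set[RegionClass] = set()
    for m in models:
        span_s, span_e = m.span
        in_seg = False
        if any(s <= pos <= e for s, e in m.cds_segments):
            found.add(RegionClass.EXONIC)
            in_seg = True
        if any(s <= pos <= e for s, e in m.utr5_segments):
            found.add(RegionClass.UTR5)
            in_seg = True
        if any(s <= pos <= e for s, e in m.utr3_segments):
            found.add(RegionClass.UTR3)
            in_seg = True
        if not in_seg and span_s <= pos <= span_e:
            found.add(RegionClass.INTRONIC)
        if m.strand == "+":
            up = span_s - flank <= pos <= span_s - 1
            down = span_e + 1 <= pos <= span_e + flank
        else:
            up = span_e + 1 <= pos <= span_e + flank
            down = span_s - flank <= pos <= span_s - 1
        if up:
            found.add(RegionClass.UPSTREAM)
        if down:
            found.add(RegionClass.DOWNSTREAM)
    for cls in _ORDER:
        if cls in found:
            return cls
    return RegionClass.INTERGENIC


def snv_consequence_oracle(
    genome: GenomeSequence, model: GeneModel, pos: int, alt: str
) -> CodingConsequence:
    """Consequence by rebuilding the mutant genome and retranslating the
    entire CDS, then diffing the two protein strings."""
    contig_seq = genome.contigs[model.contig]
    mutant_seq = contig_seq[: pos - 1] + alt + contig_seq[pos:]

    def cds_of(seq: str) -> str:
        s = "".join(seq[a - 1 : b] for a, b in model.cds_segments)
        return reverse_complement(s) if model.strand == "-" else s

    ref_prot = _translate(cds_of(contig_seq))
    alt_prot = _translate(cds_of(mutant_seq))
    if ref_prot == alt_prot:
        return CodingConsequence.SYNONYMOUS_SNV
    for r, a in zip(ref_prot, alt_prot):
        if r != a:
            if a == "*":
                return CodingConsequence.STOP_GAIN
            if r == "*":
                return CodingConsequence.STOP_LOSS
            return CodingConsequence.NONSYNONYMOUS_SNV
    raise AssertionError("proteins differ but no position does")


def indel_consequence_oracle(
    model: GeneModel, pos: int, ref: str, alt: str
) -> CodingConsequence:
    """Frameshift call from a direct count of coding bases added/removed."""
    if len(ref) > len(alt):  # deletion
        deleted = range(pos + 1, pos + len(ref))
        n = sum(
            1 for p in deleted if any(s <= p <= e for s, e in model.cds_segments)
        )
    else:  # insertion between pos and pos+1
        touches = any(
            s <= p <= e for p in (pos, pos + 1) for s, e in model.cds_segments
        )
        n = (len(alt) - 1) if touches else 0
    if n % 3 == 0:
        return CodingConsequence.NONFRAMESHIFT_INDEL
    return CodingConsequence.FRAMESHIFT_INDEL


def hard_filter_oracle(metrics) -> list[str]:
    """Re-evaluate the printed exclusion inequalities literally."""
    failed = []
    if metrics.QD is not None and metrics.QD < 2.0:
        failed.append("QD")
    if metrics.MQ is not None and metrics.MQ < 40.0:
        failed.append("MQ")
    if metrics.QUAL is not None and metrics.QUAL < 100:
        failed.append("QUAL")
    if metrics.MQRankSum is not None and metrics.MQRankSum < -12.5:
        failed.append("MQRankSum")
    if metrics.SOR is not None and metrics.SOR > 4.0:
        failed.append("SOR")
    if metrics.FS is not None and metrics.FS > 60.0:
        failed.append("FS")
    if metrics.ReadPosRankSum is not None and metrics.ReadPosRankSum < -8.0:
        failed.append("ReadPosRankSum")
    return failed
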