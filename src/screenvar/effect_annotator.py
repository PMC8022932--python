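"""Gene-based variant effect annotation.

Each variant gets exactly one region class from the closed taxonomy
{exonic, utr5, utr3, intronic, upstream, downstream, intergenic}; exonic
variants additionally get a codon-level coding consequence (synonymous /
nonsynonymous / stop-gain / stop-loss SNVs, frameshift / non-frameshift
indels) computed against the standard genetic code. When overlapping genes
supply conflicting region classes the highest-precedence class wins:

    exonic > utr5 > utr3 > intronic > upstream > downstream > intergenic

Upstream/downstream flanks are strand-aware windows (default 1000 bp) off
each end of the gene span. Intronic positions within 2 bp of a CDS
boundary carry an internal splice flag but are still counted as intronic
in summaries, because the report taxonomy has no splicing category.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from intervaltree import IntervalTree

from .errors import ContractError
from .reference_io import GeneModel, GenomeSequence, extract_cds, reverse_complement
from .variant_model import Variant, VariantClass

logger = logging.getLogger(__name__)

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_codon(codon: str) -> str | None:
    """Amino acid for ``codon`` ('*' for stop), or None if it contains N."""
    return CODON_TABLE.get(codon)


class RegionClass(str, Enum):
    EXONIC = "exonic"
    UTR5 = "utr5"
    UTR3 = "utr3"
    INTRONIC = "intronic"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    INTERGENIC = "intergenic"


#: precedence rank; lower wins
PRECEDENCE = {
    RegionClass.EXONIC: 0,
    RegionClass.UTR5: 1,
    RegionClass.UTR3: 2,
    RegionClass.INTRONIC: 3,
    RegionClass.UPSTREAM: 4,
    RegionClass.DOWNSTREAM: 5,
    RegionClass.INTERGENIC: 6,
}


class CodingConsequence(str, Enum):
    SYNONYMOUS_SNV = "synonymous_snv"
    NONSYNONYMOUS_SNV = "nonsynonymous_snv"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    FRAMESHIFT_INDEL = "frameshift_indel"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class AnnotatorConfig:
    flank_window: int = 1000  # bases defining upstream/downstream

    def __post_init__(self):
        if self.flank_window <= 0:
            raise ValueError("flank_window must be > 0")


@dataclass(frozen=True)
class AnnotatedVariant:
    variant: Variant
    region: RegionClass
    consequence: CodingConsequence | None = None
    gene_id: str | None = None
    protein_change: str | None = None
    splice_flag: bool = False


def affected_interval(variant: Variant) -> tuple[int, int]:
    """Genomic interval (1-based inclusive) a variant acts on.

    SNV: the substituted base. Deletion: the deleted bases (anchor base
    excluded). Insertion: the two bases flanking the insertion point.
    """
    vc = variant.vclass
    if vc is VariantClass.SNV:
        return (variant.pos, variant.pos)
    if vc is VariantClass.DELETION:
        return (variant.pos + 1, variant.pos + len(variant.ref) - 1)
    return (variant.pos, variant.pos + 1)


class _RegionIndex:
    """Interval index mapping positions to (precedence, class, gene_id)."""

    def __init__(self, models: list[GeneModel], config: AnnotatorConfig):
        self.tree = IntervalTree()
        w = config.flank_window
        for m in models:
            span_s, span_e = m.span
            for s, e in m.cds_segments:
                self._add(s, e, RegionClass.EXONIC, m)
            for s, e in m.utr5_segments:
                self._add(s, e, RegionClass.UTR5, m)
            for s, e in m.utr3_segments:
                self._add(s, e, RegionClass.UTR3, m)
            # introns: span positions not covered by any segment of this gene
            segs = sorted(m.cds_segments + m.utr5_segments + m.utr3_segments)
            for (_, e1), (s2, _) in zip(segs, segs[1:]):
                if s2 > e1 + 1:
                    self._add(e1 + 1, s2 - 1, RegionClass.INTRONIC, m)
            if m.strand == "+":
                up = (span_s - w, span_s - 1)
                down = (span_e + 1, span_e + w)
            else:
                up = (span_e + 1, span_e + w)
                down = (span_s - w, span_s - 1)
            self._add(max(1, up[0]), up[1], RegionClass.UPSTREAM, m)
            self._add(max(1, down[0]), down[1], RegionClass.DOWNSTREAM, m)

    def _add(self, start: int, end: int, cls: RegionClass, model: GeneModel) -> None:
        if end >= start:
            # IntervalTree is half-open; store [start, end] as [start, end+1)
            self.tree.addi(start, end + 1, (PRECEDENCE[cls], cls, model))

    def classify(self, pos: int) -> tuple[RegionClass, GeneModel | None]:
        hits = self.tree[pos]
        if not hits:
            return RegionClass.INTERGENIC, None
        _, cls, model = min(
            (iv.data for iv in hits),
            key=lambda d: (d[0], d[2].gene_id),
        )
        return cls, model


def classify_region(
    variant: Variant,
    models: list[GeneModel],
    config: AnnotatorConfig | None = None,
    index: _RegionIndex | None = None,
) -> tuple[RegionClass, GeneModel | None]:
    """Region class of a variant and the gene supplying it (None if intergenic).

    Indels are classified over their whole affected interval: the
    highest-precedence class of any overlapped base wins, so an indel that
    touches a CDS from outside still counts as exonic.
    """
    if index is None:
        index = _RegionIndex(models, config or AnnotatorConfig())
    lo, hi = affected_interval(variant)
    best: tuple[RegionClass, GeneModel | None] = (RegionClass.INTERGENIC, None)
    best_rank = PRECEDENCE[RegionClass.INTERGENIC]
    for pos in range(lo, hi + 1):
        cls, model = index.classify(pos)
        if PRECEDENCE[cls] < best_rank:
            best, best_rank = (cls, model), PRECEDENCE[cls]
    return best


def _splice_flag(pos: int, model: GeneModel) -> bool:
    """True when an intronic position sits within 2 bp of a CDS boundary."""
    for s, e in model.cds_segments:
        if s - 2 <= pos <= s - 1 or e + 1 <= pos <= e + 2:
            return True
    return False


def _coding_bases_changed(variant: Variant, model: GeneModel) -> int:
    """Number of coding bases an indel adds or removes."""
    if variant.vclass is VariantClass.DELETION:
        lo, hi = variant.pos + 1, variant.pos + len(variant.ref) - 1
        n = 0
        for s, e in model.cds_segments:
            n += max(0, min(hi, e) - max(lo, s) + 1)
        return n
    # insertion: the inserted bases are coding when the insertion point
    # touches the CDS on either side
    in_cds = any(
        s <= p <= e
        for p in (variant.pos, variant.pos + 1)
        for s, e in model.cds_segments
    )
    return len(variant.alt) - 1 if in_cds else 0


def classify_coding_effect(
    variant: Variant, model: GeneModel, genome: GenomeSequence
) -> tuple[CodingConsequence, str | None]:
    """Codon-level consequence of an exonic variant on one gene.

    SNVs mutate the affected codon and compare translations; indels are
    frameshift when the coding-base change is not a multiple of 3. Returns
    (consequence, protein_change); protein_change is refAA + codon index
    (1-based) + altAA for SNVs, None for indels. Codons containing N give
    ``unknown``. Raises :class:`ContractError` when the variant does not
    touch the model's CDS.
    """
    if not model.coding_valid:
        return CodingConsequence.UNKNOWN, None
    if variant.vclass is not VariantClass.SNV:
        n = _coding_bases_changed(variant, model)
        if n == 0:
            raise ContractError(
                f"{variant.contig}:{variant.pos} indel does not touch CDS of "
                f"{model.gene_id}"
            )
        if n % 3 == 0:
            return CodingConsequence.NONFRAMESHIFT_INDEL, None
        return CodingConsequence.FRAMESHIFT_INDEL, None

    cds_index = model.cds_position(variant.pos)
    if cds_index is None:
        raise ContractError(
            f"{variant.contig}:{variant.pos} not in CDS of {model.gene_id}"
        )
    cds = extract_cds(model, genome)
    codon_i = cds_index // 3
    within = cds_index % 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    alt_base = (
        variant.alt if model.strand == "+" else reverse_complement(variant.alt)
    )
    new_codon = codon[:within] + alt_base + codon[within + 1 :]
    ref_aa = translate_codon(codon)
    alt_aa = translate_codon(new_codon)
    if ref_aa is None or alt_aa is None:
        logger.warning(
            "%s:%d codon contains N; consequence unknown", variant.contig, variant.pos
        )
        return CodingConsequence.UNKNOWN, None
    change = f"{ref_aa}{codon_i + 1}{alt_aa}"
    if ref_aa == alt_aa:
        return CodingConsequence.SYNONYMOUS_SNV, change
    if alt_aa == "*":
        return CodingConsequence.STOP_GAIN, change
    if ref_aa == "*":
        return CodingConsequence.STOP_LOSS, change
    return CodingConsequence.NONSYNONYMOUS_SNV, change


def annotate_callset(
    variants: list[Variant],
    models: dict[str, list[GeneModel]],
    genome: GenomeSequence,
    config: AnnotatorConfig | None = None,
) -> list[AnnotatedVariant]:
    """Annotate every variant with region and, when exonic, coding consequence."""
    config = config or AnnotatorConfig()
    indexes = {
        contig: _RegionIndex(contig_models, config)
        for contig, contig_models in models.items()
    }
    out: list[AnnotatedVariant] = []
    for v in variants:
        clen = genome.lengths.get(v.contig)
        if clen is None or v.pos < 1 or v.pos + len(v.ref) - 1 > clen:
            raise ContractError(
                f"variant {v.contig}:{v.pos} outside contig bounds"
            )
        index = indexes.get(v.contig)
        if index is None:
            out.append(AnnotatedVariant(v, RegionClass.INTERGENIC))
            continue
        region, model = classify_region(v, [], config, index=index)
        consequence = None
        protein_change = None
        splice = False
        if region is RegionClass.EXONIC:
            consequence, protein_change = classify_coding_effect(v, model, genome)
        elif region is RegionClass.INTRONIC:
            splice = _splice_flag(v.pos, model)
        out.append(
            AnnotatedVariant(
                v, region, consequence,
                model.gene_id if model else None,
                protein_change, splice,
            )
        )
    return out
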