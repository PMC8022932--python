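"""Reference genome and gene-model I/O.

Defines the two substrate types every downstream stage relies on — a
contig-indexed genome sequence and per-gene coding structure — together
with their file formats (FASTA, GFF3) and the coordinate convention used
throughout the package: GFF3-style 1-based inclusive genomic intervals.
VCF POS values (also 1-based) are used as-is, so no translation layer
exists anywhere.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

#: complement map for A/C/G/T/N
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class GenomeSequence:
    """Uppercase DNA sequences keyed by contig name.

    Invariants: contig names unique and non-empty; sequences contain only
    A/C/G/T/N; ``lengths`` always mirrors the actual string lengths.
    """

    contigs: dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the sequence of ``contig`` from ``start`` to ``end``, 1-based inclusive."""
        return self.contigs[contig][start - 1 : end]

    def base(self, contig: str, pos: int) -> str:
        return self.contigs[contig][pos - 1]


def _validate_sequence(name: str, seq: str) -> None:
    bad = set(seq) - _VALID_BASES
    if bad:
        for i, ch in enumerate(seq):
            if ch not in _VALID_BASES:
                raise FormatError(
                    f"contig {name!r}: non-IUPAC character {ch!r} at position {i + 1}"
                )


def load_genome(path: str) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased and multi-line records concatenated. Raises
    :class:`FormatError` on an empty file, duplicate contig names or
    characters outside A/C/G/T/N.
    """
    genome = GenomeSequence()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if not name:
            raise FormatError(f"{path}: FASTA record with empty name")
        if name in genome.contigs:
            raise FormatError(f"{path}: duplicate contig name {name!r}")
        seq = str(rec.seq).upper()
        _validate_sequence(name, seq)
        genome.contigs[name] = seq
    if not genome.contigs:
        raise FormatError(f"{path}: no FASTA records found")
    return genome


def write_genome(genome: GenomeSequence, path: str, width: int = 70) -> None:
    """Write a genome back to FASTA (fixed line width; deterministic bytes)."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass
class GeneModel:
    """One gene's structure in genomic coordinates (1-based inclusive).

    ``cds_segments`` are sorted by genomic start and non-overlapping; for a
    minus-strand gene the *translation* order is reverse-genomic, i.e. the
    first codon comes from the highest-coordinate segment. ``coding_valid``
    is False when the CDS length is not a positive multiple of 3, in which
    case the gene still participates in region classification but never in
    coding-consequence calls.
    """

    gene_id: str
    contig: str
    strand: str  # "+" or "-"
    cds_segments: list[tuple[int, int]]
    utr5_segments: list[tuple[int, int]] = field(default_factory=list)
    utr3_segments: list[tuple[int, int]] = field(default_factory=list)
    coding_valid: bool = True

    @property
    def span(self) -> tuple[int, int]:
        segs = self.cds_segments + self.utr5_segments + self.utr3_segments
        return (min(s for s, _ in segs), max(e for _, e in segs))

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    def cds_position(self, pos: int) -> int | None:
        """Coding-order index (0-based) of genomic position ``pos``, or None.

        For minus-strand genes the index counts from the highest genomic
        coordinate of the highest segment downwards.
        """
        offset = 0
        for s, e in self.cds_segments:
            if s <= pos <= e:
                plus_index = offset + (pos - s)
                if self.strand == "+":
                    return plus_index
                return self.cds_length - 1 - plus_index
            offset += e - s + 1
        return None


def extract_cds(model: GeneModel, genome: GenomeSequence) -> str:
    """Concatenated coding sequence of ``model`` in translation orientation.

    For minus-strand genes this is the reverse complement of the genomic
    concatenation, so the returned string starts at the start codon.
    """
    seq = "".join(genome.fetch(model.contig, s, e) for s, e in model.cds_segments)
    if model.strand == "-":
        seq = reverse_complement(seq)
    return seq


def _segments_of(feats) -> list[tuple[int, int]]:
    return sorted((f.start, f.end) for f in feats)


def _check_no_internal_overlap(gene_id: str, segs: list[tuple[int, int]]) -> None:
    for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
        if s2 <= e1:
            raise FormatError(
                f"gene {gene_id!r}: overlapping segments ({s1},{e1}) and ({s2},{e2})"
            )


def load_gene_models(path: str, genome: GenomeSequence) -> dict[str, list[GeneModel]]:
    """Parse a GFF3 file into gene models grouped by contig.

    Expects gene / mRNA / CDS / five_prime_UTR / three_prime_UTR features
    with ID and Parent attributes. When a gene carries several mRNAs the one
    with the longest total CDS is kept (a warning is logged). A gene whose
    CDS length is not a multiple of 3 is kept for region classification but
    flagged ``coding_valid=False``. Features outside contig bounds raise
    :class:`FormatError`. Models are returned sorted per contig by span start.
    """
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise FormatError(f"{path}: cannot parse GFF3: {exc}") from exc

    models: dict[str, list[GeneModel]] = {}
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            logger.warning("gene %s has no mRNA feature; skipped", gene_id)
            continue

        def total_cds(m) -> int:
            return sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))

        if len(mrnas) > 1:
            logger.warning(
                "gene %s has %d mRNAs; keeping the one with the longest CDS",
                gene_id, len(mrnas),
            )
        mrna = max(mrnas, key=total_cds)

        cds = _segments_of(db.children(mrna, featuretype="CDS"))
        utr5 = _segments_of(db.children(mrna, featuretype="five_prime_UTR"))
        utr3 = _segments_of(db.children(mrna, featuretype="three_prime_UTR"))
        if not cds:
            logger.warning("gene %s has no CDS; skipped", gene_id)
            continue

        contig = gene.seqid
        if contig not in genome.contigs:
            raise FormatError(f"gene {gene_id!r}: unknown contig {contig!r}")
        clen = len(genome.contigs[contig])
        for s, e in cds + utr5 + utr3:
            if s < 1 or e > clen or s > e:
                raise FormatError(
                    f"gene {gene_id!r}: segment ({s},{e}) outside contig "
                    f"{contig!r} bounds (1..{clen})"
                )
        _check_no_internal_overlap(gene_id, sorted(cds + utr5 + utr3))

        model = GeneModel(
            gene_id=gene_id,
            contig=contig,
            strand=gene.strand,
            cds_segments=cds,
            utr5_segments=utr5,
            utr3_segments=utr3,
        )
        if model.cds_length % 3 != 0 or model.cds_length == 0:
            logger.warning(
                "gene %s: CDS length %d not a positive multiple of 3; "
                "excluded from coding-consequence calls",
                gene_id, model.cds_length,
            )
            model.coding_valid = False
        models.setdefault(contig, []).append(model)

    for contig in models:
        models[contig].sort(key=lambda m: m.span[0])
    return models
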