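"""Variant records and VCF I/O for per-mutant-line callsets.

A variant is one normalized allele change — SNV, insertion or deletion —
identified across lines by the exact key (contig, pos, ref, alt), plus the
caller quality annotations the hard filter reads (QD, MQ, QUAL, MQRankSum,
SOR, FS, ReadPosRankSum). Multi-allelic records are split one alt per
variant; MNVs and symbolic alleles are out of scope. No indel
left-normalization is performed: inputs are assumed caller-normalized.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import pysam

from .errors import FormatError, UnsupportedVariantError

logger = logging.getLogger(__name__)

#: INFO keys carried through read/write, in canonical order
METRIC_KEYS = ("QD", "MQ", "MQRankSum", "SOR", "FS", "ReadPosRankSum")


class VariantClass(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"


@dataclass(frozen=True)
class VariantQualityMetrics:
    """Caller quality annotations; None means the annotation is absent,
    which is distinct from any numeric value (absent metrics can never
    fail a filter criterion)."""

    QD: float | None = None
    MQ: float | None = None
    QUAL: float | None = None
    MQRankSum: float | None = None
    SOR: float | None = None
    FS: float | None = None
    ReadPosRankSum: float | None = None

    def __post_init__(self):
        for name in ("QUAL", "FS", "SOR"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


def classify_allele(ref: str, alt: str) -> VariantClass:
    """SNV if both alleles are single bases, insertion/deletion by length.

    Equal-length multi-base substitutions (MNVs) raise
    :class:`UnsupportedVariantError`.
    """
    if not ref or not alt:
        raise UnsupportedVariantError("empty allele")
    if any(c not in "ACGT" for c in ref + alt):
        raise UnsupportedVariantError(f"non-ACGT allele: {ref!r}>{alt!r}")
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    if len(alt) > len(ref):
        return VariantClass.INSERTION
    if len(ref) > len(alt):
        return VariantClass.DELETION
    raise UnsupportedVariantError(f"MNV not supported: {ref!r}>{alt!r}")


@dataclass(frozen=True)
class Variant:
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    line_id: str
    metrics: VariantQualityMetrics = field(default_factory=VariantQualityMetrics)

    @property
    def vclass(self) -> VariantClass:
        return classify_allele(self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity key used for cross-line recurrence comparison."""
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass
class CohortCallset:
    """Per-mutant-line variant collections, keyed by line id.

    Within one line the identity key is unique (duplicates raise on add).
    """

    lines: dict[str, list[Variant]] = field(default_factory=dict)

    def add_line(self, line_id: str, variants: list[Variant]) -> None:
        keys = [v.key for v in variants]
        if len(set(keys)) != len(keys):
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise FormatError(f"line {line_id}: duplicate variant key {k}")
                seen.add(k)
        self.lines[line_id] = list(variants)

    @property
    def n_lines(self) -> int:
        return len(self.lines)


def _is_symbolic(alt: str) -> bool:
    return alt.startswith("<") or "[" in alt or "]" in alt or alt in (".", "*")


def read_vcf(path: str, line_id: str, genome=None) -> list[Variant]:
    """Read a VCF into Variant records for one mutant line.

    Multi-allelic records are split, each alt inheriting the record's
    metrics; symbolic alleles and MNVs are skipped with a warning; absent
    INFO keys (and QUAL ".") become absent metrics. When ``genome`` is
    given, ref alleles are checked against it.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: cannot open VCF: {exc}") from exc
    variants: list[Variant] = []
    with vf:
        records = _iter_records(vf, path)
        for rec in records:
            qual = None if rec.qual is None else float(rec.qual)
            info_vals = {}
            for key in METRIC_KEYS:
                if key in rec.info:
                    raw = rec.info[key]
                    if isinstance(raw, tuple):
                        raw = raw[0]
                    info_vals[key] = None if raw is None else float(raw)
            metrics = VariantQualityMetrics(QUAL=qual, **info_vals)
            for alt in rec.alts or ():
                if _is_symbolic(alt):
                    logger.warning(
                        "%s:%d symbolic allele %s skipped", rec.contig, rec.pos, alt
                    )
                    continue
                try:
                    classify_allele(rec.ref, alt)
                except UnsupportedVariantError as exc:
                    logger.warning("%s:%d %s; skipped", rec.contig, rec.pos, exc)
                    continue
                if genome is not None:
                    expected = genome.fetch(
                        rec.contig, rec.pos, rec.pos + len(rec.ref) - 1
                    )
                    if expected != rec.ref:
                        raise FormatError(
                            f"{path}: {rec.contig}:{rec.pos} REF {rec.ref!r} does "
                            f"not match genome ({expected!r})"
                        )
                variants.append(
                    Variant(rec.contig, rec.pos, rec.ref, alt, line_id, metrics)
                )
    return variants


def _iter_records(vf, path):
    it = iter(vf)
    n = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return
        except Exception as exc:
            raise FormatError(
                f"{path}: malformed VCF record after data line {n}: {exc}"
            ) from exc
        n += 1
        yield rec


def _build_header(contig_lengths: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    descriptions = {
        "QD": "Variant Confidence/Quality by Depth",
        "MQ": "RMS Mapping Quality",
        "MQRankSum": "Z-score from Wilcoxon rank sum test of Alt vs. Ref read mapping qualities",
        "SOR": "Symmetric Odds Ratio of 2x2 contingency table to detect strand bias",
        "FS": "Phred-scaled p-value using Fisher's exact test to detect strand bias",
        "ReadPosRankSum": "Z-score from Wilcoxon rank sum test of Alt vs. Ref read position bias",
    }
    for key in METRIC_KEYS:
        header.info.add(key, number=1, type="Float", description=descriptions[key])
    return header


def write_vcf(
    variants: list[Variant], path: str, contig_lengths: dict[str, int]
) -> None:
    """Write variants to a VCF 4.2 file with typed INFO definitions.

    Input must already be sorted by (contig, pos); output bytes are
    deterministic for fixed input (no timestamps in the header). Each
    variant becomes its own record — the multi-allelic split is one-way.
    """
    order = {name: i for i, name in enumerate(contig_lengths)}
    sort_keys = [(order[v.contig], v.pos) for v in variants]
    if sort_keys != sorted(sort_keys):
        raise FormatError("write_vcf requires input sorted by (contig, pos)")
    header = _build_header(contig_lengths)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.contig, start=v.pos - 1, stop=v.pos + len(v.ref) - 1,
                alleles=(v.ref, v.alt),
            )
            if v.metrics.QUAL is not None:
                rec.qual = round(v.metrics.QUAL, 4)
            for key in METRIC_KEYS:
                val = getattr(v.metrics, key)
                if val is not None:
                    rec.info[key] = round(val, 4)
            out.write(rec)
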