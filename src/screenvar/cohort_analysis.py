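"""Cross-line cohort analysis: background removal, recurrence filtering,
candidate selection and per-line summary tables.

Two distinct recurrence rules operate at two stages, mirroring how a
mutagenized-cohort screen treats shared variants. A variant present in
*every* line is background divergence between the mutagenized clone and
the reference clone and is removed outright; a variant present in more
than ``max_recurrence`` lines (default 2) survives background removal but
is excluded from candidacy, since independently causal hits are not
expected to recur. Candidates are exonic, non-synonymous variants grouped
by gene and ranked by loss-of-function severity (stop-gain and frameshift
first).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .effect_annotator import AnnotatedVariant, CodingConsequence, RegionClass
from .variant_model import CohortCallset

#: column order of the per-line summary table
SUMMARY_COLUMNS = [
    "line_id", "upstream", "downstream", "intergenic", "intronic",
    "utr5", "utr3", "exonic", "frameshift_indel", "nonframeshift_indel",
    "nonsynonymous_snv", "synonymous_snv", "stop_gain", "total",
]

_REGION_COLS = ["upstream", "downstream", "intergenic", "intronic", "utr5", "utr3", "exonic"]
_SUBTYPE_COLS = ["frameshift_indel", "nonframeshift_indel", "nonsynonymous_snv",
                 "synonymous_snv", "stop_gain"]


@dataclass
class RecurrenceIndex:
    """Number of distinct mutant lines carrying each variant identity key."""

    counts: dict[tuple, int] = field(default_factory=dict)
    n_lines: int = 0

    def count(self, key: tuple) -> int:
        return self.counts.get(key, 0)


def build_recurrence_index(cohort: CohortCallset) -> RecurrenceIndex:
    """Count, per identity key, how many lines carry the variant (not copies)."""
    counter: Counter = Counter()
    for variants in cohort.lines.values():
        for key in {v.key for v in variants}:
            counter[key] += 1
    return RecurrenceIndex(dict(counter), cohort.n_lines)


def remove_background(cohort: CohortCallset, index: RecurrenceIndex) -> CohortCallset:
    """Drop variants shared by all lines; anything less-than-universal stays.

    Variants recurring in 3..n-1 lines survive this stage and are handled
    later by :func:`select_candidates`.
    """
    n = cohort.n_lines
    out = CohortCallset()
    for line_id, variants in cohort.lines.items():
        out.lines[line_id] = [v for v in variants if index.count(v.key) < n]
    return out


@dataclass(frozen=True)
class CandidateConfig:
    max_recurrence: int = 2
    drop_synonymous: bool = True
    severity_order: tuple[CodingConsequence, ...] = (
        CodingConsequence.STOP_GAIN,
        CodingConsequence.FRAMESHIFT_INDEL,
        CodingConsequence.NONFRAMESHIFT_INDEL,
        CodingConsequence.STOP_LOSS,
        CodingConsequence.NONSYNONYMOUS_SNV,
    )

    def __post_init__(self):
        if self.max_recurrence < 1:
            raise ValueError("max_recurrence must be >= 1")


@dataclass
class CandidateGene:
    gene_id: str
    line_id: str
    variants: list[AnnotatedVariant]
    severity_rank: int  # ordinal of the most severe consequence (0 = worst)

    @property
    def top_consequence(self) -> CodingConsequence:
        return min(
            (av.consequence for av in self.variants),
            key=lambda c: _severity_key(c),
        )


_DEFAULT_ORDER = CandidateConfig().severity_order


def _severity_key(c: CodingConsequence, order=_DEFAULT_ORDER) -> int:
    return order.index(c) if c in order else len(order)


def select_candidates(
    annotated: list[AnnotatedVariant],
    index: RecurrenceIndex,
    config: CandidateConfig | None = None,
) -> list[CandidateGene]:
    """Candidate genes for one mutant line, ranked by severity.

    Keeps variants that are exonic, not synonymous (when
    ``drop_synonymous``), have a consequence in the severity order, and
    occur in at most ``max_recurrence`` lines; groups by gene; ranks genes
    by the severity of their most severe variant, ties broken by gene id.
    """
    config = config or CandidateConfig()
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for av in annotated:
        if av.region is not RegionClass.EXONIC:
            continue
        if config.drop_synonymous and av.consequence is CodingConsequence.SYNONYMOUS_SNV:
            continue
        if av.consequence is None or av.consequence is CodingConsequence.UNKNOWN:
            continue
        if index.count(av.variant.key) > config.max_recurrence:
            continue
        by_gene.setdefault(av.gene_id, []).append(av)

    candidates = []
    for gene_id, variants in by_gene.items():
        rank = min(
            _severity_key(av.consequence, config.severity_order) for av in variants
        )
        line_id = variants[0].variant.line_id
        candidates.append(CandidateGene(gene_id, line_id, variants, rank))
    candidates.sort(key=lambda c: (c.severity_rank, c.gene_id))
    return candidates


_REGION_TO_COL = {
    RegionClass.UPSTREAM: "upstream",
    RegionClass.DOWNSTREAM: "downstream",
    RegionClass.INTERGENIC: "intergenic",
    RegionClass.INTRONIC: "intronic",
    RegionClass.UTR5: "utr5",
    RegionClass.UTR3: "utr3",
}

_CONSEQUENCE_TO_COL = {
    CodingConsequence.FRAMESHIFT_INDEL: "frameshift_indel",
    CodingConsequence.NONFRAMESHIFT_INDEL: "nonframeshift_indel",
    CodingConsequence.NONSYNONYMOUS_SNV: "nonsynonymous_snv",
    CodingConsequence.SYNONYMOUS_SNV: "synonymous_snv",
    CodingConsequence.STOP_GAIN: "stop_gain",
    # the closed table taxonomy has no stop-loss column; folded into
    # nonsynonymous so the exonic partition identity holds
    CodingConsequence.STOP_LOSS: "nonsynonymous_snv",
}


def summary_row(line_id: str, annotated: list[AnnotatedVariant]) -> dict:
    """One summary-table row; both partition identities hold by construction.

    Exonic variants with an ``unknown`` consequence (N-containing codons)
    are excluded from the exonic count as well as the subtype counts, so
    exonic always equals the subtype sum.
    """
    row = {col: 0 for col in SUMMARY_COLUMNS if col != "line_id"}
    row["line_id"] = line_id
    for av in annotated:
        if av.region is RegionClass.EXONIC:
            col = _CONSEQUENCE_TO_COL.get(av.consequence)
            if col is None:
                continue  # unknown consequence: excluded from exonic entirely
            row["exonic"] += 1
            row[col] += 1
        else:
            row[_REGION_TO_COL[av.region]] += 1
    row["total"] = sum(row[c] for c in _REGION_COLS)
    return row


def summary_row_from_counts(line_id: str, **counts) -> dict:
    """Recompute a summary row's exonic and total from raw category counts.

    Accepts the six non-exonic region counts and the five exonic subtype
    counts; exonic and total are derived, never taken as input. Used for
    worked-example arithmetic on published per-line counts.
    """
    row = {"line_id": line_id}
    for col in _REGION_COLS[:-1] + _SUBTYPE_COLS:
        row[col] = int(counts.get(col, 0))
    row["exonic"] = sum(row[c] for c in _SUBTYPE_COLS)
    row["total"] = sum(row[c] for c in _REGION_COLS)
    return {col: row[col] for col in SUMMARY_COLUMNS}


def candidate_count_from_counts(exonic: int, synonymous: int) -> int:
    """Candidate-gene count under a one-variant-per-gene reading:
    exonic variants minus synonymous ones."""
    return exonic - synonymous


def summarize_counts(
    annotated_by_line: dict[str, list[AnnotatedVariant]]
) -> pd.DataFrame:
    """Per-line region/subtype count table (background must already be removed)."""
    rows = [
        summary_row(line_id, annotated)
        for line_id, annotated in sorted(annotated_by_line.items())
    ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def report(
    candidates_by_line: dict[str, list[CandidateGene]],
    table: pd.DataFrame,
    summary_path: str,
    candidates_path: str,
    text_path: str | None = None,
) -> None:
    """Write the summary TSV (column order as printed), a candidate TSV and
    an optional human-readable report. Output is deterministic."""
    table.to_csv(summary_path, sep="\t", index=False)

    cand_rows = []
    for line_id in sorted(candidates_by_line):
        for rank, cg in enumerate(candidates_by_line[line_id], start=1):
            for av in cg.variants:
                cand_rows.append({
                    "line_id": line_id,
                    "rank": rank,
                    "gene_id": cg.gene_id,
                    "top_consequence": cg.top_consequence.value,
                    "contig": av.variant.contig,
                    "pos": av.variant.pos,
                    "ref": av.variant.ref,
                    "alt": av.variant.alt,
                    "consequence": av.consequence.value,
                    "protein_change": av.protein_change or ".",
                })
    cand_cols = ["line_id", "rank", "gene_id", "top_consequence", "contig",
                 "pos", "ref", "alt", "consequence", "protein_change"]
    pd.DataFrame(cand_rows, columns=cand_cols).to_csv(
        candidates_path, sep="\t", index=False
    )

    if text_path is not None:
        lines = ["Candidate genes per mutant line", "=" * 32, ""]
        for line_id in sorted(candidates_by_line):
            cands = candidates_by_line[line_id]
            lines.append(f"{line_id}: {len(cands)} candidate gene(s)")
            for rank, cg in enumerate(cands, start=1):
                lines.append(
                    f"  {rank}. {cg.gene_id} [{cg.top_consequence.value}] "
                    f"({len(cg.variants)} variant(s))"
                )
            lines.append("")
        with open(text_path, "w") as fh:
            fh.write("\n".join(lines))
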