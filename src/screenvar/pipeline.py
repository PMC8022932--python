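"""End-to-end pipeline: read → hard-filter → annotate → remove background →
summarize → select candidates → report.

All data products are files under one output directory; logs go to the
logging subsystem (standard error in the CLI) so outputs stay pipe-safe.
Output bytes are deterministic for a fixed input set.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .cohort_analysis import (
    CandidateConfig,
    CandidateGene,
    build_recurrence_index,
    remove_background,
    report,
    select_candidates,
    summarize_counts,
)
from .effect_annotator import (
    AnnotatedVariant,
    AnnotatorConfig,
    CodingConsequence,
    RegionClass,
    annotate_callset,
)
from .errors import FormatError
from .hard_filter import FilterThresholds, filter_callset
from .reference_io import load_gene_models, load_genome
from .variant_model import CohortCallset, Variant, read_vcf, write_vcf

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "contig", "pos", "ref", "alt", "line_id", "region", "consequence",
    "gene_id", "protein_change",
]


@dataclass
class PipelineConfig:
    genome_path: str
    gff3_path: str
    vcfs: dict[str, str]  # line_id -> path
    out_dir: str
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    annotator: AnnotatorConfig = field(default_factory=AnnotatorConfig)
    candidates: CandidateConfig = field(default_factory=CandidateConfig)


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    candidates_by_line: dict[str, list[CandidateGene]]
    annotated_by_line: dict[str, list[AnnotatedVariant]]
    n_input: dict[str, int]
    n_passed: dict[str, int]


def annotations_to_frame(annotated: list[AnnotatedVariant]) -> pd.DataFrame:
    rows = [
        {
            "contig": av.variant.contig,
            "pos": av.variant.pos,
            "ref": av.variant.ref,
            "alt": av.variant.alt,
            "line_id": av.variant.line_id,
            "region": av.region.value,
            "consequence": av.consequence.value if av.consequence else ".",
            "gene_id": av.gene_id or ".",
            "protein_change": av.protein_change or ".",
        }
        for av in annotated
    ]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def frame_to_annotations(df: pd.DataFrame) -> list[AnnotatedVariant]:
    """Rebuild lightweight annotated variants from an annotation TSV frame
    (metrics are not carried; they are spent once the hard filter has run)."""
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        consequence = (
            None if row.consequence == "." else CodingConsequence(row.consequence)
        )
        out.append(
            AnnotatedVariant(
                Variant(row.contig, int(row.pos), row.ref, row.alt, row.line_id),
                RegionClass(row.region),
                consequence,
                None if row.gene_id == "." else row.gene_id,
                None if row.protein_change == "." else row.protein_change,
            )
        )
    return out


def cohort_pipeline(
    annotated_by_line: dict[str, list[AnnotatedVariant]],
    candidate_config: CandidateConfig,
) -> tuple[pd.DataFrame, dict[str, list[CandidateGene]]]:
    """Cohort stages on already-annotated, hard-filter-passed variants:
    background removal, summary table, per-line candidate selection."""
    cohort = CohortCallset()
    for line_id, annotated in annotated_by_line.items():
        cohort.add_line(line_id, [av.variant for av in annotated])
    index = build_recurrence_index(cohort)
    cleaned = remove_background(cohort, index)
    kept_keys = {
        line_id: {v.key for v in variants}
        for line_id, variants in cleaned.lines.items()
    }
    cleaned_annotated = {
        line_id: [av for av in annotated if av.variant.key in kept_keys[line_id]]
        for line_id, annotated in annotated_by_line.items()
    }
    summary = summarize_counts(cleaned_annotated)
    candidates = {
        line_id: select_candidates(annotated, index, candidate_config)
        for line_id, annotated in cleaned_annotated.items()
    }
    return summary, candidates


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write filtered VCFs, annotation, summary and
    candidate TSVs plus a run log under ``config.out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    genome = load_genome(config.genome_path)
    models = load_gene_models(config.gff3_path, genome)

    annotated_by_line: dict[str, list[AnnotatedVariant]] = {}
    n_input: dict[str, int] = {}
    n_passed: dict[str, int] = {}
    filtered_dir = os.path.join(config.out_dir, "filtered")
    os.makedirs(filtered_dir, exist_ok=True)
    for line_id in sorted(config.vcfs):
        variants = read_vcf(config.vcfs[line_id], line_id, genome=genome)
        passed, failed = filter_callset(variants, config.thresholds)
        n_input[line_id] = len(variants)
        n_passed[line_id] = len(passed)
        write_vcf(
            passed, os.path.join(filtered_dir, f"{line_id}.passed.vcf"),
            genome.lengths,
        )
        fail_rows = [
            {
                "contig": v.contig, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "failed_criteria": ";".join(verdict.failed_criteria),
            }
            for v, verdict in failed
        ]
        pd.DataFrame(
            fail_rows,
            columns=["contig", "pos", "ref", "alt", "failed_criteria"],
        ).to_csv(
            os.path.join(filtered_dir, f"{line_id}.failed.tsv"),
            sep="\t", index=False,
        )
        annotated_by_line[line_id] = annotate_callset(
            passed, models, genome, config.annotator
        )
        logger.info(
            "%s: %d variants, %d passed hard filter",
            line_id, len(variants), len(passed),
        )

    all_annotated = [
        av for line_id in sorted(annotated_by_line)
        for av in annotated_by_line[line_id]
    ]
    annotations_to_frame(all_annotated).to_csv(
        os.path.join(config.out_dir, "annotation.tsv"), sep="\t", index=False
    )

    summary, candidates = cohort_pipeline(annotated_by_line, config.candidates)
    report(
        candidates, summary,
        os.path.join(config.out_dir, "summary.tsv"),
        os.path.join(config.out_dir, "candidates.tsv"),
        os.path.join(config.out_dir, "report.txt"),
    )

    t = config.thresholds
    log_lines = [
        f"screenvar {__version__}",
        f"lines: {', '.join(sorted(config.vcfs))}",
        f"thresholds: qd_min={t.qd_min} mq_min={t.mq_min} qual_min={t.qual_min} "
        f"mqranksum_min={t.mqranksum_min} sor_max={t.sor_max} fs_max={t.fs_max} "
        f"readpos_min={t.readpos_min}",
        f"flank_window: {config.annotator.flank_window}",
        f"max_recurrence: {config.candidates.max_recurrence}",
        f"drop_synonymous: {config.candidates.drop_synonymous}",
    ]
    with open(os.path.join(config.out_dir, "run_log.txt"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")

    return PipelineResult(summary, candidates, annotated_by_line, n_input, n_passed)
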