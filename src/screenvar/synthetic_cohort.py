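"""Synthetic mutagenized-cohort generator with a per-variant truth table.

Emulates the statistical structure a trap-formation screen's resequencing
data hands to the analysis: ~15 independently mutagenized lines, each
carrying a shared universal background set (clone divergence from the
reference), a few decoy variants recurring in more than two lines,
hundreds of line-private mutations spread across all region categories
with a mutagen-specific SNV spectrum (EMS: predominantly G:C→A:T
transitions; UV: C→T at pyrimidine dinucleotides), one planted causal
exonic loss-of-function variant per line in a line-unique gene, and a
controllable fraction of calls whose quality metrics violate the hard
filter. Every emitted variant has exactly one truth row recording its
intended region, consequence, filter verdict and provenance, so each
pipeline stage can be scored exactly.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .effect_annotator import (
    PRECEDENCE,
    CodingConsequence,
    RegionClass,
    translate_codon,
)
from .errors import ConfigError
from .hard_filter import FilterThresholds, evaluate_variant
from .reference_io import (
    GeneModel,
    GenomeSequence,
    extract_cds,
    reverse_complement,
    write_genome,
)
from .variant_model import Variant, VariantQualityMetrics, write_vcf

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")

#: region-category weights for planting private variants; the compact,
#: gene-dense synthetic genome spreads mutations across every category the
#: summary table counts
_CATEGORY_WEIGHTS = {
    RegionClass.UPSTREAM: 0.16,
    RegionClass.DOWNSTREAM: 0.14,
    RegionClass.INTERGENIC: 0.22,
    RegionClass.INTRONIC: 0.12,
    RegionClass.UTR5: 0.06,
    RegionClass.UTR3: 0.05,
    RegionClass.EXONIC: 0.25,
}


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults mirror the screen the package models: 15 mutant lines, a
    universal background set shared by all lines, decoys recurring in more
    than two lines, one exonic loss-of-function causal variant per line,
    EMS spectrum with 90% G:C→A:T transitions, and 20% of calls failing
    the hard filter. ``n_private_per_line`` defaults to a desk-scale 200;
    :meth:`fidelity_scale` returns the ~2700-mutations-per-line variant with
    a proportionally larger genome.
    """

    seed: int = 0
    n_lines: int = 15
    genome_length: int = 100_000
    n_genes: int = 20
    n_background_universal: int = 50
    n_recurrent_decoys: int = 10
    n_private_per_line: int = 200
    n_synonymous_decoys_per_line: int = 5
    mutagen_profile: str = "EMS"  # or "UV"
    ems_gc_to_at: float = 0.9  # fraction of EMS SNVs that are G:C->A:T
    indel_fraction: float = 0.12  # fraction of private variants that are indels
    fail_fraction: float = 0.2  # fraction of background+private calls failing the hard filter
    flank_window: int = 1000
    contig_name: str = "chr1"

    def __post_init__(self):
        if self.n_lines < 1:
            raise ConfigError("n_lines must be >= 1")
        if self.n_genes * 1500 > self.genome_length:
            raise ConfigError(
                f"cannot fit {self.n_genes} genes in {self.genome_length} bp"
            )
        if not 0 <= self.fail_fraction <= 1:
            raise ConfigError("fail_fraction must be in [0, 1]")
        if self.mutagen_profile not in ("EMS", "UV"):
            raise ConfigError(f"unknown mutagen_profile {self.mutagen_profile!r}")
        if self.n_recurrent_decoys and self.n_lines < 4:
            raise ConfigError(
                "recurrent decoys need n_lines >= 4 (placed in 3..n-1 lines)"
            )

    @classmethod
    def fidelity_scale(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Fidelity-scale conditions: ~2700 mutations per line on a 1 Mb genome."""
        params = dict(
            seed=seed, genome_length=1_000_000, n_genes=150,
            n_private_per_line=2700,
        )
        params.update(overrides)
        return cls(**params)


# ---------------------------------------------------------------------------
# genome simulation


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list(_BASES), 3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeSequence, dict[str, list[GeneModel]]]:
    """Generate a random genome with non-overlapping ORF gene models.

    Each gene is a valid ORF (ATG start, in-frame stop, no internal stop,
    length a multiple of 3) flanked by 5'/3' UTRs, on a random strand,
    optionally split by introns. Genes are separated by gaps wide enough
    for distinct upstream/downstream/intergenic planting pools.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    contig = config.contig_name
    genome_arr = rng.choice(list(_BASES), config.genome_length).astype("U1")

    models: list[GeneModel] = []
    cursor = 2 * config.flank_window + 200
    budget = config.genome_length - 2 * config.flank_window - 200
    for gi in range(config.n_genes):
        n_codons = int(rng.integers(60, 150))
        utr5_len = int(rng.integers(60, 150))
        utr3_len = int(rng.integers(60, 150))
        n_introns = int(rng.integers(0, 3))
        intron_lens = [int(rng.integers(60, 200)) for _ in range(n_introns)]
        strand = "+" if rng.random() < 0.5 else "-"
        cds = _random_orf(rng, n_codons)

        cut_points = sorted(
            rng.choice(np.arange(10, len(cds) - 10), size=n_introns, replace=False)
        ) if n_introns else []
        cds_parts, prev = [], 0
        for cp in cut_points:
            cds_parts.append(cds[prev:cp])
            prev = int(cp)
        cds_parts.append(cds[prev:])

        # assemble the gene's genomic sequence in transcript order
        pieces: list[tuple[str, str]] = [
            ("utr5", "".join(rng.choice(list(_BASES), utr5_len)))
        ]
        for i, part in enumerate(cds_parts):
            pieces.append(("cds", part))
            if i < len(intron_lens):
                pieces.append(
                    ("intron", "".join(rng.choice(list(_BASES), intron_lens[i])))
                )
        pieces.append(("utr3", "".join(rng.choice(list(_BASES), utr3_len))))
        if strand == "-":
            pieces = [(kind, reverse_complement(s)) for kind, s in reversed(pieces)]

        gene_len = sum(len(s) for _, s in pieces)
        start = cursor
        if start + gene_len > budget:
            raise ConfigError(
                f"cannot place gene {gi + 1}/{config.n_genes} within genome"
            )

        cds_segments, utr5_segments, utr3_segments = [], [], []
        pos = start
        for kind, s in pieces:
            seg = (pos, pos + len(s) - 1)
            genome_arr[pos - 1 : pos - 1 + len(s)] = list(s)
            if kind == "cds":
                cds_segments.append(seg)
            elif kind == "utr5":
                utr5_segments.append(seg)
            elif kind == "utr3":
                utr3_segments.append(seg)
            pos += len(s)

        models.append(
            GeneModel(
                gene_id=f"SIMG{gi + 1:04d}",
                contig=contig,
                strand=strand,
                cds_segments=sorted(cds_segments),
                utr5_segments=sorted(utr5_segments),
                utr3_segments=sorted(utr3_segments),
            )
        )
        gap = int(rng.integers(2 * config.flank_window + 300,
                               2 * config.flank_window + 600))
        cursor = start + gene_len + gap

    genome = GenomeSequence({contig: "".join(genome_arr)})
    return genome, {contig: models}


def write_gff3(models: dict[str, list[GeneModel]], path: str) -> None:
    """Write gene models as GFF3 (gene/mRNA/CDS/UTR features with ID/Parent)."""
    lines = ["##gff-version 3"]
    for contig in models:
        for m in models[contig]:
            s, e = m.span
            gid, mid = m.gene_id, f"{m.gene_id}.t1"
            lines.append(f"{contig}\tsim\tgene\t{s}\t{e}\t.\t{m.strand}\t.\tID={gid}")
            lines.append(
                f"{contig}\tsim\tmRNA\t{s}\t{e}\t.\t{m.strand}\t.\tID={mid};Parent={gid}"
            )
            ordered = (
                m.cds_segments if m.strand == "+" else list(reversed(m.cds_segments))
            )
            phase, rows = 0, []
            for cs, ce in ordered:
                rows.append((cs, ce, phase))
                phase = (3 - ((ce - cs + 1 - phase) % 3)) % 3
            for cs, ce, ph in sorted(rows):
                lines.append(
                    f"{contig}\tsim\tCDS\t{cs}\t{ce}\t.\t{m.strand}\t{ph}\t"
                    f"ID={mid}.cds;Parent={mid}"
                )
            for us, ue in m.utr5_segments:
                lines.append(
                    f"{contig}\tsim\tfive_prime_UTR\t{us}\t{ue}\t.\t{m.strand}\t.\t"
                    f"ID={mid}.u5;Parent={mid}"
                )
            for us, ue in m.utr3_segments:
                lines.append(
                    f"{contig}\tsim\tthree_prime_UTR\t{us}\t{ue}\t.\t{m.strand}\t.\t"
                    f"ID={mid}.u3;Parent={mid}"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# exhaustive per-position region scan (also the planting pools)


def scan_region_classes(
    models: list[GeneModel], contig_length: int, flank_window: int = 1000
) -> np.ndarray:
    """Per-position region class over a whole contig by direct array marking.

    Marks classes in ascending precedence so the highest-precedence class
    wins at every position. Independent of the interval-tree annotator;
    serves both as the simulator's planting pool and as an exhaustive
    oracle. Returns an int8 array (1-based position p at index p-1) of the
    precedence codes in :data:`screenvar.effect_annotator.PRECEDENCE`.
    """
    codes = np.full(contig_length, PRECEDENCE[RegionClass.INTERGENIC], dtype=np.int8)

    def mark(s: int, e: int, cls: RegionClass) -> None:
        s, e = max(1, s), min(contig_length, e)
        if e >= s:
            codes[s - 1 : e] = PRECEDENCE[cls]

    order = [
        RegionClass.DOWNSTREAM, RegionClass.UPSTREAM, RegionClass.INTRONIC,
        RegionClass.UTR3, RegionClass.UTR5, RegionClass.EXONIC,
    ]
    for cls in order:
        for m in models:
            span_s, span_e = m.span
            if cls is RegionClass.DOWNSTREAM:
                if m.strand == "+":
                    mark(span_e + 1, span_e + flank_window, cls)
                else:
                    mark(span_s - flank_window, span_s - 1, cls)
            elif cls is RegionClass.UPSTREAM:
                if m.strand == "+":
                    mark(span_s - flank_window, span_s - 1, cls)
                else:
                    mark(span_e + 1, span_e + flank_window, cls)
            elif cls is RegionClass.INTRONIC:
                segs = sorted(m.cds_segments + m.utr5_segments + m.utr3_segments)
                for (_, e1), (s2, _) in zip(segs, segs[1:]):
                    if s2 > e1 + 1:
                        mark(e1 + 1, s2 - 1, cls)
            elif cls is RegionClass.UTR3:
                for s, e in m.utr3_segments:
                    mark(s, e, cls)
            elif cls is RegionClass.UTR5:
                for s, e in m.utr5_segments:
                    mark(s, e, cls)
            else:
                for s, e in m.cds_segments:
                    mark(s, e, cls)
    return codes


_CODE_TO_CLASS = {code: cls for cls, code in PRECEDENCE.items()}


# ---------------------------------------------------------------------------
# metric draws


def _draw_passing_metrics(rng) -> VariantQualityMetrics:
    return VariantQualityMetrics(
        QD=float(rng.uniform(20, 35)),
        MQ=float(rng.uniform(55, 60)),
        QUAL=float(rng.uniform(300, 3000)),
        MQRankSum=float(rng.uniform(-2, 2)),
        SOR=float(rng.uniform(0.5, 2.0)),
        FS=float(rng.uniform(0, 5)),
        ReadPosRankSum=float(rng.uniform(-2, 2)),
    )


_FAIL_DRAWS = (
    ("QD", lambda rng: float(rng.uniform(0.0, 1.9))),
    ("MQ", lambda rng: float(rng.uniform(10, 39))),
    ("QUAL", lambda rng: float(rng.uniform(0, 99))),
    ("MQRankSum", lambda rng: float(rng.uniform(-20, -13))),
    ("SOR", lambda rng: float(rng.uniform(4.5, 8))),
    ("FS", lambda rng: float(rng.uniform(65, 120))),
    ("ReadPosRankSum", lambda rng: float(rng.uniform(-15, -8.5))),
)


def _draw_failing_metrics(rng) -> VariantQualityMetrics:
    """Passing draw with one uniformly chosen criterion pushed past threshold."""
    base = _draw_passing_metrics(rng)
    attr, draw = _FAIL_DRAWS[int(rng.integers(0, len(_FAIL_DRAWS)))]
    return replace(base, **{attr: draw(rng)})


# ---------------------------------------------------------------------------
# variant planting


class _Planter:
    """Draws variant positions/alleles from per-category pools.

    A global reservation set keeps every planted variant's affected
    interval disjoint from every other's, so identity keys never collide
    accidentally and cross-line recurrence counts are exact by design.
    """

    def __init__(self, config, genome, models, rng):
        self.config = config
        self.genome = genome
        self.contig = config.contig_name
        self.seq = genome.contigs[self.contig]
        self.models = models[self.contig]
        self.rng = rng
        self.codes = scan_region_classes(
            self.models, len(self.seq), config.flank_window
        )
        self.pools = {
            cls: (np.flatnonzero(self.codes == code) + 1)
            for cls, code in PRECEDENCE.items()
        }
        self.used: set[int] = set()
        self.gene_cds_pos = {}
        for m in self.models:
            pos: list[int] = []
            for s, e in m.cds_segments:
                pos.extend(range(s, e + 1))
            self.gene_cds_pos[m.gene_id] = pos
        self.model_by_id = {m.gene_id: m for m in self.models}

    def _free(self, lo: int, hi: int) -> bool:
        return not any(p in self.used for p in range(lo, hi + 1))

    def _reserve(self, lo: int, hi: int) -> None:
        self.used.update(range(lo, hi + 1))

    def _take(self, pool: np.ndarray, span: int = 1, predicate=None) -> int:
        if len(pool) == 0:
            raise ConfigError("empty planting pool")
        for _ in range(20_000):
            pos = int(pool[self.rng.integers(0, len(pool))])
            if pos + span - 1 > len(self.seq):
                continue
            if not self._free(pos, pos + span - 1):
                continue
            if predicate and not predicate(pos):
                continue
            self._reserve(pos, pos + span - 1)
            return pos
        raise ConfigError("could not place variant; pools exhausted")

    # --- allele draws ------------------------------------------------------

    def _snv_alt(self, ref: str) -> str:
        cfg = self.config
        if cfg.mutagen_profile == "EMS":
            if ref == "G":
                return "A"
            if ref == "C":
                return "T"
        elif cfg.mutagen_profile == "UV" and ref == "C":
            return "T"
        choices = [b for b in _BASES if b != ref]
        return choices[int(self.rng.integers(0, 3))]

    def _spectrum_predicate(self):
        cfg = self.config
        seq = self.seq
        if cfg.mutagen_profile == "EMS":
            if self.rng.random() < cfg.ems_gc_to_at:
                return lambda p: seq[p - 1] in "GC"
            return lambda p: seq[p - 1] in "AT"
        # UV: C in a pyrimidine-dinucleotide context
        def uv_ok(p: int) -> bool:
            if seq[p - 1] != "C":
                return False
            left = seq[p - 2] if p >= 2 else ""
            right = seq[p] if p < len(seq) else ""
            return left in "CT" or right in "CT"
        return uv_ok

    def draw_snv(self, cls: RegionClass) -> tuple[int, str, str]:
        pos = self._take(self.pools[cls], predicate=self._spectrum_predicate())
        ref = self.seq[pos - 1]
        return pos, ref, self._snv_alt(ref)

    def draw_indel(self, cls: RegionClass) -> tuple[int, str, str]:
        length = int(self.rng.integers(1, 7))
        if self.rng.random() < 0.5:  # insertion
            pos = self._take(self.pools[cls], span=2)
            anchor = self.seq[pos - 1]
            ins = "".join(self.rng.choice(list(_BASES), length))
            return pos, anchor, anchor + ins
        pos = self._take(self.pools[cls], span=length + 1)
        return pos, self.seq[pos - 1 : pos + length], self.seq[pos - 1]

    # --- targeted coding draws --------------------------------------------

    def coding_consequence(self, model, pos: int, alt: str) -> CodingConsequence:
        """SNV consequence by full-CDS retranslation (simulator-side call)."""
        cds = extract_cds(model, self.genome)
        idx = model.cds_position(pos)
        base = alt if model.strand == "+" else reverse_complement(alt)
        ci = idx // 3
        mutant_codon = (
            cds[ci * 3 : idx] + base + cds[idx + 1 : ci * 3 + 3]
        )
        ref_aa = translate_codon(cds[ci * 3 : ci * 3 + 3])
        alt_aa = translate_codon(mutant_codon)
        if ref_aa == alt_aa:
            return CodingConsequence.SYNONYMOUS_SNV
        if alt_aa == "*":
            return CodingConsequence.STOP_GAIN
        if ref_aa == "*":
            return CodingConsequence.STOP_LOSS
        return CodingConsequence.NONSYNONYMOUS_SNV

    def draw_coding_snv(
        self, want: CodingConsequence, gene_id: str | None = None
    ) -> tuple[int, str, str, str]:
        """SNV in a CDS engineered to have consequence ``want``."""
        gene_ids = [gene_id] if gene_id else list(self.gene_cds_pos)
        for _ in range(50_000):
            gid = gene_ids[int(self.rng.integers(0, len(gene_ids)))]
            positions = self.gene_cds_pos[gid]
            pos = positions[int(self.rng.integers(0, len(positions)))]
            if not self._free(pos, pos):
                continue
            ref = self.seq[pos - 1]
            model = self.model_by_id[gid]
            found = None
            for alt in (b for b in _BASES if b != ref):
                if self.coding_consequence(model, pos, alt) is want:
                    found = alt
                    break
            if found is None:
                continue
            self._reserve(pos, pos)
            return pos, ref, found, gid
        raise ConfigError(f"could not engineer a {want.value} SNV")

    def draw_frameshift(self, gene_id: str) -> tuple[int, str, str]:
        """1- or 2-bp insertion strictly inside the gene's CDS."""
        model = self.model_by_id[gene_id]
        interior = [
            p for p in self.gene_cds_pos[gene_id]
            if any(s <= p < e for s, e in model.cds_segments)
        ]
        for _ in range(20_000):
            pos = interior[int(self.rng.integers(0, len(interior)))]
            if not self._free(pos, pos + 1):
                continue
            anchor = self.seq[pos - 1]
            length = int(self.rng.integers(1, 3))
            ins = "".join(self.rng.choice(list(_BASES), length))
            self._reserve(pos, pos + 1)
            return pos, anchor, anchor + ins
        raise ConfigError(f"could not place frameshift in {gene_id}")


def _choose_category(rng) -> RegionClass:
    classes = list(_CATEGORY_WEIGHTS)
    probs = np.array([_CATEGORY_WEIGHTS[c] for c in classes])
    return classes[int(rng.choice(len(classes), p=probs / probs.sum()))]


def simulate_cohort(
    config: SimulationConfig, out_dir: str | None = None
) -> tuple[GenomeSequence, dict[str, list[GeneModel]], dict[str, list[Variant]], pd.DataFrame]:
    """Generate the full synthetic cohort and its truth table.

    Returns (genome, models, per-line variant lists, truth DataFrame);
    when ``out_dir`` is given also writes FASTA, GFF3, one VCF per line
    and the truth TSV there. Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    genome, models = simulate_genome(config, rng)
    planter = _Planter(config, genome, models, rng)
    contig = config.contig_name
    line_ids = [f"SIM{i + 1:04d}" for i in range(config.n_lines)]

    truth_rows: list[dict] = []
    per_line: dict[str, list[tuple]] = {lid: [] for lid in line_ids}

    def gene_near(pos: int) -> str | None:
        for m in planter.models:
            s, e = m.span
            if s - config.flank_window <= pos <= e + config.flank_window:
                return m.gene_id
        return None

    def planted_region(pos, ref, alt) -> RegionClass:
        if len(ref) == 1 and len(alt) == 1:
            lo = hi = pos
        elif len(ref) > len(alt):
            lo, hi = pos + 1, pos + len(ref) - 1
        else:
            lo, hi = pos, pos + 1
        return _CODE_TO_CLASS[int(planter.codes[lo - 1 : hi].min())]

    def add(pos, ref, alt, lines, kind, region, consequence, gene_id, metrics,
            is_causal=False):
        passes = evaluate_variant(metrics, FilterThresholds()).passed
        truth_rows.append({
            "contig": contig, "pos": pos, "ref": ref, "alt": alt,
            "lines": ";".join(lines), "n_lines": len(lines), "kind": kind,
            "region": region.value if region else ".",
            "consequence": consequence.value if consequence else ".",
            "gene_id": gene_id or ".",
            "passes_filter": passes,
            "is_causal": is_causal,
        })
        for lid in lines:
            per_line[lid].append((pos, ref, alt, metrics))

    def maybe_failing_metrics():
        if rng.random() < config.fail_fraction:
            return _draw_failing_metrics(rng)
        return _draw_passing_metrics(rng)

    # universal background: in every line, one shared metrics draw so the
    # variant's filter verdict is uniform across the cohort
    for _ in range(config.n_background_universal):
        pos, ref, alt = planter.draw_snv(_choose_category(rng))
        region = planted_region(pos, ref, alt)
        gid = None if region is RegionClass.INTERGENIC else gene_near(pos)
        cons = None
        if region is RegionClass.EXONIC:
            model = next(
                m for m in planter.models if m.cds_position(pos) is not None
            )
            gid, cons = model.gene_id, planter.coding_consequence(model, pos, alt)
        add(pos, ref, alt, line_ids, "background", region, cons, gid,
            maybe_failing_metrics())

    # recurrent decoys: exonic nonsynonymous in 3..n-1 lines, passing metrics
    for _ in range(config.n_recurrent_decoys):
        pos, ref, alt, gid = planter.draw_coding_snv(
            CodingConsequence.NONSYNONYMOUS_SNV
        )
        k = int(rng.integers(3, config.n_lines))
        carriers = sorted(rng.choice(line_ids, size=k, replace=False).tolist())
        add(pos, ref, alt, carriers, "recurrent_decoy", RegionClass.EXONIC,
            CodingConsequence.NONSYNONYMOUS_SNV, gid, _draw_passing_metrics(rng))

    # causal loss-of-function: one per line in a line-unique gene, always passing
    gene_ids = list(planter.gene_cds_pos)
    if config.n_lines > len(gene_ids):
        raise ConfigError("need at least one unique gene per line for causal planting")
    causal_genes = rng.choice(gene_ids, size=config.n_lines, replace=False)
    for lid, gid in zip(line_ids, causal_genes):
        planted = False
        if rng.random() < 0.5:
            try:
                pos, ref, alt, _ = planter.draw_coding_snv(
                    CodingConsequence.STOP_GAIN, gene_id=gid
                )
                add(pos, ref, alt, [lid], "causal", RegionClass.EXONIC,
                    CodingConsequence.STOP_GAIN, gid,
                    _draw_passing_metrics(rng), is_causal=True)
                planted = True
            except ConfigError:
                planted = False
        if not planted:
            pos, ref, alt = planter.draw_frameshift(gid)
            add(pos, ref, alt, [lid], "causal", RegionClass.EXONIC,
                CodingConsequence.FRAMESHIFT_INDEL, gid,
                _draw_passing_metrics(rng), is_causal=True)

    # line-private variants, including guaranteed synonymous exonic decoys
    for lid in line_ids:
        for _ in range(config.n_synonymous_decoys_per_line):
            pos, ref, alt, gid = planter.draw_coding_snv(
                CodingConsequence.SYNONYMOUS_SNV
            )
            add(pos, ref, alt, [lid], "synonymous_decoy", RegionClass.EXONIC,
                CodingConsequence.SYNONYMOUS_SNV, gid, _draw_passing_metrics(rng))
        n_general = config.n_private_per_line - config.n_synonymous_decoys_per_line
        for _ in range(n_general):
            cls = _choose_category(rng)
            if rng.random() < config.indel_fraction:
                pos, ref, alt = planter.draw_indel(cls)
            else:
                pos, ref, alt = planter.draw_snv(cls)
            region = planted_region(pos, ref, alt)
            gid = None if region is RegionClass.INTERGENIC else gene_near(pos)
            cons = None
            if region is RegionClass.EXONIC:
                if len(ref) == 1 and len(alt) == 1:
                    model = next(
                        m for m in planter.models if m.cds_position(pos) is not None
                    )
                    gid, cons = (
                        model.gene_id,
                        planter.coding_consequence(model, pos, alt),
                    )
                else:
                    gid, cons = _indel_consequence(planter, pos, ref, alt)
            add(pos, ref, alt, [lid], "private", region, cons, gid,
                maybe_failing_metrics())

    truth = (
        pd.DataFrame(truth_rows)
        .sort_values(["pos", "alt"], kind="mergesort")
        .reset_index(drop=True)
    )
    cohort = {
        lid: [
            Variant(contig, pos, ref, alt, lid, metrics)
            for pos, ref, alt, metrics in sorted(per_line[lid])
        ]
        for lid in line_ids
    }
    if out_dir is not None:
        write_outputs(genome, models, cohort, truth, out_dir)
    return genome, models, cohort, truth


def _indel_consequence(planter, pos, ref, alt):
    """Intended frameshift/non-frameshift call for an exonic-planted indel."""
    for m in planter.models:
        if len(ref) > len(alt):
            lo, hi = pos + 1, pos + len(ref) - 1
            n = sum(max(0, min(hi, e) - max(lo, s) + 1) for s, e in m.cds_segments)
        else:
            touches = any(
                s <= p <= e for p in (pos, pos + 1) for s, e in m.cds_segments
            )
            n = len(alt) - 1 if touches else 0
        if n > 0:
            cons = (
                CodingConsequence.NONFRAMESHIFT_INDEL
                if n % 3 == 0
                else CodingConsequence.FRAMESHIFT_INDEL
            )
            return m.gene_id, cons
    return None, CodingConsequence.UNKNOWN


def write_outputs(genome, models, cohort, truth, out_dir: str) -> None:
    """Write FASTA, GFF3, per-line VCFs and the truth TSV (deterministic)."""
    os.makedirs(out_dir, exist_ok=True)
    write_genome(genome, os.path.join(out_dir, "genome.fa"))
    write_gff3(models, os.path.join(out_dir, "genes.gff3"))
    for lid, variants in cohort.items():
        write_vcf(variants, os.path.join(out_dir, f"{lid}.vcf"), genome.lengths)
    truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryReport:
    per_line: pd.DataFrame  # line_id, causal_gene, recovered, rank
    surviving_decoys: dict[str, int] = field(default_factory=dict)

    @property
    def n_recovered(self) -> int:
        return int(self.per_line["recovered"].sum())

    @property
    def n_lines(self) -> int:
        return len(self.per_line)


def evaluate_recovery(
    candidates_by_line: dict[str, list], truth: pd.DataFrame
) -> RecoveryReport:
    """Score candidate output against the truth table.

    Reports, per line, whether the planted causal gene appears among that
    line's candidates and at what rank; counts surviving decoys by kind
    (expected zero for background, recurrent and synonymous decoys).
    Raises when candidate line ids are absent from the truth (outputs from
    a different run).
    """
    truth_lines: set[str] = set()
    for ls in truth["lines"]:
        truth_lines.update(ls.split(";"))
    missing = set(candidates_by_line) - truth_lines
    if missing:
        raise ValueError(f"candidate lines not present in truth: {sorted(missing)}")

    rows = []
    for _, trow in truth[truth["is_causal"]].iterrows():
        lid = trow["lines"]
        rank = None
        for i, cg in enumerate(candidates_by_line.get(lid, []), start=1):
            if cg.gene_id == trow["gene_id"]:
                rank = i
                break
        rows.append({
            "line_id": lid,
            "causal_gene": trow["gene_id"],
            "recovered": rank is not None,
            "rank": rank if rank is not None else -1,
        })
    per_line = pd.DataFrame(
        rows, columns=["line_id", "causal_gene", "recovered", "rank"]
    ).sort_values("line_id").reset_index(drop=True)

    decoy_keys = {
        kind: set(
            truth.loc[truth["kind"] == kind, ["contig", "pos", "ref", "alt"]]
            .itertuples(index=False, name=None)
        )
        for kind in ("background", "recurrent_decoy", "synonymous_decoy")
    }
    surviving = {kind: 0 for kind in decoy_keys}
    for cands in candidates_by_line.values():
        for cg in cands:
            for av in cg.variants:
                for kind, keys in decoy_keys.items():
                    if av.variant.key in keys:
                        surviving[kind] += 1
    return RecoveryReport(per_line, surviving)
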