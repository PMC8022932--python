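# Methods

## Problem and model

A forward genetic screen mutagenizes independent clonal lines of
*Arthrobotrys oligospora* (EMS or UV), selects lines with a phenotype
(defective nematode-trap formation), and resequences each line against
the wild-type reference assembly. The analysis problem is to isolate,
per line, the small set of genes plausibly carrying the causal mutation
from a callset of a few thousand variants. The package models this as a
four-stage deterministic pipeline over per-line VCFs:

hard filter → effect annotation → cohort background removal →
recurrence filtering and loss-of-function ranking.

No statistical inference is involved; every stage is a rule with
explicit parameters, so correctness is established by oracle equivalence
and planted-truth recovery rather than by estimation accuracy.

## Hard filter

Seven exclusion expressions over the caller's site annotations
(GATK-style): QD < 2.0, MQ < 40.0, QUAL < 100, MQRankSum < −12.5,
SOR > 4.0, FS > 60.0, ReadPosRankSum < −8.0. Decisions:

- **Strict inequalities, boundary values pass.** The expressions are
  removal conditions; a variant is removed only when one is true.
- **Absent annotations never fail.** Rank-sum statistics are undefined
  at sites without both allele classes; treating absence as failure
  would discard most genuine calls.
- **One threshold set for SNVs and indels.** The two variant classes
  are filtered identically; per-class thresholds would be a trivial
  extension but are not part of the modeled procedure.

All seven thresholds are overridable (API and CLI).

## Effect annotation

Coordinates are GFF3/VCF 1-based inclusive throughout; there is no
internal coordinate translation. One transcript per gene is kept (the
longest-CDS mRNA when several exist), because the downstream taxonomy is
per-gene, not per-isoform.

Region classes partition every genomic position. Where overlapping
genes (or a gene and a neighbor's flank) disagree, precedence decides:
exonic > utr5 > utr3 > intronic > upstream > downstream > intergenic.
Flanks are strand-aware windows off each end of the gene span; the
default `flank_window` of 1000 bp is the conventional gene-based
annotator default, since the modeled study does not state one. Ties
between two genes supplying the same class go to the lexicographically
smaller gene id (deterministic, logged nowhere else).

Indels are classified over their affected interval — deleted bases for a
deletion (anchor excluded), the two flanking bases for an insertion — and
take the highest-precedence class of any overlapped base, so an indel
reaching into a CDS from outside counts as exonic. This maximizes
sensitivity for the loss-of-function candidates the screen seeks.

Coding consequences: SNVs mutate the affected codon (reassembled across
CDS segment junctions, reverse-complemented for minus-strand genes) and
compare translations under the standard genetic code — synonymous,
nonsynonymous, stop-gain, or stop-loss. Indels count coding bases
added/removed; a multiple of 3 is non-frameshift, anything else
frameshift. Choices on degenerate inputs:

- A codon containing N yields `unknown`; such variants are excluded
  from exonic subtype counts *and* from the exonic column itself so the
  summary partition identity always holds.
- Genes whose total CDS length is not a multiple of 3 are kept for
  region classification but excluded from consequence calls.
- `stop_loss` is a first-class API value but folds into
  `nonsynonymous_snv` in summary tables, whose subtype list is closed.
- Intronic positions within 2 bp of a CDS boundary carry an internal
  splice flag but are reported as intronic; the report taxonomy has no
  splicing category.
- MNVs and symbolic alleles are out of scope (skipped with a warning on
  read); indel left-normalization is not performed — inputs are assumed
  caller-normalized, as the simulator's are.

## Cohort analysis

Two recurrence rules operate at different stages, with different
rationales:

- **Background removal** drops variants present in *all* lines. These
  are pre-existing differences between the mutagenized parent clone and
  the sequenced reference clone. A variant in n−1 of n lines survives
  this stage.
- **Candidate recurrence** excludes variants present in more than
  `max_recurrence` lines (default 2): independent mutagenesis rarely
  hits the same site, so recurrent variants are systematic artifacts.
  "Occurrence" counts distinct lines, not copies.

Variant identity across lines is the exact key (contig, pos, ref, alt).

Candidates are exonic, non-synonymous (`drop_synonymous` default true),
low-recurrence variants grouped by gene; genes rank by the most severe
consequence under the order stop_gain > frameshift > non-frameshift >
stop_loss > nonsynonymous, ties broken by gene id. The candidate-gene
count for a line under a one-variant-per-gene reading is exonic minus
synonymous; when several surviving variants hit one gene the gene is
counted once, so real data can diverge from that arithmetic.

The published per-line count table this package uses as a worked-example
fixture (`screenvar.screen_data`) stores only the independent categories;
exonic and total are always recomputed. One published row (TWF1041) is
internally inconsistent — its five exonic subtypes sum to 18 against a
printed exonic of 17 — and the tests assert that discrepancy explicitly
rather than reproducing the typo.

## Synthetic cohort generator

The simulator emulates the statistical structure the pipeline assumes,
at two scales. Desk scale (the default, used by the test suite): a
100 kb single-contig genome, 20 non-overlapping ORF genes on both
strands (ATG start, in-frame stop, no internal stops, 0–2 introns,
5′/3′ UTRs), 15 lines, 200 private variants per line. Fidelity scale
(`SimulationConfig.fidelity_scale()`, used by the acceptance script): a
1 Mb genome, 150 genes, ~2700 mutations per line, matching the per-line
callset size the modeled screen reports. Structure per line:

- 50 universal background variants shared by every line, each with one
  metrics draw reused across lines so its filter verdict is uniform —
  matching the fact that background divergence yields the same call in
  every sample;
- 10 recurrent decoys: exonic nonsynonymous SNVs planted in 3..n−1
  lines with passing metrics, so the recurrence rule (not the quality
  filter) is what must remove them;
- one causal loss-of-function variant per line — a stop-gain SNV or a
  1–2 bp frameshift insertion — in a line-unique gene, always with
  passing metrics;
- 5 guaranteed synonymous exonic decoys per line;
- private variants spread over all region categories
  (weights: exonic 0.25, intergenic 0.22, upstream 0.16, downstream
  0.14, intronic 0.12, utr5 0.06, utr3 0.05), 12% indels of length 1–6.

SNV spectra: EMS draws G:C→A:T transitions with probability 0.9 (a
literature-standard EMS spectrum; the modeled study reports dose, not
spectrum) and other substitutions otherwise; UV draws C→T at
pyrimidine-dinucleotide contexts. Both are configurable.

Quality metrics for failing calls (`fail_fraction`, default 0.2,
applied to background and private variants) pick one criterion uniformly
and draw its value beyond threshold with a safety margin, leaving the
others comfortable (QD 20–35, MQ 55–60, QUAL 300–3000, rank sums ±2,
SOR 0.5–2, FS 0–5). The generator tests filter logic, not caller
realism: margins keep verdicts unambiguous under VCF float32 storage.

Planted variants reserve their affected genomic intervals globally, so
identity keys never collide by accident and cross-line recurrence counts
are exact by construction. Intended region/consequence labels come from
an exhaustive per-position precedence scan and codon retranslation
implemented independently of the interval-tree annotator, which is what
makes truth-versus-annotation agreement a real test.

What the simulator does **not** model, and hence what passing tests do
not show about real data: read-level errors and alignment artifacts
(metrics are drawn, not computed from reads), heterokaryotic mixtures of
nuclei that can mask mutations, multi-isoform genes, left-unnormalized
indel representations, and MNVs. Recovery of 15/15 planted causal genes
demonstrates the filters' logic, not sensitivity on real callsets.

## Numerical and I/O choices

- VCF INFO floats are stored as 32-bit by htslib and printed at ~6
  significant digits; the writer rounds metrics to 4 decimals, and
  round-trip tests compare at 1e-4 relative tolerance. Identity keys
  round-trip exactly.
- All outputs (FASTA, GFF3, VCF, TSVs, reports) are byte-deterministic
  for a fixed seed/config: fixed headers, no timestamps, sorted
  iteration everywhere.
- The acceptance script runs the fidelity-scale cohort once and the
  desk-scale determinism check twice; problem sizes (15 lines × ~2750
  calls; 1 Mb genome) were chosen as the smallest configuration that
  matches the modeled screen's per-line callset size.

## Known limitations

- Region precedence fixes one answer for genuinely ambiguous overlaps
  (e.g. a variant upstream of one gene and downstream of another is
  upstream); a different convention would shift flank-category counts.
- Candidate ranking covers coding variants only; lines whose causal
  mutation is non-coding (the modeled screen had two) surface with an
  empty or short candidate list rather than a noncoding ranking.
- The GFF3 reader expects gene/mRNA/CDS/UTR features with ID/Parent
  attributes; GTF and fuzzy-coordinate dialects are unsupported.
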