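# Methods

## Coordinates and formats

All genomic intervals are 0-based half-open internally; GTF/GFF3 I/O is
1-based inclusive, converted only at the file boundary. Half-open
intervals make every overlap length `max(0, min(ends) − max(starts))`
with no ±1 special cases. Strand-unknown records (`.`) are rejected,
never guessed: the antisense taxonomy is meaningless without strand.
Both GFF3 (`ID`/`Parent`) and GTF (`gene_id`/`transcript_id`) dialects
are accepted for the annotation; exons of multiple mRNAs of one gene are
unioned into the gene model.

## Candidate classification

Labels are assigned by a fixed decision sequence, so every candidate
receives exactly one label and gate counts always partition the input:
annotated-coding → sense overlap → length < 200 nt → ORF > 100 aa →
FPKM<sub>max</sub> < 1 → antisense overlap ≥ 50 nt (NAT) / = 0 (lincRNA)
/ in between (sub-threshold reject). All published gates are inclusive
at the boundary (200 nt, 100 aa, 50 nt, FPKM 1.0 all pass).

**ORF scanning** replaces an external trained gene-finder with a
deterministic longest-ORF scan: all three frames of the sense strand of
the spliced transcript, ATG to first in-frame stop, length in amino
acids excluding the stop. The filter needs only an upper bound on coding
potential, and the 100-aa rule is the published criterion; a trained
model could remove borderline candidates this scan keeps, which is the
main behavioural difference. `require_stop=false` counts
open-ended 3′ ORFs for sensitivity analysis. Scanning is
sense-strand-only (3 frames, not 6): transcript orientation is known
from strand-specific sequencing, and an antisense ORF belongs to the
opposite transcript.

**Overlap length** is exonic by default (candidate exons × gene exons);
a span mode measures candidate exons against the gene body instead. The
stricter exonic reading is the default because physical sense–antisense
pairing happens between mature transcripts.

**Overlap geometry** always uses spans: head/tail classification is
about transcript termini, which are span properties. "Fully overlapped"
covers both containment directions (NAT within gene body and the
converse); the direction is recorded separately (`containment`) so the
two cases remain distinguishable in reports. For partial overlaps the
overlap region provably contains exactly one terminus of each
transcript; both 5′ termini ⇒ head-to-head, both 3′ ⇒ tail-to-tail, and
a mixed combination triggers an assertion (it is geometrically
impossible for antisense transcripts and would indicate a coordinate
bug).

**Cognate assignment** under multi-gene overlap: maximal antisense
overlap, ties broken by smaller span-midpoint distance, then
lexicographically smallest gene id. A NAT is classified once, against
its cognate only; secondary overlaps still count toward genome NAT
coverage (fraction of genes with any qualifying antisense NAT).

## Expression statistics

Replicates are pooled before DE: the two most correlated replicate
columns per condition are summed (counts) or averaged (FPKM), with a
warning when their Pearson correlation is below 0.9. FPKM is
`count · 10⁹ / (library_total · exonic_length)` on the pooled values.

Fisher's exact test operates on fragment counts as the 2×2 table
`[[c₁, N₁−c₁], [c₂, N₂−c₂]]`; the two-sided p sums all tables with the
observed margins whose point probability does not exceed the observed
one (the same convention as `scipy.stats.fisher_exact`; implemented via
the vectorised hypergeometric pmf, and cross-checked in the tests
against both exact enumeration and scipy). When only FPKM is supplied
the p gate is disabled and DE falls back to fold change only, with a
loud warning — this degrades the published two-gate criterion and is
intended for noise-free debugging, not analysis.

Fold change uses a 0.1-FPKM pseudocount on both terms, applied **only
when either term is below the pseudocount**: well-measured ratios stay
exact (so a 10 → 20 FPKM change is exactly 2.0 and passes the ≥ 2
gate), while zero-FPKM denominators cannot produce infinities. The
magnitude sits at the detection floor set by the FPKM ≥ 1 filter.

The Pi-response pattern evaluates four contrasts (P4 vs C4, P8 vs C8,
R4 vs P4, R4 vs C4). "Return to control levels" on resupply is
operationalised as an OR of two readings: R4 down relative to the
depleted level (R4 vs P4 DOWN) or R4 back at control (R4 vs C4
UNCHANGED). The mirrored rules give the down-responsive pattern. If
both arms fire simultaneously (up in one depletion contrast, down in
the other — a pathological profile), the up arm takes precedence; this
tie cannot occur for the planted synthetic profiles.

Pair correlation uses the five pooled per-condition FPKM values
(n = 5), on raw FPKM; a log₂(FPKM+1) mode exists. Replicate-level PCC
is used only for pooling QC. The r² ≥ 0.6 threshold is inclusive. Pairs
with a constant profile on either side are skipped and logged (a
constant series has no defined correlation). No multiple-testing
correction is applied by default, matching the published two-gate
criterion; a Benjamini–Hochberg column is available via `--bh`.

Group comparisons between transcript categories report both Welch's
unequal-variance t and Mann–Whitney U (two-sided). A literally paired
test between populations of unequal, unmatched sizes is undefined; the
two unpaired tests assess the same claim, that the distributions
differ.

## Synthetic data: the stated world

Defaults: 20 single-exon protein-coding genes (900–1500 nt,
codon-aligned, each painted with a complete ORF of ≥ 299 aa) on one
chromosome; 10 NATs (4 fully overlapped, 3 head-to-head, 3
tail-to-tail, 350–900 nt, overlap ≥ 60 nt); 5 lincRNAs; 8 decoys, two
per reject class (150 nt; planted 120-aa ORF; FPKM<sub>max</sub> 0.5;
30 nt overlap). All 10 NATs are Pi-responsive (6 up, 4 down) with a
four-fold planted effect at P4/P8 returning to baseline at R4; 6
concordant and 3 discordant pairs are planted by giving the cognate
mRNA the same or the opposite direction; the tenth responsive NAT's
mRNA stays flat, so no pair forms (and, noise permitting, its constant
profile is skipped rather than correlated).

Counts are negative-binomial (dispersion 10 — mid-range for bulk
RNA-seq biological replicates) around
`FPKM · length · library/10⁹` with one million fragments per library
and 2 replicates per condition; `noise: none` uses the rounded means
directly, which makes full-pipeline recovery of every planted label
exact and is the basis of the zero-noise acceptance test. Baseline
FPKMs are log-uniform: 30–150 for responsive transcripts (so a
four-fold effect is unambiguous at this depth — at the low end of that
range a four-fold *drop* still leaves ~5 pooled fragments, enough for
the Fisher gate), 5–50 otherwise. Background GC is 45%, coding codons
are drawn at 55%, echoing the lower GC of noncoding transcripts.

Noncoding loci are rejection-sampled (fresh bases from the same seeded
stream) until the planted transcript's sense-strand ORF is ≤ 100 aa, so
no NAT or lincRNA accidentally trips the coding gate; the 120-aa decoy
ORF is planted in the decoy's non-overlapping portion so it never
corrupts the host gene's CDS. A `multi_exon` flag splits each gene into
two codon-aligned exons around a 120-nt intron to exercise the exonic
overlap mode.

What the generator does **not** emulate: read-level artefacts (FASTQ,
mapping bias, positional coverage), assembly fragmentation, overlapping
gene models, trans-NATs, intronic lncRNAs, more than one chromosome,
and realistic expression-vs-length correlations. A green recovery test
therefore establishes that the decision rules and statistics are
implemented correctly on well-formed inputs, not that the pipeline is
robust to assembly noise.

Determinism: every draw flows from `numpy.random.default_rng` seeded
from the config (layout and counts use separate substreams), so a fixed
config yields byte-identical FASTA/GFF3/GTF/TSV outputs.

## Known limitations

* FPKM-only input disables the exact-test gate (warned, see above).
* The candidate's ORF gate needs the genome; without FASTA the gate is
  skipped (geometry-only classification).
* Coverage counts genes with any qualifying antisense NAT; it does not
  weight by overlap extent.
* The five-point correlation behind pair detection has very low power;
  the inclusive r² gate is a published convention, not an inference
  procedure.
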