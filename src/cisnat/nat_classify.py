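"""Candidate filtering and the antisense overlap taxonomy.

Assembled transcripts are partitioned into NATs (natural antisense
transcripts), lincRNAs and rejects by a fixed decision sequence, and each
NAT is classified against its cognate protein-coding gene as fully
overlapped, head-to-head (5'/5' partial overlap, divergent geometry) or
tail-to-tail (3'/3' partial overlap, convergent geometry).

Published cutoffs (all inclusive where stated as such):

* candidate length >= 200 nt
* predicted ORF <= 100 amino acids
* antisense overlap with an annotated gene model >= 50 nt
* maximum FPKM across samples >= 1 (transcripts with FPKMmax < 1 excluded)

Overlap length is exonic by default (candidate exons x gene exons); a
span mode measures candidate exons against the gene body instead.  The
head/tail classification always uses spans: the geometry is about
transcript termini, which are span properties.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import ExpressionTable, GeneModel, GenomicInterval, Transcript, ValidationError

__all__ = [
    "CandidateLabel",
    "OverlapClass",
    "NATCall",
    "Thresholds",
    "antisense_overlap_nt",
    "sense_overlap_nt",
    "classify_candidate",
    "overlap_class",
    "assign_cognate_gene",
    "genome_nat_coverage",
]


class CandidateLabel(str, enum.Enum):
    NAT = "NAT"
    LINCRNA = "LINCRNA"
    REJECT_ANNOTATED = "REJECT_ANNOTATED"
    REJECT_SHORT = "REJECT_SHORT"
    REJECT_ORF = "REJECT_ORF"
    REJECT_LOW_FPKM = "REJECT_LOW_FPKM"
    REJECT_SENSE_OVERLAP = "REJECT_SENSE_OVERLAP"
    REJECT_SUBTHRESHOLD_OVERLAP = "REJECT_SUBTHRESHOLD_OVERLAP"


class OverlapClass(str, enum.Enum):
    FULL = "FULL"
    HEAD_TO_HEAD = "HEAD_TO_HEAD"
    TAIL_TO_TAIL = "TAIL_TO_TAIL"


@dataclass(frozen=True)
class NATCall:
    """A classified NAT: its cognate gene, overlap length and geometry."""

    nat_id: str
    cognate_gene_id: str
    overlap_nt: int
    overlap_class: OverlapClass
    #: for FULL calls, which span contains which ("nat_in_gene" or
    #: "gene_in_nat"); None for partial overlaps
    containment: Optional[str] = None


@dataclass(frozen=True)
class Thresholds:
    """Every published cutoff in one auditable record."""

    min_length_nt: int = 200
    max_orf_aa: int = 100
    min_overlap_nt: int = 50
    min_fpkm_max: float = 1.0
    de_fold: float = 2.0
    de_p: float = 0.05
    pair_r2: float = 0.6
    fc_pseudocount: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "min_length_nt",
            "max_orf_aa",
            "min_overlap_nt",
            "min_fpkm_max",
            "de_fold",
            "de_p",
            "pair_r2",
            "fc_pseudocount",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        if self.de_fold <= 1:
            raise ValidationError("de_fold must exceed 1")
        if not (0 < self.de_p < 1):
            raise ValidationError("de_p must lie in (0, 1)")
        if not (0 < self.pair_r2 <= 1):
            raise ValidationError("pair_r2 must lie in (0, 1]")


def _exonic_overlap(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> int:
    # both exon lists are sorted and internally disjoint, so the sum of
    # pairwise intersections is the true per-base intersection
    total = 0
    for ea in a:
        for eb in b:
            total += max(0, min(ea.end, eb.end) - max(ea.start, eb.start))
    return total


def antisense_overlap_nt(
    candidate: Transcript, gene: GeneModel, mode: str = "exonic"
) -> int:
    """Per-base overlap between a candidate and a gene on the opposite
    strand; 0 for a different chromosome or the same strand."""
    if candidate.chrom != gene.chrom or candidate.strand == gene.strand:
        return 0
    if mode == "exonic":
        return _exonic_overlap(candidate.exons, gene.exons)
    if mode == "span":
        return _exonic_overlap(candidate.exons, [gene.span])
    raise ValueError(f"unknown overlap mode {mode!r}")


def sense_overlap_nt(candidate: Transcript, gene: GeneModel, mode: str = "exonic") -> int:
    """Per-base exonic overlap with a gene on the *same* strand."""
    if candidate.chrom != gene.chrom or candidate.strand != gene.strand:
        return 0
    if mode == "span":
        return _exonic_overlap(candidate.exons, [gene.span])
    return _exonic_overlap(candidate.exons, gene.exons)


def classify_candidate(
    candidate: Transcript,
    genes: Sequence[GeneModel],
    expr: Optional[ExpressionTable],
    th: Thresholds = Thresholds(),
    orf_aa: Optional[int] = None,
    mode: str = "exonic",
) -> CandidateLabel:
    """Assign exactly one label to an assembled candidate.

    Decision sequence (first failing gate wins):

    0. annotated as protein coding -> REJECT_ANNOTATED
    1. exonic overlap with any gene on the same strand -> REJECT_SENSE_OVERLAP
    2. spliced length < min_length_nt -> REJECT_SHORT
    3. longest ORF > max_orf_aa -> REJECT_ORF
    4. FPKMmax < min_fpkm_max (or candidate absent from the expression
       table) -> REJECT_LOW_FPKM
    5. max antisense overlap >= min_overlap_nt -> NAT
    6. zero antisense overlap with every gene -> LINCRNA
    7. otherwise (0 < overlap < min) -> REJECT_SUBTHRESHOLD_OVERLAP

    ``orf_aa`` is the precomputed longest-ORF length of the candidate
    (see :func:`cisnat.transcript_model.longest_orf_aa`); when None the
    ORF gate is skipped, which is only appropriate for geometry-only
    tests.  ``expr`` must hold FPKM values; a None table likewise skips
    the abundance gate.
    """
    if candidate.source_class == "annotated_coding":
        return CandidateLabel.REJECT_ANNOTATED
    if any(sense_overlap_nt(candidate, g, mode=mode) > 0 for g in genes):
        return CandidateLabel.REJECT_SENSE_OVERLAP
    if candidate.spliced_length < th.min_length_nt:
        return CandidateLabel.REJECT_SHORT
    if orf_aa is not None and orf_aa > th.max_orf_aa:
        return CandidateLabel.REJECT_ORF
    if expr is not None:
        if candidate.transcript_id not in expr.values.index:
            return CandidateLabel.REJECT_LOW_FPKM
        fpkm_max = float(expr.values.loc[candidate.transcript_id].max())
        if fpkm_max < th.min_fpkm_max:
            return CandidateLabel.REJECT_LOW_FPKM
    best = max(
        (antisense_overlap_nt(candidate, g, mode=mode) for g in genes), default=0
    )
    if best >= th.min_overlap_nt:
        return CandidateLabel.NAT
    if best == 0:
        return CandidateLabel.LINCRNA
    return CandidateLabel.REJECT_SUBTHRESHOLD_OVERLAP


def overlap_class(nat: Transcript, gene: GeneModel) -> OverlapClass:
    """Geometry of an antisense overlap, from the two spans.

    FULL when either span contains the other (the containment direction
    is reported separately by :func:`containment_direction`).  For
    partial overlaps the overlap region contains exactly one terminus of
    each transcript: both 5' termini -> HEAD_TO_HEAD, both 3' termini ->
    TAIL_TO_TAIL.  Any other combination is geometrically impossible for
    antisense transcripts on a line and raises.
    """
    n, g = nat.span, gene.span
    if g.contains(n) or n.contains(g):
        return OverlapClass.FULL
    lo, hi = max(n.start, g.start), min(n.end, g.end)
    if lo >= hi:
        raise ValidationError(
            f"{nat.transcript_id} and {gene.gene_id} do not overlap"
        )

    def within(pos: int) -> bool:
        return lo <= pos < hi

    heads = within(n.five_prime()) and within(g.five_prime())
    tails = within(n.three_prime()) and within(g.three_prime())
    if heads == tails:
        raise AssertionError(
            "mixed 5'/3' overlap for an antisense pair: coordinate bug "
            f"({nat.transcript_id} vs {gene.gene_id})"
        )
    return OverlapClass.HEAD_TO_HEAD if heads else OverlapClass.TAIL_TO_TAIL


def containment_direction(nat: Transcript, gene: GeneModel) -> Optional[str]:
    """For FULL overlaps, whether the NAT lies within the gene body
    ("nat_in_gene") or contains it ("gene_in_nat"); ties (equal spans)
    report "nat_in_gene"."""
    n, g = nat.span, gene.span
    if g.contains(n):
        return "nat_in_gene"
    if n.contains(g):
        return "gene_in_nat"
    return None


def assign_cognate_gene(
    nat: Transcript,
    genes: Sequence[GeneModel],
    th: Thresholds = Thresholds(),
    mode: str = "exonic",
) -> NATCall:
    """Pick the cognate gene for a NAT among all qualifying overlaps.

    The cognate is the gene with maximum antisense overlap; ties are
    broken by smaller distance between span midpoints, then by
    lexicographically smallest gene_id.
    """
    qualifying = []
    nspan = nat.span
    for g in genes:
        ov = antisense_overlap_nt(nat, g, mode=mode)
        if ov >= th.min_overlap_nt:
            gspan = g.span
            mid_dist = abs((nspan.start + nspan.end) - (gspan.start + gspan.end))
            qualifying.append((-ov, mid_dist, g.gene_id, ov, g))
    if not qualifying:
        raise ValidationError(
            f"{nat.transcript_id}: no gene with antisense overlap >= "
            f"{th.min_overlap_nt} nt; caller must label first"
        )
    qualifying.sort(key=lambda t: t[:3])
    _, _, _, ov, gene = qualifying[0]
    return NATCall(
        nat_id=nat.transcript_id,
        cognate_gene_id=gene.gene_id,
        overlap_nt=ov,
        overlap_class=overlap_class(nat, gene),
        containment=containment_direction(nat, gene),
    )


def genome_nat_coverage(
    nats: Sequence[Transcript],
    genes: Sequence[GeneModel],
    th: Thresholds = Thresholds(),
    mode: str = "exonic",
) -> float:
    """Percentage of annotated genes overlapped antisense by at least one
    NAT at >= min_overlap_nt (cognate or secondary overlap alike)."""
    if not genes:
        raise ValidationError("gene list is empty")
    covered = 0
    for g in genes:
        if any(
            antisense_overlap_nt(n, g, mode=mode) >= th.min_overlap_nt for n in nats
        ):
            covered += 1
    return 100.0 * covered / len(genes)
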