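"""Sequence-level computations on transcripts.

Spliced-sequence extraction, GC content, and open-reading-frame length
prediction.  The ORF scanner is the coding-potential gate for the lncRNA
filters: a candidate whose longest sense-strand ORF exceeds 100 amino
acids is treated as potentially coding and rejected.

The scanner is deliberately simple and deterministic: it searches the
sense strand of the spliced transcript in all three frames for
ATG...stop spans and reports the longest, counted in amino acids and
excluding the stop codon.  Transcript orientation is known from
strand-specific sequencing, so the three reverse-strand frames belong to
the opposite transcript and are not scanned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

from Bio.Seq import Seq

from .io_formats import Transcript, ValidationError

__all__ = ["SplicedSequence", "OrfResult", "spliced_sequence", "gc_content", "longest_orf_aa"]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID_BASES = frozenset("ACGTN")


class UndefinedValueError(ValueError):
    """The requested statistic is undefined for this input."""


@dataclass(frozen=True)
class SplicedSequence:
    """The mature (spliced) sequence of a transcript, 5'->3' in transcript
    orientation."""

    transcript_id: str
    sequence: str


@dataclass(frozen=True)
class OrfResult:
    """Longest open reading frame found on the sense strand.

    ``max_orf_aa`` counts translated amino acids (Met included, stop
    excluded); ``frame`` and ``start_offset`` locate the ATG.  A sequence
    with no complete ORF has ``max_orf_aa == 0`` and undefined position
    fields (both -1).
    """

    max_orf_aa: int
    frame: int = -1
    start_offset: int = -1


def spliced_sequence(
    transcript: Transcript, genome: Mapping[str, Union[str, object]]
) -> SplicedSequence:
    """Extract the spliced transcript sequence from a genome.

    Exon sequences are concatenated in genomic order; for minus-strand
    transcripts the concatenation is reverse-complemented as a whole, so
    the result reads 5'->3' in transcript orientation.  ``genome`` may be
    a plain dict of strings or a ``pyfaidx.Fasta``-like mapping.
    """
    chrom = transcript.chrom
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} absent from genome")
    chrom_seq = genome[chrom]
    chrom_len = len(chrom_seq)
    parts = []
    for exon in transcript.exons:
        if exon.end > chrom_len:
            raise ValidationError(
                f"transcript {transcript.transcript_id}: exon [{exon.start},"
                f"{exon.end}) outside {chrom!r} (length {chrom_len})"
            )
        parts.append(str(chrom_seq[exon.start : exon.end]).upper())
    seq = "".join(parts)
    if transcript.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return SplicedSequence(transcript_id=transcript.transcript_id, sequence=seq)


def gc_content(sequence: str) -> float:
    """GC percentage in [0, 100]; N bases are excluded from both numerator
    and denominator."""
    seq = sequence.upper()
    _check_bases(seq)
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise UndefinedValueError("GC content undefined for empty or all-N sequence")
    return 100.0 * gc / acgt


def _check_bases(seq: str) -> None:
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValidationError(f"invalid nucleotide characters: {sorted(bad)}")


def longest_orf_aa(sequence: str, require_stop: bool = True) -> OrfResult:
    """Longest sense-strand ORF, in amino acids excluding the stop codon.

    Scans all three forward frames for ATG...stop spans (stop = TAA, TAG
    or TGA).  Codons containing N never match ATG or a stop.  With
    ``require_stop=False`` an ATG still open at the 3' end counts its
    complete codons to the end of the sequence (sensitivity mode).
    """
    seq = sequence.upper()
    _check_bases(seq)
    n = len(seq)
    best = OrfResult(0)
    for frame in range(3):
        open_start = None  # earliest ATG since the last in-frame stop
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if open_start is None and codon == "ATG":
                open_start = pos
            elif open_start is not None and codon in STOP_CODONS:
                aa = (pos - open_start) // 3
                if aa > best.max_orf_aa:
                    best = OrfResult(aa, frame, open_start)
                open_start = None
            pos += 3
        if open_start is not None and not require_stop:
            aa = (pos - open_start) // 3
            if aa > best.max_orf_aa:
                best = OrfResult(aa, frame, open_start)
    return best
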