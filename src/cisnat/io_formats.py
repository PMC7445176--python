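"""Readers and writers for the standard formats the pipeline touches.

All genomic coordinates are held internally as 0-based, half-open
intervals; GTF/GFF3 files on disk are 1-based with inclusive ends and the
conversion happens only at the I/O boundary.  Half-open intervals make
every overlap length ``max(0, min(ends) - max(starts))`` with no off-by-one
special cases.

Strand-unknown records (strand ``.``) are rejected rather than guessed:
the antisense taxonomy is strand-specific by construction, so a transcript
without a strand cannot be classified.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

__all__ = [
    "CONDITIONS",
    "GenomicInterval",
    "Transcript",
    "GeneModel",
    "ExpressionTable",
    "ValidationError",
    "ParseError",
    "read_gtf",
    "write_gtf",
    "read_gene_models",
    "read_expression_table",
    "read_fasta",
]

#: The five physiological states: control day 4, phosphate-depleted day 4,
#: phosphate-depleted day 8, phosphate-resupplied day 4, control day 8.
CONDITIONS = ("C4", "P4", "P8", "R4", "C8")

STRANDS = ("+", "-")


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(
                f"strand must be one of {STRANDS}, got {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_nt(self, other: "GenomicInterval") -> int:
        """Per-base intersection length, ignoring strand."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def five_prime(self) -> int:
        """Position of the 5' terminus (transcription start) on this strand."""
        return self.start if self.strand == "+" else self.end - 1

    def three_prime(self) -> int:
        """Position of the 3' terminus (transcription end) on this strand."""
        return self.end - 1 if self.strand == "+" else self.start


def _validate_exons(exons: Sequence[GenomicInterval], owner: str) -> None:
    if not exons:
        raise ValidationError(f"{owner}: needs at least one exon")
    chroms = {e.chrom for e in exons}
    strands = {e.strand for e in exons}
    if len(chroms) > 1:
        raise ValidationError(f"{owner}: exons on multiple chromosomes {chroms}")
    if len(strands) > 1:
        raise ValidationError(f"{owner}: exons on mixed strands")
    for a, b in zip(exons, exons[1:]):
        if b.start < a.end:
            raise ValidationError(
                f"{owner}: exons not sorted/disjoint: [{a.start},{a.end}) then "
                f"[{b.start},{b.end})"
            )


@dataclass(frozen=True)
class Transcript:
    """A stranded, possibly multi-exon transcribed unit.

    ``source_class`` distinguishes reference protein-coding transcripts
    (``annotated_coding``) from newly assembled units (``assembled_novel``);
    only the latter enter the lncRNA candidate filters.
    """

    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    gene_id: Optional[str] = None
    source_class: str = "assembled_novel"

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(sorted(self.exons, key=lambda e: e.start)))
        _validate_exons(self.exons, f"transcript {self.transcript_id}")
        if self.source_class not in ("annotated_coding", "assembled_novel"):
            raise ValidationError(
                f"transcript {self.transcript_id}: bad source_class "
                f"{self.source_class!r}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    """An annotated protein-coding locus against which antisense overlap
    is measured."""

    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(sorted(self.exons, key=lambda e: e.start)))
        _validate_exons(self.exons, f"gene {self.gene_id}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        """Gene body: hull from the first exon start to the last exon end."""
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass
class ExpressionTable:
    """Per-sample expression values (fragment counts or FPKM) with
    condition/replicate tags.

    ``values`` is a transcripts x samples DataFrame.  ``sample_map`` tags
    every column with ``(condition, replicate)``.  When ``kind == 'counts'``
    each sample must declare its total mapped fragments in
    ``library_totals``.
    """

    values: pd.DataFrame
    sample_map: Mapping[str, tuple[str, int]]
    kind: str = "counts"
    library_totals: Optional[Mapping[str, int]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "fpkm"):
            raise ValidationError(f"kind must be counts or fpkm, got {self.kind!r}")
        unmapped = [c for c in self.values.columns if c not in self.sample_map]
        if unmapped:
            raise ValidationError(f"columns without sample_map entry: {unmapped}")
        for col, (cond, _rep) in self.sample_map.items():
            if cond not in CONDITIONS:
                raise ValidationError(
                    f"sample {col!r}: unknown condition {cond!r} "
                    f"(expected one of {CONDITIONS})"
                )
        if self.values.isna().any().any():
            raise ValidationError("expression table contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")
        if self.kind == "counts":
            if self.library_totals is None:
                raise ValidationError("counts tables require per-sample library totals")
            for col in self.values.columns:
                tot = self.library_totals.get(col)
                if tot is None or tot <= 0:
                    raise ValidationError(
                        f"sample {col!r}: positive library total required"
                    )

    def samples_for(self, condition: str) -> list[str]:
        return [
            c for c in self.values.columns if self.sample_map[c][0] == condition
        ]

    @property
    def conditions(self) -> list[str]:
        seen = []
        for c in self.values.columns:
            cond = self.sample_map[c][0]
            if cond not in seen:
                seen.append(cond)
        return seen


# ---------------------------------------------------------------------------
# GTF / GFF3
# ---------------------------------------------------------------------------

def _parse_feature(line: str, lineno: int, path):
    if len(line.split("\t")) != 9:
        raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
    try:
        return feature_from_line(line)
    except Exception as exc:  # gffutils raises a mix of error types
        raise ParseError(f"{path}:{lineno}: malformed record: {exc}") from exc


def _first_attr(feature, *keys: str) -> Optional[str]:
    for key in keys:
        vals = feature.attributes.get(key)
        if vals:
            return vals[0]
    return None


def read_gtf(path) -> list[Transcript]:
    """Read assembled transcripts from a GTF file.

    Exon records are grouped by ``transcript_id``; coordinates are
    converted from GTF's 1-based inclusive convention to the internal
    0-based half-open one.  Non-exon feature rows (e.g. ``transcript``)
    are ignored.  A ``source_class`` attribute, when present, is honoured;
    the default is ``assembled_novel``.
    """
    path = Path(path)
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[Optional[str], str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = _parse_feature(line, lineno, path)
            if feat.featuretype != "exon":
                continue
            if feat.strand not in STRANDS:
                raise ValidationError(
                    f"{path}:{lineno}: strand {feat.strand!r} not allowed; "
                    "the pipeline is strand-specific"
                )
            if feat.end < feat.start:
                raise ValidationError(f"{path}:{lineno}: end < start")
            tid = _first_attr(feat, "transcript_id", "Parent")
            if tid is None:
                raise ParseError(f"{path}:{lineno}: exon without transcript_id")
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            exons_by_tx.setdefault(tid, []).append(iv)
            if tid not in meta:
                order.append(tid)
                meta[tid] = (
                    _first_attr(feat, "gene_id"),
                    _first_attr(feat, "source_class") or "assembled_novel",
                )
    transcripts = []
    for tid in order:
        gene_id, source_class = meta[tid]
        transcripts.append(
            Transcript(
                transcript_id=tid,
                exons=tuple(exons_by_tx[tid]),
                gene_id=gene_id,
                source_class=source_class,
            )
        )
    return transcripts


def write_gtf(
    transcripts: Iterable[Transcript],
    path,
    extra_attributes: Optional[Mapping[str, Mapping[str, str]]] = None,
    source: str = "cisnat",
    header: Optional[str] = None,
) -> None:
    """Write transcripts as GTF (1-based inclusive coordinates), one exon
    feature per exon.

    ``extra_attributes`` maps transcript_id to extra key/value attribute
    pairs (e.g. ``overlap_class``, ``cognate_gene``) appended to each line.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(header if header is not None else "##gtf; coordinates 1-based inclusive\n")
        for tx in transcripts:
            attrs = [
                f'gene_id "{tx.gene_id or tx.transcript_id}"',
                f'transcript_id "{tx.transcript_id}"',
                f'source_class "{tx.source_class}"',
            ]
            if extra_attributes and tx.transcript_id in extra_attributes:
                for k, v in extra_attributes[tx.transcript_id].items():
                    attrs.append(f'{k} "{v}"')
            attr_str = "; ".join(attrs) + ";"
            for exon in tx.exons:
                fh.write(
                    "\t".join(
                        [
                            exon.chrom,
                            source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand,
                            ".",
                            attr_str,
                        ]
                    )
                    + "\n"
                )


def read_gene_models(path, coding_only: bool = True) -> list[GeneModel]:
    """Read protein-coding gene models from GFF3 or GTF.

    GFF3 files are expected to carry gene / mRNA / exon features linked by
    ``ID``/``Parent``; GTF files need only exon features with a ``gene_id``
    attribute.  Features whose ``biotype`` (or ``gene_biotype``) is not
    ``protein_coding``, and non-gene feature types such as ``ncRNA_gene``,
    are excluded when ``coding_only`` is set.
    """
    path = Path(path)
    exons_by_parent: dict[str, list[GenomicInterval]] = {}
    parent_of: dict[str, str] = {}  # mRNA ID -> gene ID
    gene_ids: list[str] = []
    gene_biotype: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = _parse_feature(line, lineno, path)
            ftype = feat.featuretype
            if ftype == "gene":
                gid = _first_attr(feat, "ID", "gene_id")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: gene without ID")
                if gid in gene_biotype:
                    raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
                gene_ids.append(gid)
                gene_biotype[gid] = (
                    _first_attr(feat, "biotype", "gene_biotype") or "protein_coding"
                )
            elif ftype in ("mRNA", "transcript"):
                tid = _first_attr(feat, "ID", "transcript_id")
                parent = _first_attr(feat, "Parent", "gene_id")
                if tid and parent:
                    parent_of[tid] = parent
            elif ftype == "exon":
                if feat.strand not in STRANDS:
                    raise ValidationError(f"{path}:{lineno}: strand-less exon")
                parent = _first_attr(feat, "Parent", "gene_id")
                if parent is None:
                    raise ParseError(f"{path}:{lineno}: exon without Parent/gene_id")
                iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
                exons_by_parent.setdefault(parent, []).append(iv)
            # other feature types (ncRNA_gene, CDS, ...) are ignored here
    # resolve exons attached to mRNAs up to their gene
    exons_by_gene: dict[str, list[GenomicInterval]] = {}
    for parent, exons in exons_by_parent.items():
        gid = parent_of.get(parent, parent)
        exons_by_gene.setdefault(gid, []).extend(exons)
    if not gene_ids:  # bare GTF without gene feature rows
        gene_ids = sorted(exons_by_gene)
    genes = []
    for gid in gene_ids:
        if coding_only and gene_biotype.get(gid, "protein_coding") != "protein_coding":
            continue
        exons = exons_by_gene.get(gid)
        if not exons:
            raise ValidationError(f"gene {gid!r} has no exon records")
        merged = _merge_exons(sorted(exons, key=lambda e: (e.start, e.end)))
        genes.append(GeneModel(gene_id=gid, exons=tuple(merged)))
    return genes


def _merge_exons(exons: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union overlapping exon intervals (several mRNAs of one gene)."""
    merged: list[GenomicInterval] = []
    for e in exons:
        if merged and e.start <= merged[-1].end:
            last = merged[-1]
            if e.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, e.end, last.strand)
        else:
            merged.append(e)
    return merged


# ---------------------------------------------------------------------------
# Expression tables and FASTA
# ---------------------------------------------------------------------------

def read_expression_table(
    path,
    sample_map: Mapping[str, tuple[str, int]],
    kind: str = "counts",
    library_totals: Optional[Mapping[str, int]] = None,
) -> ExpressionTable:
    """Read a TSV of expression values (transcripts x samples).

    The first column is the transcript identifier.  ``sample_map`` must
    tag every data column with a ``(condition, replicate)`` pair.  Missing
    cells are an error: the pipeline performs no imputation.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ExpressionTable(
        values=df, sample_map=sample_map, kind=kind, library_totals=library_totals
    )


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-record, line-wrapped) FASTA into an uppercase dict."""
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
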