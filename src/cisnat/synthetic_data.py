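"""Seeded synthetic stranded-transcriptome generator with planted truth.

Emits a complete input set — genome FASTA, protein-coding annotation
(GFF3), assembled-transcript GTF, fragment-count tables over the five
phosphate states with replicates — plus a ground-truth table, so every
pipeline stage is testable without any download.

The stated world (defaults):

* 20 single-exon protein-coding genes on one chromosome, each with a
  planted ORF well above the 100-amino-acid coding gate;
* 10 antisense NATs — 4 fully overlapped, 3 head-to-head, 3 tail-to-tail
  — each overlapping its host gene by >= 50 nt on the opposite strand;
* 5 intergenic lincRNAs clear of every gene;
* 8 decoys, two per reject class: 150 nt (too short), a planted 120-aa
  ORF (too coding), FPKMmax 0.5 (too scarce), 30 nt overlap (below the
  50 nt gate);
* all 10 NATs phosphate responsive (6 up, 4 down) with a planted
  four-fold effect at P4/P8 returning to baseline at R4; 6 concordant
  and 3 discordant NAT-mRNA pairs (the tenth responsive NAT's mRNA stays
  flat, so no pair forms);
* negative-binomial fragment counts (dispersion 10) over 2 replicates
  per condition at one million mapped fragments per library.  With
  ``noise="none"`` counts equal the rounded planted means, giving exact
  pipeline recovery of every planted label.

Noncoding loci are rejection-sampled until their sense-strand ORF stays
at or below 100 amino acids, so no planted noncoding transcript
accidentally trips the coding gate.  Everything derives from
``numpy.random.default_rng`` seeded from the config: the same config
yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import (
    CONDITIONS,
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    Transcript,
    ValidationError,
    write_fasta,
    write_gtf,
)
from .transcript_model import longest_orf_aa

__all__ = ["SimConfig", "SimulatedDataset", "simulate_genome", "simulate_annotation", "simulate_counts", "simulate_dataset", "write_dataset"]

_STOPS = ("TAA", "TAG", "TGA")
_COMP = str.maketrans("ACGTN", "TGCAN")


class ConfigurationError(ValueError):
    pass


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Declarative description of one synthetic dataset."""

    seed: int = 0
    n_genes: int = 20
    n_nats_full: int = 4
    n_nats_hh: int = 3
    n_nats_tt: int = 3
    n_lincrnas: int = 5
    n_decoys_short: int = 2
    n_decoys_orf: int = 2
    n_decoys_low_fpkm: int = 2
    n_decoys_subthreshold: int = 2
    replicates: int = 2
    library_size: int = 1_000_000
    dispersion: float = 10.0
    noise: str = "nb"  # "nb" or "none" (noise-free debug mode)
    effect_fold: float = 4.0
    n_responsive_up: int = 6
    n_responsive_down: int = 4
    n_pairs_concordant: int = 6
    n_pairs_discordant: int = 3
    gc_noncoding: float = 45.0
    gc_coding: float = 55.0
    chrom_name: str = "chr1"
    min_chrom_len: int = 0
    multi_exon: bool = False
    # baseline FPKM draw ranges (log-uniform); responsive transcripts sit
    # higher so the planted effect is detectable at the default library size
    baseline_fpkm_responsive: tuple[float, float] = (30.0, 150.0)
    baseline_fpkm_other: tuple[float, float] = (5.0, 50.0)
    decoy_low_fpkm: float = 0.5

    def __post_init__(self) -> None:
        counts = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name.startswith(("n_",))
        }
        if any(v < 0 for v in counts.values()):
            raise ConfigurationError("all counts must be non-negative")
        if self.noise not in ("nb", "none"):
            raise ConfigurationError("noise must be 'nb' or 'none'")
        if self.replicates < 2:
            raise ConfigurationError("need at least 2 replicates per condition")
        hosts = (
            self.n_nats
            + self.n_decoys_short
            + self.n_decoys_orf
            + self.n_decoys_low_fpkm
            + self.n_decoys_subthreshold
        )
        if hosts > self.n_genes:
            raise ConfigurationError(
                f"infeasible packing: {hosts} gene-hosted features but only "
                f"{self.n_genes} genes"
            )
        if self.n_responsive_up + self.n_responsive_down > self.n_nats:
            raise ConfigurationError("more responsive NATs than NATs")
        if self.n_pairs_concordant + self.n_pairs_discordant > (
            self.n_responsive_up + self.n_responsive_down
        ):
            raise ConfigurationError("more planted pairs than responsive NATs")
        if self.effect_fold <= 1:
            raise ConfigurationError("effect_fold must exceed 1")

    @property
    def n_nats(self) -> int:
        return self.n_nats_full + self.n_nats_hh + self.n_nats_tt


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    transcripts: list[Transcript]
    truth: pd.DataFrame
    expression: Optional[ExpressionTable] = None


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, gc_pct: float) -> str:
    g = gc_pct / 200.0
    a = (100.0 - gc_pct) / 200.0
    return "".join(rng.choice(list("ACGT"), size=n, p=[a, g, g, a]))


def _random_codons(rng: np.random.Generator, n: int, gc_pct: float) -> str:
    """n random non-stop codons near the requested GC."""
    out = []
    while len(out) < n:
        codon = _random_bases(rng, 3, gc_pct)
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _cds(rng: np.random.Generator, n_codons: int, gc_pct: float) -> str:
    """A complete coding sequence of exactly ``n_codons`` codons:
    ATG + (n_codons - 2) non-stop codons + TAA, i.e. an ORF of
    ``n_codons - 1`` amino acids."""
    return "ATG" + _random_codons(rng, n_codons - 2, gc_pct) + "TAA"


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

_MARGIN = 1500  # slot margin on each side of a gene, hosts NAT extensions


@dataclass
class _Locus:
    gene_id: str
    strand: str
    gene_len: int
    hosted: Optional[str] = None  # FULL / HH / TT / short / orf / low / sub
    hosted_id: Optional[str] = None
    nat_len: int = 0
    ov: int = 0
    offset: int = 0  # for contained features: start offset inside the gene


def _plan_loci(cfg: SimConfig, rng: np.random.Generator) -> list[_Locus]:
    roles = (
        ["FULL"] * cfg.n_nats_full
        + ["HH"] * cfg.n_nats_hh
        + ["TT"] * cfg.n_nats_tt
        + ["short"] * cfg.n_decoys_short
        + ["orf"] * cfg.n_decoys_orf
        + ["low"] * cfg.n_decoys_low_fpkm
        + ["sub"] * cfg.n_decoys_subthreshold
    )
    loci = []
    nat_i = linc_i = 0
    counters = {"short": 0, "orf": 0, "low": 0, "sub": 0}
    for i in range(cfg.n_genes):
        gene_len = int(rng.integers(300, 501)) * 3  # 900..1500, codon-aligned
        strand = "+" if rng.random() < 0.5 else "-"
        locus = _Locus(gene_id=f"g{i + 1:03d}", strand=strand, gene_len=gene_len)
        if i < len(roles):
            role = roles[i]
            locus.hosted = role
            if role in ("FULL", "HH", "TT"):
                nat_i += 1
                locus.hosted_id = f"nat{nat_i:03d}"
            else:
                counters[role] += 1
                locus.hosted_id = f"decoy_{role}{counters[role]:02d}"
            if role == "FULL":
                locus.nat_len = int(rng.integers(350, min(901, gene_len - 20)))
                locus.offset = int(rng.integers(1, gene_len - locus.nat_len))
            elif role in ("HH", "TT"):
                locus.nat_len = int(rng.integers(350, 901))
                hi = min(locus.nat_len - 60, gene_len - 60, 400)
                locus.ov = int(rng.integers(60, hi + 1))
            elif role == "short":
                locus.nat_len = 150
                locus.offset = int(rng.integers(1, gene_len - 151))
            elif role == "orf":
                locus.nat_len = 500
                locus.ov = 60
            elif role == "low":
                locus.nat_len = int(rng.integers(350, min(701, gene_len - 20)))
                locus.offset = int(rng.integers(1, gene_len - locus.nat_len))
            elif role == "sub":
                locus.nat_len = 300
                locus.ov = 30
        loci.append(locus)
    return loci


def _partial_interval(
    gs: int, ge: int, gene_strand: str, end: str, ov: int, ext: int
) -> tuple[int, int]:
    """Interval of an antisense transcript overlapping ``ov`` nt at the
    gene's 5' ("head") or 3' ("tail") end and extending ``ext`` nt beyond."""
    at_left = (gene_strand == "+") == (end == "head")
    if at_left:
        return gs - ext, gs + ov
    return ge - ov, ge + ext


def _build(cfg: SimConfig) -> SimulatedDataset:
    rng = np.random.default_rng([cfg.seed, 0])
    loci = _plan_loci(cfg, rng)

    chrom_parts: list[str] = []
    pos = 0
    genes: list[GeneModel] = []
    transcripts: list[Transcript] = []
    truth_rows: list[dict] = []
    chrom = cfg.chrom_name
    intron = 120  # codon-aligned, used only in multi-exon mode

    def gene_exons(gs: int, ge: int, strand: str) -> tuple[GenomicInterval, ...]:
        if not cfg.multi_exon:
            return (GenomicInterval(chrom, gs, ge, strand),)
        e1 = 3 * ((ge - gs) // 6)  # codon-aligned split point
        return (
            GenomicInterval(chrom, gs, gs + e1, strand),
            GenomicInterval(chrom, gs + e1 + intron, ge + intron, strand),
        )

    for locus in loci:
        slot_len = _MARGIN + locus.gene_len + (intron if cfg.multi_exon else 0) + _MARGIN
        gs = pos + _MARGIN
        exons = gene_exons(gs, gs + locus.gene_len, locus.strand)
        ge = exons[-1].end  # gene body end (includes the intron if any)
        anti = "-" if locus.strand == "+" else "+"

        # geometry of the hosted antisense feature (in genome coordinates)
        feat_exons: Optional[tuple[GenomicInterval, ...]] = None
        if locus.hosted in ("FULL", "short", "low"):
            # contained within the first exon so exonic overlap is intact
            host = exons[0]
            offset = min(locus.offset, host.length - locus.nat_len - 1)
            offset = max(offset, 1)
            fs = host.start + offset
            feat_exons = (GenomicInterval(chrom, fs, fs + locus.nat_len, anti),)
        elif locus.hosted in ("HH", "TT", "orf", "sub"):
            end = "head" if locus.hosted in ("HH", "orf") else "tail"
            if locus.hosted == "sub":
                end = "tail"
            ext = locus.nat_len - locus.ov
            fs, fe = _partial_interval(gs, ge, locus.strand, end, locus.ov, ext)
            feat_exons = (GenomicInterval(chrom, fs, fe, anti),)

        # sequence for the slot, rejection-sampled so that no planted
        # noncoding transcript carries an ORF above the coding gate
        n_codons = locus.gene_len // 3
        for attempt in range(300):
            slot = list(_random_bases(rng, slot_len, cfg.gc_noncoding))
            cds = _cds(rng, n_codons, cfg.gc_coding)
            # paint the CDS across the exons (intron left noncoding); on the
            # minus strand the genomic text is the reverse complement, laid
            # out so the spliced exon concatenation reads back as the CDS
            genomic_cds = cds if locus.strand == "+" else _revcomp(cds)
            ci = 0
            for exon in exons:
                slot[exon.start - pos : exon.end - pos] = genomic_cds[
                    ci : ci + exon.length
                ]
                ci += exon.length
            if locus.hosted == "orf":
                # plant a 120-aa ORF in the decoy's non-overlapping portion
                orf_seq = _cds(rng, 121, cfg.gc_coding)  # 363 nt, ORF of 120 aa
                fs, fe = feat_exons[0].start, feat_exons[0].end
                sense_start = 110  # transcript-relative, clear of the gene edge
                if anti == "-":
                    g_lo = fe - sense_start - len(orf_seq)
                    slot[g_lo - pos : g_lo - pos + len(orf_seq)] = _revcomp(orf_seq)
                else:
                    g_lo = fs + sense_start
                    slot[g_lo - pos : g_lo - pos + len(orf_seq)] = orf_seq
            slot_seq = "".join(slot)

            if feat_exons is None or locus.hosted in ("short", "orf"):
                break  # nothing to verify (length gate / planted ORF decide)
            sense = "".join(
                slot_seq[e.start - pos : e.end - pos] for e in feat_exons
            )
            if anti == "-":
                sense = _revcomp(sense)
            if longest_orf_aa(sense).max_orf_aa <= 100:
                break
        else:
            raise ConfigurationError(
                f"could not draw an ORF-free sequence for {locus.hosted_id}"
            )

        chrom_parts.append(slot_seq)
        genes.append(GeneModel(gene_id=locus.gene_id, exons=exons))
        transcripts.append(
            Transcript(
                transcript_id=locus.gene_id,
                exons=exons,
                gene_id=locus.gene_id,
                source_class="annotated_coding",
            )
        )
        truth_rows.append(
            {
                "transcript_id": locus.gene_id,
                "category": "MRNA",
                "expected_label": "REJECT_ANNOTATED",
                "overlap_class": "",
                "cognate_gene": "",
                "planted_pattern": "NONE",
                "pair_concordance": "",
                "spliced_length": sum(e.length for e in exons),
            }
        )
        if feat_exons is not None:
            feat_tx = Transcript(
                transcript_id=locus.hosted_id,
                exons=feat_exons,
                source_class="assembled_novel",
            )
            transcripts.append(feat_tx)
            expected = {
                "FULL": "NAT",
                "HH": "NAT",
                "TT": "NAT",
                "short": "REJECT_SHORT",
                "orf": "REJECT_ORF",
                "low": "REJECT_LOW_FPKM",
                "sub": "REJECT_SUBTHRESHOLD_OVERLAP",
            }[locus.hosted]
            cls = {
                "FULL": "FULL",
                "HH": "HEAD_TO_HEAD",
                "TT": "TAIL_TO_TAIL",
            }.get(locus.hosted, "")
            truth_rows.append(
                {
                    "transcript_id": locus.hosted_id,
                    "category": "NAT" if expected == "NAT" else "DECOY",
                    "expected_label": expected,
                    "overlap_class": cls,
                    "cognate_gene": locus.gene_id if expected == "NAT" else "",
                    "planted_pattern": "NONE",
                    "pair_concordance": "",
                    "spliced_length": feat_tx.spliced_length,
                }
            )
        pos += slot_len

    # lincRNAs in gene-free slots
    for i in range(cfg.n_lincrnas):
        length = int(rng.integers(300, 801))
        strand = "+" if rng.random() < 0.5 else "-"
        slot_len = 600 + length + 600
        for attempt in range(300):
            slot_seq = _random_bases(rng, slot_len, cfg.gc_noncoding)
            seq = slot_seq[600 : 600 + length]
            sense = seq if strand == "+" else _revcomp(seq)
            if longest_orf_aa(sense).max_orf_aa <= 100:
                break
        else:
            raise ConfigurationError("could not draw an ORF-free lincRNA")
        chrom_parts.append(slot_seq)
        tid = f"linc{i + 1:03d}"
        transcripts.append(
            Transcript(
                transcript_id=tid,
                exons=(GenomicInterval(chrom, pos + 600, pos + 600 + length, strand),),
                source_class="assembled_novel",
            )
        )
        truth_rows.append(
            {
                "transcript_id": tid,
                "category": "LINCRNA",
                "expected_label": "LINCRNA",
                "overlap_class": "",
                "cognate_gene": "",
                "planted_pattern": "NONE",
                "pair_concordance": "",
                "spliced_length": length,
            }
        )
        pos += slot_len

    genome_seq = "".join(chrom_parts)
    if len(genome_seq) < cfg.min_chrom_len:
        genome_seq += _random_bases(
            rng, cfg.min_chrom_len - len(genome_seq), cfg.gc_noncoding
        )

    truth_columns = [
        "transcript_id",
        "category",
        "expected_label",
        "overlap_class",
        "cognate_gene",
        "planted_pattern",
        "pair_concordance",
        "spliced_length",
    ]
    truth = pd.DataFrame(truth_rows, columns=truth_columns).set_index(
        "transcript_id", drop=False
    )
    _plant_expression_design(cfg, rng, truth)
    return SimulatedDataset(
        config=cfg,
        genome={chrom: genome_seq},
        genes=genes,
        transcripts=transcripts,
        truth=truth,
    )


def _plant_expression_design(
    cfg: SimConfig, rng: np.random.Generator, truth: pd.DataFrame
) -> None:
    """Assign planted response patterns, pair concordance and baseline
    FPKMs in place."""
    nat_ids = list(truth.index[truth["category"] == "NAT"])
    directions = ["UP"] * cfg.n_responsive_up + ["DOWN"] * cfg.n_responsive_down
    responsive = nat_ids[: len(directions)]
    for tid, d in zip(responsive, directions):
        truth.loc[tid, "planted_pattern"] = f"{d}_PI_RESPONSIVE"
    pair_labels = ["CONCORDANT"] * cfg.n_pairs_concordant + [
        "DISCORDANT"
    ] * cfg.n_pairs_discordant
    for tid, conc in zip(responsive, pair_labels):
        gene = truth.loc[tid, "cognate_gene"]
        truth.loc[tid, "pair_concordance"] = conc
        truth.loc[gene, "pair_concordance"] = conc
        nat_dir = truth.loc[tid, "planted_pattern"].split("_")[0]
        if conc == "CONCORDANT":
            gene_dir = nat_dir
        else:
            gene_dir = "DOWN" if nat_dir == "UP" else "UP"
        truth.loc[gene, "planted_pattern"] = f"{gene_dir}_PI_RESPONSIVE"

    lo_r, hi_r = cfg.baseline_fpkm_responsive
    lo_o, hi_o = cfg.baseline_fpkm_other
    baselines = []
    for tid, row in truth.iterrows():
        if row["expected_label"] == "REJECT_LOW_FPKM":
            b = cfg.decoy_low_fpkm
        elif row["planted_pattern"] != "NONE":
            b = float(np.exp(rng.uniform(np.log(lo_r), np.log(hi_r))))
        else:
            b = float(np.exp(rng.uniform(np.log(lo_o), np.log(hi_o))))
        baselines.append(b)
    truth["baseline_fpkm"] = baselines


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> dict[str, str]:
    """Chromosome sequences hosting all planted features."""
    return _build(config).genome


def simulate_annotation(
    config: SimConfig,
) -> tuple[list[GeneModel], list[Transcript], pd.DataFrame]:
    """Gene models, assembled transcripts and the ground-truth table."""
    ds = _build(config)
    return ds.genes, ds.transcripts, ds.truth


def simulate_counts(truth: pd.DataFrame, config: SimConfig) -> ExpressionTable:
    """Fragment-count table over the five conditions with replicates.

    Condition means follow the planted pattern: responsive transcripts
    carry ``effect_fold`` times (up) or one over ``effect_fold`` (down)
    their baseline at P4 and P8, and the baseline at C4, R4 and C8.
    Replicate counts are negative-binomial around the mean (or the
    rounded mean itself with ``noise='none'``).
    """
    rng = np.random.default_rng([config.seed, 1])
    f = config.effect_fold
    multipliers = {
        "UP_PI_RESPONSIVE": {"C4": 1, "P4": f, "P8": f, "R4": 1, "C8": 1},
        "DOWN_PI_RESPONSIVE": {"C4": 1, "P4": 1 / f, "P8": 1 / f, "R4": 1, "C8": 1},
        "NONE": {c: 1 for c in CONDITIONS},
    }
    samples = [
        f"{cond}_r{r + 1}" for cond in CONDITIONS for r in range(config.replicates)
    ]
    data = {}
    for tid, row in truth.iterrows():
        mult = multipliers[row["planted_pattern"]]
        length = int(row["spliced_length"])
        counts = []
        for cond in CONDITIONS:
            mean_fpkm = row["baseline_fpkm"] * mult[cond]
            mean_count = mean_fpkm * length * config.library_size / 1e9
            for _ in range(config.replicates):
                if config.noise == "none":
                    counts.append(int(round(mean_count)))
                elif mean_count == 0:
                    counts.append(0)
                else:
                    r = config.dispersion
                    counts.append(
                        int(rng.negative_binomial(r, r / (r + mean_count)))
                    )
        data[tid] = counts
    values = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    values.index.name = "transcript_id"
    sample_map = {
        s: (s.split("_r")[0], int(s.split("_r")[1])) for s in samples
    }
    totals = {s: config.library_size for s in samples}
    return ExpressionTable(
        values=values, sample_map=sample_map, kind="counts", library_totals=totals
    )


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """One call for the full bundle: genome, annotation, truth, counts."""
    ds = _build(config)
    ds.expression = simulate_counts(ds.truth, config)
    return ds


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write genome.fa, genes.gff3, transcripts.gtf, counts.tsv, truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "genes.gff3",
        "transcripts": outdir / "transcripts.gtf",
        "counts": outdir / "counts.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(ds.genome, paths["genome"])
    _write_gff3(ds.genes, paths["annotation"])
    write_gtf(ds.transcripts, paths["transcripts"])
    expr = ds.expression
    if expr is None:
        expr = simulate_counts(ds.truth, ds.config)
    with open(paths["counts"], "w") as fh:
        fh.write(f"# kind counts\n")
        for s in expr.values.columns:
            fh.write(f"# library_total {s} {expr.library_totals[s]}\n")
        expr.values.to_csv(fh, sep="\t")
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def _write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s = g.span
            fh.write(
                f"{s.chrom}\tcisnat-sim\tgene\t{s.start + 1}\t{s.end}\t.\t"
                f"{s.strand}\t.\tID={g.gene_id};biotype=protein_coding\n"
            )
            fh.write(
                f"{s.chrom}\tcisnat-sim\tmRNA\t{s.start + 1}\t{s.end}\t.\t"
                f"{s.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for e in g.exons:
                fh.write(
                    f"{e.chrom}\tcisnat-sim\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\tParent={g.gene_id}.t1\n"
                )
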