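import numpy as np
import pytest

from cisnat.io_formats import GenomicInterval, GeneModel, Transcript
from cisnat.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def zero_noise_dataset():
    """The default stated world in noise-free debug mode: 20 genes, 4/3/3
    NATs by class, 5 lincRNAs, 8 decoys, 10 responsive NATs, 6+3 pairs."""
    return simulate_dataset(SimConfig(seed=11, noise="none"))


@pytest.fixture(scope="session")
def noisy_dataset():
    return simulate_dataset(SimConfig(seed=11))


def random_exons(rng, chrom="chr1", strand=None, max_coord=10_000, max_exons=3):
    """Sorted, disjoint exons for oracle tests."""
    strand = strand or rng.choice(["+", "-"])
    n = rng.integers(1, max_exons + 1)
    cuts = np.sort(rng.choice(np.arange(1, max_coord), size=2 * n, replace=False))
    exons = []
    for i in range(n):
        s, e = int(cuts[2 * i]), int(cuts[2 * i + 1])
        if e > s:
            exons.append(GenomicInterval(chrom, s, e, strand))
    if not exons:
        exons = [GenomicInterval(chrom, 0, 100, strand)]
    return tuple(exons)


def make_transcript(tid, exons, **kw):
    return Transcript(transcript_id=tid, exons=tuple(exons), **kw)


def make_gene(gid, exons):
    return GeneModel(gene_id=gid, exons=tuple(exons))
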