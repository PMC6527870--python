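import numpy as np
import pytest

from polwave.models import GeneModel, ReadSet


@pytest.fixture
def plus_gene() -> GeneModel:
    """10-kb single-exon plus-strand gene starting at 0."""
    return GeneModel("gA", "gA.t1", "chr1", "+", 0, 10_000, ((0, 10_000),))


@pytest.fixture
def minus_gene() -> GeneModel:
    return GeneModel("gB", "gB.t1", "chr1", "-", 50_000, 62_000, ((50_000, 62_000),))


@pytest.fixture
def two_intron_gene() -> GeneModel:
    """Plus-strand gene with two introns: exons (0,200), (1400,1700), (2800,3000)."""
    return GeneModel(
        "gC", "gC.t1", "chr2", "+", 0, 3000, ((0, 200), (1400, 1700), (2800, 3000))
    )


def make_reads(intervals, strand="+", chrom="chr1", **kw) -> ReadSet:
    """ReadSet from a list of (start, end) on one chrom/strand."""
    n = len(intervals)
    strands = [strand] * n if isinstance(strand, str) else list(strand)
    return ReadSet(
        [chrom] * n,
        [s for s, _ in intervals],
        [e for _, e in intervals],
        strands,
        **kw,
    )


def random_reads(rng: np.random.Generator, n: int, span: int = 10_000, chrom="chr1") -> ReadSet:
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, 200, size=n)
    strands = rng.choice(["+", "-"], size=n)
    return ReadSet([chrom] * n, starts, starts + lengths, strands)


def brute_force_count(reads: ReadSet, chrom, start, end, strand=None) -> int:
    """Exhaustive per-read half-open overlap test (independent oracle)."""
    n = 0
    for r in reads:
        if r.chrom != chrom:
            continue
        if strand is not None and r.strand != strand:
            continue
        if r.start < end and r.end > start:
            n += 1
    return n
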