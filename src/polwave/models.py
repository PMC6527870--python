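"""Core genomic data model.

All coordinates are 0-based half-open (BED convention). ``strand`` is one of
``'+'``, ``'-'``; unstranded regions use ``'.'``. The TSS of a gene is the
first transcribed base: ``start`` on the plus strand, ``end - 1`` on the
minus strand. "TSS+x" offsets are always measured in the direction of
transcription and mirrored genomically for minus-strand genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GeneModel",
    "ReadInterval",
    "ReadSet",
    "Region",
]


@dataclass(frozen=True)
class Region:
    """A genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"region end {self.end} < start {self.start}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReadInterval:
    """A single aligned-read interval (proxy for an aligned read)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"read end {self.end} <= start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid read strand {self.strand!r}")


@dataclass(frozen=True)
class GeneModel:
    """One transcript isoform with strand-aware TSS/TES and exon blocks.

    ``exons`` are non-overlapping, sorted genomic (start, end) blocks
    contained in ``[start, end)``; introns are the gaps between them.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: non-positive length")
        prev = self.start
        for s, e in self.exons:
            if s < prev or e <= s or e > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon ({s},{e}) malformed or outside "
                    f"[{self.start},{self.end}) / overlapping previous block"
                )
            prev = e

    @property
    def tss(self) -> int:
        """Genomic coordinate of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Genomic coordinate of the last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                out.append((e0, s1))
        return tuple(out)

    @property
    def intronic_length(self) -> int:
        return sum(e - s for s, e in self.introns)

    def to_offset(self, genomic: int) -> int:
        """TSS-relative offset (bp, transcription direction) of a genomic position."""
        return genomic - self.start if self.strand == "+" else self.tss - genomic


class ReadSet:
    """A strand-labeled collection of read intervals with library metadata.

    Reads are stored columnar (numpy arrays) and indexed lazily per
    (chrom, strand) for O(log n) half-open overlap counting.
    ``mapped_total`` is the primary-genome mapped-read total used for depth
    normalization; ``spikein_total`` the spike-in genome count (ChIP-RX).
    """

    def __init__(
        self,
        chroms: Sequence[str] | np.ndarray,
        starts: Sequence[int] | np.ndarray,
        ends: Sequence[int] | np.ndarray,
        strands: Sequence[str] | np.ndarray,
        mapped_total: int | None = None,
        spikein_total: int = 0,
        sample_id: str = "",
        condition: str = "",
        metadata: dict | None = None,
    ):
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.strands = np.asarray(strands, dtype=object)
        n = len(self.starts)
        if not (len(self.chroms) == len(self.ends) == len(self.strands) == n):
            raise ValueError("column length mismatch")
        if n and np.any(self.ends <= self.starts):
            raise ValueError("read with end <= start")
        self.mapped_total = int(mapped_total) if mapped_total is not None else n
        if self.mapped_total < n:
            raise ValueError("mapped_total below retained read count")
        self.spikein_total = int(spikein_total)
        if self.spikein_total < 0:
            raise ValueError("negative spikein_total")
        self.sample_id = sample_id
        self.condition = condition
        self.metadata = dict(metadata or {})
        self._index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] | None = None

    @classmethod
    def from_reads(cls, reads: Iterable[ReadInterval], **kw) -> "ReadSet":
        reads = list(reads)
        return cls(
            [r.chrom for r in reads],
            [r.start for r in reads],
            [r.end for r in reads],
            [r.strand for r in reads],
            **kw,
        )

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self) -> Iterator[ReadInterval]:
        for c, s, e, st in zip(self.chroms, self.starts, self.ends, self.strands):
            yield ReadInterval(str(c), int(s), int(e), str(st))

    @property
    def reads(self) -> list[ReadInterval]:
        return list(self)

    def _build_index(self) -> None:
        index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        if len(self):
            chrom_arr = self.chroms.astype(str)
            strand_arr = self.strands.astype(str)
            for chrom in np.unique(chrom_arr):
                on_chrom = chrom_arr == chrom
                for strand in ("+", "-"):
                    mask = on_chrom & (strand_arr == strand)
                    if mask.any():
                        # separately sorted starts and ends: reads overlapping
                        # [a,b) = #(start < b) - #(end <= a), exact half-open
                        index[(str(chrom), strand)] = (
                            np.sort(self.starts[mask]),
                            np.sort(self.ends[mask]),
                        )
        self._index = index

    def count_in(self, chrom: str, start: int, end: int, strand: str | None = None) -> int:
        """Number of reads overlapping [start, end) by >= 1 bp on `strand`
        ('+', '-', or None for both)."""
        if self._index is None:
            self._build_index()
        total = 0
        for st in ("+", "-") if strand is None else (strand,):
            entry = self._index.get((chrom, st))
            if entry is None:
                continue
            starts, ends = entry
            total += int(
                np.searchsorted(starts, end, side="left")
                - np.searchsorted(ends, start, side="right")
            )
        return total

    def count_in_bins(
        self, chrom: str, edges: np.ndarray, strand: str | None = None
    ) -> np.ndarray:
        """Overlap counts for consecutive bins [edges[i], edges[i+1])."""
        if self._index is None:
            self._build_index()
        edges = np.asarray(edges, dtype=np.int64)
        out = np.zeros(len(edges) - 1, dtype=np.int64)
        for st in ("+", "-") if strand is None else (strand,):
            entry = self._index.get((chrom, st))
            if entry is None:
                continue
            starts, ends = entry
            out += np.searchsorted(starts, edges[1:], side="left") - np.searchsorted(
                ends, edges[:-1], side="right"
            )
        return out

    def count_many(
        self,
        chrom: str,
        starts: np.ndarray,
        ends: np.ndarray,
        strand: str | None = None,
    ) -> np.ndarray:
        """Overlap counts for arbitrary (possibly non-contiguous) windows."""
        if self._index is None:
            self._build_index()
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        out = np.zeros(len(starts), dtype=np.int64)
        for st in ("+", "-") if strand is None else (strand,):
            entry = self._index.get((chrom, st))
            if entry is None:
                continue
            rs, re = entry
            out += np.searchsorted(rs, ends, side="left") - np.searchsorted(
                re, starts, side="right"
            )
        return out

    def replace(self, **kw) -> "ReadSet":
        """Copy with selected fields replaced."""
        base = dict(
            chroms=self.chroms,
            starts=self.starts,
            ends=self.ends,
            strands=self.strands,
            mapped_total=self.mapped_total,
            spikein_total=self.spikein_total,
            sample_id=self.sample_id,
            condition=self.condition,
            metadata=self.metadata,
        )
        base.update(kw)
        return ReadSet(**base)

    def subset(self, mask: np.ndarray, mapped_total: int | None = None, **meta) -> "ReadSet":
        md = dict(self.metadata)
        md.update(meta)
        return ReadSet(
            self.chroms[mask],
            self.starts[mask],
            self.ends[mask],
            self.strands[mask],
            mapped_total=mapped_total,
            spikein_total=self.spikein_total,
            sample_id=self.sample_id,
            condition=self.condition,
            metadata=md,
        )
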