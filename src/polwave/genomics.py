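"""Strand-aware region arithmetic, read filtering, and coverage counting.

Overlap semantics throughout: two half-open intervals overlap iff they share
at least one base pair; touching endpoints do not overlap.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np

from .models import GeneModel, ReadSet, Region

__all__ = [
    "filter_reads",
    "count_region",
    "offset_region",
    "coverage_track",
]

_OPPOSITE = {"+": "-", "-": "+"}


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping intervals into disjoint sorted ones."""
    if not intervals:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    arr = np.asarray(merged, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def filter_reads(reads: ReadSet, mask: Iterable[Region]) -> ReadSet:
    """Remove reads overlapping any mask interval by >= 1 bp.

    Mask strand is ignored (masking removes e.g. exonic / rRNA-cluster reads
    regardless of read orientation). ``mapped_total`` is recomputed as the
    retained read count; the policy is recorded in the output metadata.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in mask:
        by_chrom.setdefault(m.chrom, []).append((m.start, m.end))
    if not by_chrom:
        return reads.subset(np.ones(len(reads), dtype=bool), mask_policy="empty-mask")
    keep = np.ones(len(reads), dtype=bool)
    for chrom, ivs in by_chrom.items():
        ms, me = _merge_intervals(ivs)
        sel = reads.chroms.astype(str) == chrom
        if not sel.any():
            continue
        rs = reads.starts[sel]
        re_ = reads.ends[sel]
        # first mask whose end exceeds the read start; overlap iff it also
        # begins before the read end (masks are disjoint and sorted)
        idx = np.searchsorted(me, rs, side="right")
        hit = (idx < len(ms)) & (ms[np.minimum(idx, len(ms) - 1)] < re_)
        out = keep[sel]
        out[hit] = False
        keep[sel] = out
    return reads.subset(
        keep, mask_policy="mapped_total=retained-count; masked reads dropped"
    )


def count_region(reads: ReadSet, region: Region, strand_mode: str = "both") -> int:
    """Count reads overlapping ``region`` by >= 1 bp, filtered by strand.

    ``strand_mode``: 'same' / 'opposite' relative to the region strand, or
    'both'. An unstranded region only supports 'both'.
    """
    if strand_mode not in ("same", "opposite", "both"):
        raise ValueError(f"invalid strand_mode {strand_mode!r}")
    if strand_mode == "both":
        want = None
    else:
        if region.strand == ".":
            raise ValueError("unstranded region requires strand_mode='both'")
        want = region.strand if strand_mode == "same" else _OPPOSITE[region.strand]
    return reads.count_in(region.chrom, region.start, region.end, want)


def offset_region(
    gene: GeneModel,
    from_anchor: str,
    start_offset: int,
    end_offset: int,
    orientation: str = "sense",
) -> Region:
    """Build a genomic window from transcription-direction offsets.

    Offsets are bp downstream of the anchor (TSS or TES) in the direction of
    transcription; negative offsets reach upstream. For minus-strand genes
    the window is mirrored genomically. ``orientation`` sets the region
    strand: sense = gene strand, antisense = opposite. Windows extending past
    the chromosome start are clipped (with a warning).
    """
    if from_anchor not in ("TSS", "TES"):
        raise ValueError(f"invalid anchor {from_anchor!r}")
    if end_offset <= start_offset:
        raise ValueError("empty window: end_offset <= start_offset")
    anchor = gene.tss if from_anchor == "TSS" else gene.tes
    if gene.strand == "+":
        gstart, gend = anchor + start_offset, anchor + end_offset
    else:
        # positional [s,e) downstream of a minus-strand anchor covers genomic
        # bases anchor-s, anchor-s-1, ..., anchor-e+1  ->  [anchor-e+1, anchor-s+1)
        gstart, gend = anchor - end_offset + 1, anchor - start_offset + 1
    if gstart < 0:
        warnings.warn(
            f"window for {gene.gene_id} extends past chromosome start; clipped",
            stacklevel=2,
        )
        gstart = 0
        gend = max(gend, 0)
    strand = gene.strand if orientation == "sense" else _OPPOSITE[gene.strand]
    if orientation not in ("sense", "antisense"):
        raise ValueError(f"invalid orientation {orientation!r}")
    return Region(gene.chrom, gstart, gend, strand)


def coverage_track(
    reads: ReadSet,
    chrom: str,
    bin_size: int,
    chrom_size: int | None = None,
    strand: str | None = None,
) -> np.ndarray:
    """Per-bin overlap counts over a chromosome (bin i = [i*bin, (i+1)*bin)).

    A read overlapping several bins is counted in each. Returns an empty
    track (with a warning) for a chromosome absent from the read set.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    on_chrom = reads.chroms.astype(str) == chrom if len(reads) else np.array([], bool)
    if not on_chrom.any():
        warnings.warn(f"no reads on chromosome {chrom!r}; empty track", stacklevel=2)
        n_bins = int(np.ceil(chrom_size / bin_size)) if chrom_size else 0
        return np.zeros(n_bins, dtype=np.int64)
    span = chrom_size if chrom_size is not None else int(reads.ends[on_chrom].max())
    n_bins = int(np.ceil(span / bin_size))
    edges = np.arange(n_bins + 1, dtype=np.int64) * bin_size
    return reads.count_in_bins(chrom, edges, strand)
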