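"""Reading and writing the plain-text genomic formats used by the pipeline.

BED6 for reads and masks, BED12 or minimal GTF for gene models, bedGraph
for coverage export, TSV for tables. All readers produce 0-based half-open
coordinates (GTF is converted on read); writers re-emit BED records
bit-identically so round-trips are exact.

Gene identity in BED12 is carried in the name field as
``gene_id|transcript_id`` (a bare name is used for both ids).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .models import GeneModel, ReadSet, Region

__all__ = [
    "read_gene_models",
    "write_gene_models_bed12",
    "read_reads_bed6",
    "write_reads_bed6",
    "read_regions_bed",
    "write_bedgraph",
]


class FormatError(ValueError):
    """Malformed record in an input file (message names the line number)."""


def _parse_bed12_line(line: str, lineno: int, path: str) -> GeneModel:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise FormatError(f"{path}:{lineno}: expected 12 BED fields, got {len(f)}")
    try:
        chrom, start, end = f[0], int(f[1]), int(f[2])
        name, strand = f[3], f[5]
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from None
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise FormatError(f"{path}:{lineno}: blockCount does not match block lists")
    exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
    for es, ee in exons:
        if ee > end or es < start:
            raise FormatError(f"{path}:{lineno}: exon block outside transcript")
    gene_id, _, transcript_id = name.partition("|")
    try:
        return GeneModel(
            gene_id=gene_id,
            transcript_id=transcript_id or gene_id,
            chrom=chrom,
            strand=strand,
            start=start,
            end=end,
            exons=exons,
        )
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from None


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _read_gtf(path: Path) -> list[GeneModel]:
    tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF fields")
            if f[2] != "exon":
                continue
            try:
                start, end = int(f[3]) - 1, int(f[4])  # 1-based closed -> half-open
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            attrs = dict(_GTF_ATTR.findall(f[8]))
            tid = attrs.get("transcript_id")
            if tid is None:
                raise FormatError(f"{path}:{lineno}: exon without transcript_id")
            rec = tx.setdefault(
                tid,
                {
                    "gene_id": attrs.get("gene_id", tid),
                    "chrom": f[0],
                    "strand": f[6],
                    "exons": [],
                },
            )
            if rec["chrom"] != f[0] or rec["strand"] != f[6]:
                raise FormatError(f"{path}:{lineno}: transcript {tid} spans chrom/strand")
            rec["exons"].append((start, end))
    models = []
    for tid, rec in tx.items():
        exons = tuple(sorted(rec["exons"]))
        models.append(
            GeneModel(
                gene_id=rec["gene_id"],
                transcript_id=tid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                start=exons[0][0],
                end=exons[-1][1],
                exons=exons,
            )
        )
    return models


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read transcript models from BED12 or minimal GTF (by extension).

    Returns one GeneModel per transcript in deterministic
    (chrom, start, transcript_id) order.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        models = _read_gtf(path)
    else:
        models = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                models.append(_parse_bed12_line(line, lineno, str(path)))
    models.sort(key=lambda g: (g.chrom, g.start, g.transcript_id))
    return models


def write_gene_models_bed12(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in models:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            offs = ",".join(str(s - g.start) for s, e in g.exons) + ","
            name = g.gene_id if g.gene_id == g.transcript_id else f"{g.gene_id}|{g.transcript_id}"
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{name}\t0\t{g.strand}"
                f"\t{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{offs}\n"
            )


def read_reads_bed6(
    path: str | Path,
    mapped_total: int | None = None,
    spikein_total: int = 0,
    sample_id: str = "",
    condition: str = "",
    strand_flip: bool = False,
) -> ReadSet:
    """Read aligned-read intervals from BED6.

    ``strand_flip`` inverts every read strand on import (for dUTP-style
    stranded libraries where the sequenced strand is the opposite of the
    transcript); default off.
    """
    chroms, starts, ends, strands = [], [], [], []
    flip = {"+": "-", "-": "+"}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED fields")
            try:
                starts.append(int(f[1]))
                ends.append(int(f[2]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if f[5] not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: invalid strand {f[5]!r}")
            chroms.append(f[0])
            strands.append(flip[f[5]] if strand_flip else f[5])
    return ReadSet(
        chroms,
        starts,
        ends,
        strands,
        mapped_total=mapped_total,
        spikein_total=spikein_total,
        sample_id=sample_id,
        condition=condition,
        metadata={"strand_flip": strand_flip},
    )


def write_reads_bed6(reads: ReadSet, path: str | Path, name: str = "read") -> None:
    with open(path, "w") as fh:
        for i, (c, s, e, st) in enumerate(
            zip(reads.chroms, reads.starts, reads.ends, reads.strands)
        ):
            fh.write(f"{c}\t{s}\t{e}\t{name}{i}\t0\t{st}\n")


def read_regions_bed(path: str | Path) -> list[Region]:
    """Read mask / window regions from BED3+ (strand used when present)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "."
            out.append(Region(f[0], start, end, strand))
    return out


def write_bedgraph(
    track: np.ndarray | Sequence[float],
    chrom: str,
    bin_size: int,
    path: str | Path,
    mode: str = "w",
) -> None:
    """Write a per-bin track as bedGraph, merging adjacent equal-value bins
    and skipping zero bins."""
    track = np.asarray(track)
    with open(path, mode) as fh:
        i = 0
        n = len(track)
        while i < n:
            v = track[i]
            j = i + 1
            while j < n and track[j] == v:
                j += 1
            if v != 0:
                val = int(v) if float(v).is_integer() else float(v)
                fh.write(f"{chrom}\t{i * bin_size}\t{j * bin_size}\t{val}\n")
            i = j
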