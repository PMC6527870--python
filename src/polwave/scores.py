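"""Per-gene Pol II processivity and directionality scores.

Processivity compares nascent signal far into the gene body with signal just
downstream of the TSS:

    P = log2((distal_reads + k) / (proximal_reads + k))

with pseudo-count k (default 1 read). Two window variants are provided:

* fourSU  — proximal TSS+1..2 kb, distal TSS+5..7 kb, strand-matched reads,
  genes > 8 kb only. Note the distal window is twice as wide, so uniform
  coverage gives P = log2(2) (about 1), not 0; scores are interpreted in
  condition comparisons.
* chip    — proximal TSS+0.5..1.5 kb, distal TES-1 kb..TES+2 kb, unstranded.

Promoter directionality compares genic sense transcription with upstream
antisense transcription:

    D = log2((sense + k) / (antisense + k))

with sense reads counted on the gene strand over TSS..TES and antisense
reads on the opposite strand over 1 kb upstream of the TSS (transcription
direction); genes < 300 bp are excluded. All offsets are mirrored
genomically for minus-strand genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genomics import count_region, offset_region
from .models import GeneModel, ReadSet, Region

__all__ = [
    "ScoreParams",
    "processivity_score",
    "directionality_score",
    "score_table",
    "score_delta",
    "zscore_matrix",
    "metagene_profile",
]

_WINDOWS = {
    # variant -> (proximal (anchor, start, end), distal (anchor, start, end))
    "fourSU": (("TSS", 1000, 2000), ("TSS", 5000, 7000)),
    "chip": (("TSS", 500, 1500), ("TES", -1000, 2000)),
}


@dataclass
class ScoreParams:
    """Windows and constants for the score calculations."""

    variant: str = "fourSU"
    pseudo_count: float = 1.0
    proximal: tuple[str, int, int] | None = None
    distal: tuple[str, int, int] | None = None
    antisense_window: int = 1000  # bp upstream of TSS (1500 per the wider variant)
    min_gene_length: int = 8000  # strict > for processivity
    min_gene_length_directionality: int = 300

    def __post_init__(self) -> None:
        if self.variant not in _WINDOWS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not self.pseudo_count > 0:
            raise ValueError("pseudo_count must be > 0")
        prox, dist = _WINDOWS[self.variant]
        if self.proximal is None:
            self.proximal = prox
        if self.distal is None:
            self.distal = dist


def _window_count(reads: ReadSet, gene: GeneModel, win: tuple[str, int, int], stranded: bool) -> int:
    region = offset_region(gene, win[0], win[1], win[2], orientation="sense")
    return count_region(reads, region, "same" if stranded else "both")


def processivity_score(
    reads: ReadSet, gene: GeneModel, p: ScoreParams
) -> tuple[float, int, int] | None:
    """(P, proximal_count, distal_count), or None when the gene is too short
    for the 4sU windows (skip, not an error)."""
    stranded = p.variant == "fourSU"
    if stranded and gene.length <= p.min_gene_length:
        return None
    prox = _window_count(reads, gene, p.proximal, stranded)
    dist = _window_count(reads, gene, p.distal, stranded)
    k = p.pseudo_count
    return math.log2((dist + k) / (prox + k)), prox, dist


def directionality_score(
    reads: ReadSet, gene: GeneModel, p: ScoreParams
) -> tuple[float, int, int] | None:
    """(D, sense_count, antisense_count), or None for genes < 300 bp."""
    if gene.length < p.min_gene_length_directionality:
        return None
    sense_region = Region(gene.chrom, gene.start, gene.end, gene.strand)
    sense = count_region(reads, sense_region, "same")
    anti_region = offset_region(gene, "TSS", -p.antisense_window, 0, orientation="antisense")
    anti = count_region(reads, anti_region, "same")
    k = p.pseudo_count
    return math.log2((sense + k) / (anti + k)), sense, anti


def score_table(
    reads: ReadSet,
    genes: Sequence[GeneModel],
    params: ScoreParams | None = None,
    condition: str = "",
) -> pd.DataFrame:
    """Score every gene; ineligible genes carry NaN with a skip reason."""
    params = params or ScoreParams()
    rows = []
    for g in genes:
        row = {
            "gene_id": g.gene_id,
            "condition": condition or reads.condition,
            "processivity": np.nan,
            "directionality": np.nan,
            "proximal_count": np.nan,
            "distal_count": np.nan,
            "sense_count": np.nan,
            "antisense_count": np.nan,
            "skip_reason": "",
        }
        res = processivity_score(reads, g, params)
        if res is None:
            row["skip_reason"] = "gene_too_short_for_processivity"
        else:
            row["processivity"], row["proximal_count"], row["distal_count"] = res
        res = directionality_score(reads, g, params)
        if res is not None:
            row["directionality"], row["sense_count"], row["antisense_count"] = res
        elif row["skip_reason"]:
            row["skip_reason"] += ";gene_too_short_for_directionality"
        else:
            row["skip_reason"] = "gene_too_short_for_directionality"
        rows.append(row)
    return pd.DataFrame(rows)


def score_delta(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Per-gene log2 score differences (a minus b) over shared genes."""
    a = table_a.set_index("gene_id")
    b = table_b.set_index("gene_id")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared gene ids between score tables")
    out = pd.DataFrame(
        {
            "delta_processivity": a.loc[shared, "processivity"] - b.loc[shared, "processivity"],
            "delta_directionality": a.loc[shared, "directionality"]
            - b.loc[shared, "directionality"],
        }
    )
    out.index.name = "gene_id"
    return out.reset_index()


def zscore_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise Z scores (sd with n-1); zero-variance rows become all-zero
    and are flagged. Returns (Z, flagged)."""
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 columns for row-wise Z scores")
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flagged = sd[:, 0] == 0
    safe = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / safe
    z[flagged, :] = 0.0
    return (
        pd.DataFrame(z, index=matrix.index, columns=matrix.columns),
        pd.Series(flagged, index=matrix.index, name="zero_variance"),
    )


def _gene_metagene_edges(gene: GeneModel, anchor: str, span: int, bin_size: int):
    """Genomic bin edges for TSS/TES-anchored positional bins -span..+span,
    plus whether the genomic order is flipped relative to positional order."""
    a = gene.tss if anchor == "TSS" else gene.tes
    pos_edges = np.arange(-span, span + bin_size, bin_size, dtype=np.int64)
    if gene.strand == "+":
        return a + pos_edges, False
    return (a - pos_edges + 1)[::-1], True


def metagene_profile(
    readsets: ReadSet | Sequence[ReadSet],
    genes: Sequence[GeneModel],
    anchor: str = "TSS",
    span: int = 7500,
    strand_split: bool = True,
    bin_size: int = 50,
    min_gene_length: int = 0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Average read density around TSS/TES across genes.

    Minus-strand genes are mirrored before averaging, so positive positions
    always point downstream in the direction of transcription. With
    ``strand_split`` sense (gene-strand) and antisense curves are reported
    separately; otherwise a combined curve. ``normalize`` rescales each
    sample to reads-per-million so curves from libraries normalized to
    different totals are comparable.

    Returns a tidy DataFrame: position, sample_id, sense[, antisense].
    """
    if span <= 0:
        raise ValueError("span must be > 0")
    if isinstance(readsets, ReadSet):
        readsets = [readsets]
    use = [g for g in genes if g.length >= min_gene_length]
    if not use:
        raise ValueError("no qualifying genes for metagene profile")
    n_bins = 2 * span // bin_size
    positions = np.arange(-span, span, bin_size) + bin_size // 2
    frames = []
    for si, rs in enumerate(readsets):
        sense = np.zeros(n_bins)
        anti = np.zeros(n_bins)
        opp = {"+": "-", "-": "+"}
        for g in use:
            edges, flipped = _gene_metagene_edges(g, anchor, span, bin_size)
            s_counts = rs.count_in_bins(g.chrom, edges, g.strand)
            a_counts = rs.count_in_bins(g.chrom, edges, opp[g.strand])
            if flipped:
                s_counts = s_counts[::-1]
                a_counts = a_counts[::-1]
            sense += s_counts
            anti += a_counts
        sense /= len(use)
        anti /= len(use)
        if normalize and rs.mapped_total > 0:
            sense *= 1e6 / rs.mapped_total
            anti *= 1e6 / rs.mapped_total
        df = pd.DataFrame({"position": positions, "sample_id": rs.sample_id or f"sample{si}"})
        if strand_split:
            df["sense"] = sense
            df["antisense"] = anti
        else:
            df["density"] = sense + anti
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
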