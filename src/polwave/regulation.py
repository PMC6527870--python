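"""Nascent gene-regulation calls from 4sU read counts.

Gene-level nascent expression is quantified on intronic space only (exonic
reads carry mature-RNA background): intronic read count, normalized for
intronic gene length (kb) and sequencing depth (millions of mapped reads) —
an intronic RPKM. An expression filter keeps genes whose RPKM averaged over
all samples clears a threshold; fold change is the log2 ratio of
replicate-averaged normalized reads (pseudo-count 1) and significance comes
from a per-gene two-sided t-test on log2(normalized + 1) replicate values
with Benjamini-Hochberg adjustment.

The read sets passed in are expected to be exon-masked upstream (pipeline
order: mask, then quantify); counting is restricted to reads overlapping
the gene body on the gene strand.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import GeneModel, ReadSet, Region
from .genomics import count_region
from .stats import bh_adjust, pooled_ttest

__all__ = ["quantify_genes", "expression_filter", "differential"]


def quantify_genes(
    readsets: Sequence[ReadSet], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Intronic RPKM matrix, genes x samples.

    RPKM = intronic reads / (intronic length / 1e3) / (mapped_total / 1e6).
    Genes with zero intronic length are excluded (reported separately via
    the ``attrs['excluded']`` list on the result).
    """
    if not readsets:
        raise ValueError("need >= 1 readset")
    cols = {}
    usable = [g for g in genes if g.intronic_length > 0]
    excluded = [g.gene_id for g in genes if g.intronic_length == 0]
    if excluded:
        warnings.warn(
            f"{len(excluded)} gene(s) with zero intronic length excluded", stacklevel=2
        )
    for i, rs in enumerate(readsets):
        name = rs.sample_id or f"sample{i}"
        vals = []
        for g in usable:
            n = count_region(rs, Region(g.chrom, g.start, g.end, g.strand), "same")
            vals.append(
                n / (g.intronic_length / 1e3) / (rs.mapped_total / 1e6)
                if rs.mapped_total > 0
                else 0.0
            )
        cols[name] = vals
    out = pd.DataFrame(cols, index=[g.gene_id for g in usable])
    out.index.name = "gene_id"
    out.attrs["excluded"] = excluded
    return out


def expression_filter(matrix: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Keep genes whose RPKM averaged over all samples is >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return matrix.loc[matrix.mean(axis=1) >= threshold]


def differential(
    matrix: pd.DataFrame,
    labels: Mapping[str, str],
    condition_order: tuple[str, str] | None = None,
    pseudo_count: float = 1.0,
    rpkm_min: float | None = None,
) -> pd.DataFrame:
    """Two-condition differential table on a normalized count matrix.

    ``labels`` maps sample column -> condition; ``condition_order`` fixes
    (A, B) so log2FC = log2((mean_A + k)/(mean_B + k)); default
    lexicographic. With a single replicate in either condition only fold
    changes are reported (p, q absent, with a warning). ``rpkm_min`` adds a
    ``passes_filter`` column from the all-sample-mean expression filter.
    """
    conds = sorted(set(labels.values())) if condition_order is None else list(condition_order)
    if len(conds) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conds}")
    ca, cb = conds
    a_cols = [c for c in matrix.columns if labels.get(c) == ca]
    b_cols = [c for c in matrix.columns if labels.get(c) == cb]
    if not a_cols or not b_cols:
        raise ValueError("each condition needs >= 1 sample column")

    a = matrix[a_cols].to_numpy(dtype=float)
    b = matrix[b_cols].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    k = pseudo_count
    log2fc = np.log2((mean_a + k) / (mean_b + k))

    have_reps = len(a_cols) >= 2 and len(b_cols) >= 2
    if have_reps:
        la = np.log2(a + 1.0)
        lb = np.log2(b + 1.0)
        pvals = np.array(
            [pooled_ttest(la[i], lb[i], var_floor=1e-12)[1] for i in range(len(matrix))]
        )
        qvals = bh_adjust(pvals)
    else:
        warnings.warn("single replicate: fold changes only, no p/q", stacklevel=2)
        pvals = np.full(len(matrix), np.nan)
        qvals = np.full(len(matrix), np.nan)

    out = pd.DataFrame(
        {
            "gene_id": matrix.index,
            f"mean_{ca}": mean_a,
            f"mean_{cb}": mean_b,
            "log2fc": log2fc,
            "p": pvals,
            "q": qvals,
        }
    )
    if rpkm_min is not None:
        keep = set(expression_filter(matrix, rpkm_min).index)
        out["passes_filter"] = out["gene_id"].isin(keep)
    return out
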