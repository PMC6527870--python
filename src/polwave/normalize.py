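"""Depth and spike-in (ChIP-RX) normalization.

Two scaling conventions:

* spike-in: alpha = 1e6 / spike-in mapped reads (reads-per-million of the
  exogenous genome), the ChIP-RX convention — signal becomes comparable
  across samples because the spike-in chromatin was added at a fixed ratio
  of cells.
* depth: alpha_i = min_j(mapped_total_j) / mapped_total_i, bringing every
  library down to the smallest one. Scaling is always multiplicative
  (weights), never read subsampling, so results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .models import ReadSet

__all__ = ["ScaleFactor", "spikein_scale", "depth_scale", "apply_scale"]


@dataclass(frozen=True)
class ScaleFactor:
    sample_id: str
    alpha: float
    basis: str  # 'spikein' | 'depth'

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("scale factor must be > 0")
        if self.basis not in ("spikein", "depth"):
            raise ValueError(f"invalid basis {self.basis!r}")


def spikein_scale(readset: ReadSet) -> ScaleFactor:
    """Reads-per-million spike-in scaling: alpha = 1e6 / spikein_total."""
    if readset.spikein_total <= 0:
        raise ValueError("no spike-in reads")
    return ScaleFactor(
        sample_id=readset.sample_id,
        alpha=1e6 / readset.spikein_total,
        basis="spikein",
    )


def depth_scale(readsets: Sequence[ReadSet]) -> list[ScaleFactor]:
    """Scale all libraries to the smallest mapped total."""
    if any(rs.mapped_total <= 0 for rs in readsets):
        raise ValueError("mapped_total must be > 0 for depth scaling")
    if len(readsets) == 1:
        warnings.warn("single readset: identity depth factor", stacklevel=2)
        return [ScaleFactor(readsets[0].sample_id, 1.0, "depth")]
    smallest = min(rs.mapped_total for rs in readsets)
    return [
        ScaleFactor(rs.sample_id, smallest / rs.mapped_total, "depth")
        for rs in readsets
    ]


def apply_scale(value, factor: ScaleFactor):
    """Multiply a count or track by a scale factor."""
    return np.asarray(value, dtype=float) * factor.alpha if np.ndim(value) else float(value) * factor.alpha
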