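"""Small shared statistical utilities."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "pooled_ttest"]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (NaN-safe: NaN stays NaN)."""
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def pooled_ttest(a: np.ndarray, b: np.ndarray, var_floor: float = 0.0) -> tuple[float, float]:
    """Two-sided pooled-variance two-sample t-test.

    ``var_floor`` bounds the pooled variance away from zero so that
    zero-variance groups give a finite statistic instead of infinity.
    Returns (t, p); (nan, nan) when either group has < 2 values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        return float("nan"), float("nan")
    s2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    s2 = max(s2, var_floor)
    diff = a.mean() - b.mean()
    if s2 == 0.0:
        return (0.0, 1.0) if diff == 0 else (float("inf"), 0.0)
    t = diff / np.sqrt(s2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df=na + nb - 2)
    return float(t), float(p)
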