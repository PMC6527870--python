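"""Interactor calling from label-free proteomics (LFQ) intensity matrices.

The workflow mirrors standard affinity-purification mass-spectrometry
scoring: proteins supported by fewer than two razor/unique peptides are
dismissed; missing control intensities are imputed near the detection
baseline (draws from Normal(5% quantile of observed intensities, 0.1), on
the log2 scale) when the corresponding IP (bait) sample observed the
protein; enrichment is mean log2 bait minus mean log2 control with a
pooled-variance t-test and Benjamini-Hochberg adjustment; interactors are
called by strict log2FC and q-value thresholds (e.g. log2FC > 2 and
q < 0.1, or > 1 for a more promiscuous bait).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_adjust, pooled_ttest

__all__ = [
    "LfqMatrix",
    "InteractorCall",
    "peptide_filter",
    "impute_baseline",
    "enrichment",
    "call_interactors",
]


@dataclass
class LfqMatrix:
    """Protein x sample matrix of log2 LFQ intensities.

    ``intensities``: DataFrame, NaN marks a missing (not detected) value.
    ``roles``: sample -> 'bait' | 'control'.
    ``peptide_counts``: razor/unique peptides per protein (optional until
    peptide_filter is applied).
    """

    intensities: pd.DataFrame
    roles: dict[str, str]
    peptide_counts: pd.Series | None = None

    def __post_init__(self) -> None:
        missing_roles = set(self.intensities.columns) - set(self.roles)
        if missing_roles:
            raise ValueError(f"samples without a role: {sorted(missing_roles)}")
        bad = set(self.roles.values()) - {"bait", "control"}
        if bad:
            raise ValueError(f"invalid roles: {sorted(bad)}")

    @property
    def bait_cols(self) -> list[str]:
        return [c for c in self.intensities.columns if self.roles[c] == "bait"]

    @property
    def control_cols(self) -> list[str]:
        return [c for c in self.intensities.columns if self.roles[c] == "control"]


@dataclass(frozen=True)
class InteractorCall:
    protein_id: str
    log2fc: float
    p: float
    q: float
    called: bool


def peptide_filter(matrix: LfqMatrix, min_peptides: int = 2) -> LfqMatrix:
    """Dismiss proteins identified by fewer than ``min_peptides``
    razor/unique peptides."""
    if matrix.peptide_counts is None:
        raise ValueError("peptide_counts required for peptide_filter")
    keep = matrix.peptide_counts >= min_peptides
    idx = matrix.intensities.index[keep.reindex(matrix.intensities.index, fill_value=False)]
    return LfqMatrix(
        intensities=matrix.intensities.loc[idx],
        roles=dict(matrix.roles),
        peptide_counts=matrix.peptide_counts.loc[idx],
    )


def impute_baseline(
    matrix: LfqMatrix, seed: int, quantile: float = 0.05, sd: float = 0.1
) -> LfqMatrix:
    """Impute missing control intensities near the detection baseline.

    A missing control entry is replaced by a draw from
    Normal(mu, sd) with mu the ``quantile`` (default 5%) quantile of the
    global pool of observed log2 intensities — but only when the
    corresponding bait (IP) replicate observed the protein (equal bait and
    control replicate counts pair them in column order; otherwise any
    observed bait value qualifies the protein). Other missing entries are
    left missing. Observed entries are never altered. Deterministic given
    ``seed``.
    """
    df = matrix.intensities.copy()
    observed = df.to_numpy()[~np.isnan(df.to_numpy())]
    if observed.size == 0:
        raise ValueError("all intensities missing; nothing to anchor imputation")
    mu = float(np.quantile(observed, quantile))  # linear interpolation
    rng = np.random.default_rng(seed)

    bait, ctrl = matrix.bait_cols, matrix.control_cols
    if len(bait) == len(ctrl) and len(bait) > 0:
        pairs = list(zip(sorted(bait), sorted(ctrl)))
        for bcol, ccol in pairs:
            m = df[ccol].isna() & df[bcol].notna()
            df.loc[m, ccol] = rng.normal(mu, sd, size=int(m.sum()))
    else:
        any_bait = df[bait].notna().any(axis=1)
        for ccol in ctrl:
            m = df[ccol].isna() & any_bait
            df.loc[m, ccol] = rng.normal(mu, sd, size=int(m.sum()))
    return LfqMatrix(
        intensities=df,
        roles=dict(matrix.roles),
        peptide_counts=matrix.peptide_counts,
    )


def enrichment(matrix: LfqMatrix, var_floor: float = 1e-6) -> pd.DataFrame:
    """Per-protein bait/control enrichment.

    Returns a DataFrame (index = protein) with columns ``log2fc`` (mean
    bait minus mean control, log2 scale), ``p`` (two-sided pooled-variance
    t-test on observed values; variance floored at ``var_floor``), ``q``
    (Benjamini-Hochberg), ``n_bait``/``n_control`` (observed counts) and
    ``flagged`` (True when a group has < 2 observed values after
    imputation; such proteins carry log2fc only, p = q = NaN).
    """
    bait = matrix.intensities[matrix.bait_cols].to_numpy(dtype=float)
    ctrl = matrix.intensities[matrix.control_cols].to_numpy(dtype=float)
    n = len(matrix.intensities)
    log2fc = np.full(n, np.nan)
    pvals = np.full(n, np.nan)
    nb = np.zeros(n, dtype=int)
    nc = np.zeros(n, dtype=int)
    for i in range(n):
        b = bait[i][~np.isnan(bait[i])]
        c = ctrl[i][~np.isnan(ctrl[i])]
        nb[i], nc[i] = len(b), len(c)
        if len(b) and len(c):
            log2fc[i] = b.mean() - c.mean()
        if len(b) >= 2 and len(c) >= 2:
            # identical groups: difference 0 with zero variance -> p = 1
            _, pvals[i] = pooled_ttest(b, c, var_floor=var_floor)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "q": bh_adjust(pvals),
            "n_bait": nb,
            "n_control": nc,
            "flagged": (nb < 2) | (nc < 2),
        },
        index=matrix.intensities.index,
    )
    return out


def call_interactors(
    stats: pd.DataFrame, fc_threshold: float, q_threshold: float
) -> list[InteractorCall]:
    """Strict-threshold interactor calls: log2FC > fc AND q < q_threshold."""
    if fc_threshold <= 0 or q_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    calls = []
    for pid, row in stats.iterrows():
        called = bool(
            np.isfinite(row["log2fc"])
            and np.isfinite(row["q"])
            and row["log2fc"] > fc_threshold
            and row["q"] < q_threshold
        )
        calls.append(
            InteractorCall(
                protein_id=str(pid),
                log2fc=float(row["log2fc"]),
                p=float(row["p"]),
                q=float(row["q"]),
                called=called,
            )
        )
    return calls
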