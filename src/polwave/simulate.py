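"""Synthetic data with known ground truth for every analysis stage.

The nascent-RNA generator is a kinematic model of Pol II transcription:
polymerases initiate as a Poisson process, elongate at a per-gene velocity
``v`` (bp/min), and prematurely terminate at 1-kb checkpoints with per-kb
survival probability ``s`` (the processivity truth). Metabolic labeling
(4sU) marks the RNA segment each surviving polymerase synthesises during
the labeling window; sequencing reads are fixed-length intervals drawn from
labeled RNA. In DRB-release mode initiation is blocked until washout
(time 0), resumes, and cells are harvested at the release time ``t_r`` with
labeling during the final ``label_time`` minutes, so the most distal labeled
position (the transcription wavefront) sits at ``v * t_r``. Promoter
features are emulated by a TSS-proximal start peak (pausing proxy) and by
upstream antisense transcripts on the opposite strand.

ChIP-RX mixtures and label-free proteomics (LFQ) matrices with
missing-at-baseline values are generated by the remaining functions; each
generator is deterministic given its seed and can return its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .interactome import LfqMatrix
from .models import GeneModel, ReadSet

__all__ = [
    "SimGenomeConfig",
    "PolDynamics",
    "LabelingProtocol",
    "simulate_genome",
    "simulate_nascent_reads",
    "simulate_chiprx_reads",
    "simulate_lfq",
]


@dataclass
class SimGenomeConfig:
    """Layout of the synthetic genome.

    ``intron_fraction`` is the target intronic share of each gene body
    (0 gives single-exon genes). Genes are placed non-overlapping, separated
    by ``intergenic_gap``, strands ~50/50.
    """

    n_genes: int = 200
    gene_length_range: tuple[int, int] = (50_000, 100_000)
    intron_fraction: float = 0.85
    chrom_sizes: Mapping[str, int] | None = None
    intergenic_gap: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid gene_length_range")
        if not 0.0 <= self.intron_fraction < 1.0:
            raise ValueError("intron_fraction must be in [0, 1)")


@dataclass
class PolDynamics:
    """Per-gene Pol II kinetic truth. Scalar fields apply to every gene;
    a mapping keyed by gene_id sets per-gene values.

    initiation_rate: Poisson initiation events / min per gene.
    velocity: elongation rate, bp/min.
    survival_per_kb: probability a polymerase continues past each 1-kb
        checkpoint (1.0 = fully processive).
    antisense_fraction: fraction of initiation events producing upstream
        antisense transcripts on the opposite strand.
    """

    initiation_rate: float | Mapping[str, float] = 20.0
    velocity: float | Mapping[str, float] = 3000.0
    survival_per_kb: float | Mapping[str, float] = 1.0
    antisense_fraction: float | Mapping[str, float] = 0.0
    antisense_length_mean: float = 1000.0
    antisense_start_span: float = 250.0
    start_peak_width: int = 300
    start_peak_weight: float = 0.0

    def per_gene(self, name: str, gene_id: str) -> float:
        v = getattr(self, name)
        return float(v[gene_id]) if isinstance(v, Mapping) else float(v)


@dataclass
class LabelingProtocol:
    """Labeling / harvest protocol.

    ``drb=False`` is steady-state labeling (default 15 min of 4sU);
    ``drb=True`` models DRB block and release, with harvest at
    ``release_time`` minutes after washout and labeling during the final
    ``label_time`` (default 10) minutes of release.

    ``release_pulse_min`` sizes the synchronized wave: DRB blocks the
    transition into productive elongation while initiation continues, so a
    queue of promoter-proximal Pol II accumulates during the block and is
    released as a bolus at washout (time 0). The pulse holds the equivalent
    of that many minutes of initiation; it sharpens the wavefront at
    v * release_time, as seen in release experiments.
    """

    drb: bool = False
    release_time: float = 10.0
    label_time: float | None = None
    release_pulse_min: float = 10.0
    read_length: int = 50
    depth: int = 100_000

    def __post_init__(self) -> None:
        if self.label_time is None:
            self.label_time = 10.0 if self.drb else 15.0
        if self.label_time <= 0:
            raise ValueError("label_time must be > 0")
        if self.drb and self.release_time <= 0:
            raise ValueError("DRB mode requires release_time > 0")


def _split_lengths(total: int, n: int, minimum: int, rng: np.random.Generator) -> np.ndarray:
    """n positive integers with the given minimum summing to total."""
    if total < n * minimum:
        raise ValueError("cannot split: total too small")
    extra = rng.multinomial(total - n * minimum, np.full(n, 1.0 / n))
    return extra + minimum


def simulate_genome(cfg: SimGenomeConfig) -> list[GeneModel]:
    """Place non-overlapping multi-exon genes on synthetic chromosomes."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    strands = rng.choice(["+", "-"], size=cfg.n_genes)

    if cfg.chrom_sizes is None:
        needed = int(lengths.sum() + (cfg.n_genes + 1) * cfg.intergenic_gap)
        chrom_sizes = {"chrSim1": needed}
    else:
        chrom_sizes = dict(cfg.chrom_sizes)

    models: list[GeneModel] = []
    chrom_iter = iter(sorted(chrom_sizes.items()))
    chrom, size = next(chrom_iter)
    cursor = cfg.intergenic_gap
    for i in range(cfg.n_genes):
        L = int(lengths[i])
        while cursor + L > size:
            try:
                chrom, size = next(chrom_iter)
            except StopIteration:
                raise ValueError(
                    "cannot place genes without overlap; increase chrom sizes"
                ) from None
            cursor = cfg.intergenic_gap
        start, end = cursor, cursor + L
        if cfg.intron_fraction == 0.0:
            exons = ((start, end),)
        else:
            # short exons (~100-400 bp, as in long mammalian genes); exon
            # count set by the target exonic share of the gene body
            exonic = max(2 * 100, int(round((1.0 - cfg.intron_fraction) * L)))
            n_exons = max(2, int(round(exonic / 250)))
            while n_exons > 2 and 400 * n_exons + 500 * (n_exons - 1) > L:
                n_exons -= 1
            exon_lens = rng.integers(100, 401, size=n_exons)
            intron_total = L - int(exon_lens.sum())
            intron_lens = _split_lengths(intron_total, n_exons - 1, 500, rng)
            exons = []
            pos = start
            for j in range(n_exons):
                exons.append((pos, pos + int(exon_lens[j])))
                pos += int(exon_lens[j])
                if j < n_exons - 1:
                    pos += int(intron_lens[j])
            exons = tuple(exons)
        models.append(
            GeneModel(
                gene_id=f"g{i:04d}",
                transcript_id=f"g{i:04d}.t1",
                chrom=chrom,
                strand=str(strands[i]),
                start=start,
                end=end,
                exons=exons,
            )
        )
        cursor = end + cfg.intergenic_gap
    return models


def _positional_to_genomic(
    gene: GeneModel, p1: np.ndarray, p2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Map TSS-relative positional intervals [p1,p2) to genomic [start,end)."""
    tss = gene.tss
    if gene.strand == "+":
        return tss + p1, tss + p2
    return tss - p2 + 1, tss - p1 + 1


def simulate_nascent_reads(
    genes: Sequence[GeneModel],
    dyn: PolDynamics,
    proto: LabelingProtocol,
    seed: int,
    return_truth: bool = False,
):
    """Simulate strand-specific 4sU (or 4sU-DRB) reads for a gene set.

    Returns a ReadSet, or ``(ReadSet, truth)`` where truth maps gene_id to
    the kinetic parameters used plus sense/antisense event and read tallies.
    """
    rng = np.random.default_rng(seed)
    t_r = proto.release_time if proto.drb else 0.0
    label = float(proto.label_time)

    seg_gene: list[int] = []
    seg_p1: list[np.ndarray] = []
    seg_p2: list[np.ndarray] = []
    seg_anti: list[np.ndarray] = []
    truth: dict[str, dict] = {}

    for gi, gene in enumerate(genes):
        lam = dyn.per_gene("initiation_rate", gene.gene_id)
        v = dyn.per_gene("velocity", gene.gene_id)
        s = dyn.per_gene("survival_per_kb", gene.gene_id)
        f_a = dyn.per_gene("antisense_fraction", gene.gene_id)
        L = gene.length

        if proto.drb:
            u_lo, u_hi = 0.0, t_r  # initiation only after washout
        else:
            u_lo, u_hi = -(L / v + label), 0.0  # steady state: all that can matter
        harvest = t_r
        n_ev = rng.poisson(lam * (u_hi - u_lo))
        n_pulse = rng.poisson(lam * proto.release_pulse_min) if proto.drb else 0
        truth[gene.gene_id] = {
            "velocity": v,
            "survival_per_kb": s,
            "antisense_fraction": f_a,
            "initiation_rate": lam,
            "n_sense_events": 0,
            "n_antisense_events": 0,
        }
        if n_ev + n_pulse == 0:
            continue
        u = np.concatenate(
            [rng.uniform(u_lo, u_hi, size=n_ev), np.zeros(n_pulse)]
        )
        anti = rng.random(n_ev + n_pulse) < f_a

        # sense polymerases: run to min(distance at harvest, termination, L)
        su = u[~anti]
        if len(su):
            if s >= 1.0:
                stop = np.full(len(su), np.inf)
            else:
                stop = rng.geometric(1.0 - s, size=len(su)) * 1000.0
            stop = np.minimum(stop, L)
            x_end = np.minimum(v * (harvest - su), stop)
            x_start = np.clip(v * (harvest - label - su), 0.0, x_end)
            keep = x_end > x_start
            if keep.any():
                seg_gene.append(gi)
                seg_p1.append(x_start[keep])
                seg_p2.append(x_end[keep])
                seg_anti.append(np.zeros(keep.sum(), dtype=bool))
            truth[gene.gene_id]["n_sense_events"] = int(keep.sum())

        # antisense: start 0..span upstream of the TSS, exponential lengths,
        # elongating away from the gene on the opposite strand
        au = u[anti]
        if len(au):
            d0 = rng.uniform(0.0, dyn.antisense_start_span, size=len(au))
            tlen = rng.exponential(dyn.antisense_length_mean, size=len(au))
            x_end = np.minimum(v * (harvest - au), tlen)
            x_start = np.clip(v * (harvest - label - au), 0.0, x_end)
            keep = x_end > x_start
            if keep.any():
                seg_gene.append(gi)
                # positional coords negative upstream of TSS
                seg_p1.append(-(d0[keep] + x_end[keep]))
                seg_p2.append(-(d0[keep] + x_start[keep]))
                seg_anti.append(np.ones(keep.sum(), dtype=bool))
            truth[gene.gene_id]["n_antisense_events"] = int(keep.sum())

    opp = {"+": "-", "-": "+"}
    if proto.depth == 0 or not seg_gene:
        empty = ReadSet([], [], [], [], mapped_total=0, metadata={"drb": proto.drb})
        for t in truth.values():
            t["n_sense_reads"] = t["n_antisense_reads"] = 0
        return (empty, truth) if return_truth else empty

    gene_of_seg = np.concatenate(
        [np.full(len(a), g) for g, a in zip(seg_gene, seg_p1)]
    )
    p1 = np.concatenate(seg_p1)
    p2 = np.concatenate(seg_p2)
    anti_seg = np.concatenate(seg_anti)
    seg_len = p2 - p1

    pick = rng.choice(len(p1), size=proto.depth, p=seg_len / seg_len.sum())
    rl = proto.read_length
    r1 = p1[pick] + rng.random(proto.depth) * np.maximum(seg_len[pick] - rl, 0.0)
    r2 = np.minimum(r1 + rl, p2[pick])
    read_gene = gene_of_seg[pick]
    read_anti = anti_seg[pick]

    # start peak: a fixed share of sense reads concentrated at the TSS
    if dyn.start_peak_weight > 0:
        to_peak = (~read_anti) & (rng.random(proto.depth) < dyn.start_peak_weight)
        n_pk = int(to_peak.sum())
        pk_start = rng.random(n_pk) * dyn.start_peak_width
        r1[to_peak] = pk_start
        r2[to_peak] = pk_start + np.minimum(rl, dyn.start_peak_width)

    chroms = np.empty(proto.depth, dtype=object)
    strands = np.empty(proto.depth, dtype=object)
    starts = np.empty(proto.depth, dtype=np.int64)
    ends = np.empty(proto.depth, dtype=np.int64)
    for gi, gene in enumerate(genes):
        m = read_gene == gi
        if not m.any():
            continue
        a = np.floor(r1[m]).astype(np.int64)
        b = np.maximum(np.ceil(r2[m]).astype(np.int64), a + 1)
        gs, ge = _positional_to_genomic(gene, a, b)
        starts[m], ends[m] = gs, ge
        chroms[m] = gene.chrom
        strands[m] = np.where(read_anti[m], opp[gene.strand], gene.strand)
        truth[gene.gene_id]["n_sense_reads"] = int((m & ~read_anti).sum())
        truth[gene.gene_id]["n_antisense_reads"] = int((m & read_anti).sum())
    for t in truth.values():
        t.setdefault("n_sense_reads", 0)
        t.setdefault("n_antisense_reads", 0)

    rs = ReadSet(
        chroms,
        starts,
        ends,
        strands,
        mapped_total=proto.depth,
        metadata={"drb": proto.drb, "release_time": t_r, "label_time": label, "seed": seed},
    )
    return (rs, truth) if return_truth else rs


def simulate_chiprx_reads(
    genes: Sequence[GeneModel],
    occupancy: Mapping[str, float] | None,
    primary_depth: int,
    spikein_depth: int,
    seed: int,
    read_length: int = 50,
    spike_chrom: str = "spikechr1",
    spike_chrom_size: int = 1_000_000,
) -> ReadSet:
    """Simulate a spike-in (ChIP-RX) read mixture.

    Primary reads land on gene bodies with probability proportional to
    (per-bp occupancy x gene length); ``occupancy=None`` means flat.
    Spike-in reads occupy a disjoint chromosome namespace and are tallied in
    ``spikein_total``; they are also emitted so the mixture is inspectable.
    """
    rng = np.random.default_rng(seed)
    occ = np.array(
        [1.0 if occupancy is None else float(occupancy[g.gene_id]) for g in genes]
    )
    if np.any(occ < 0):
        raise ValueError("occupancy must be nonnegative")
    w = occ * np.array([g.length for g in genes], dtype=float)
    if w.sum() <= 0:
        raise ValueError("zero total occupancy")
    counts = rng.multinomial(primary_depth, w / w.sum())

    chroms, starts, ends, strands = [], [], [], []
    for g, n in zip(genes, counts):
        if n == 0:
            continue
        s = g.start + rng.integers(0, max(g.length - read_length, 1), size=n)
        chroms.append(np.full(n, g.chrom, dtype=object))
        starts.append(s)
        ends.append(np.minimum(s + read_length, g.end))
        strands.append(rng.choice(["+", "-"], size=n).astype(object))
    if spikein_depth > 0:
        s = rng.integers(0, spike_chrom_size - read_length, size=spikein_depth)
        chroms.append(np.full(spikein_depth, spike_chrom, dtype=object))
        starts.append(s)
        ends.append(s + read_length)
        strands.append(rng.choice(["+", "-"], size=spikein_depth).astype(object))

    return ReadSet(
        np.concatenate(chroms) if chroms else [],
        np.concatenate(starts) if starts else [],
        np.concatenate(ends) if ends else [],
        np.concatenate(strands) if strands else [],
        mapped_total=primary_depth + spikein_depth,
        spikein_total=spikein_depth,
        metadata={"spike_chrom": spike_chrom, "seed": seed},
    )


def simulate_lfq(
    n_proteins: int,
    n_true: int,
    effect_log2fc: float,
    n_reps: int = 3,
    baseline_mean: float = 25.0,
    baseline_sd: float = 2.0,
    missing_rule: str = "baseline",
    seed: int = 0,
    rep_sd: float = 0.3,
    detection_limit: float | None = None,
) -> tuple[LfqMatrix, pd.Series]:
    """Simulate a log2 LFQ intensity matrix for a pull-down experiment.

    The first ``n_true`` proteins are bait-specific interactors, elevated by
    ``effect_log2fc`` log2 units in bait (IP) samples. Under
    ``missing_rule='baseline'`` intensities below the detection limit
    (default: baseline_mean - baseline_sd) are missing, emulating
    missing-at-baseline dropout in controls. Returns (matrix, truth labels).
    """
    if n_true > n_proteins:
        raise ValueError("n_true > n_proteins")
    if missing_rule not in ("baseline", "none"):
        raise ValueError(f"unknown missing_rule {missing_rule!r}")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    is_true = np.zeros(n_proteins, dtype=bool)
    is_true[:n_true] = True

    base = rng.normal(baseline_mean, baseline_sd, size=n_proteins)
    cols, roles = [], {}
    data = np.empty((n_proteins, 2 * n_reps))
    for r in range(n_reps):
        for role, j in (("bait", r), ("control", n_reps + r)):
            name = f"{role}_{r + 1}"
            cols.append(name)
            roles[name] = role
            shift = effect_log2fc * is_true if role == "bait" else 0.0
            data[:, len(cols) - 1] = base + shift + rng.normal(0, rep_sd, n_proteins)
    # column order: bait_1..bait_n, control_1..control_n
    order = sorted(range(len(cols)), key=lambda i: (roles[cols[i]] != "bait", cols[i]))
    cols = [cols[i] for i in order]
    data = data[:, order]

    df = pd.DataFrame(data, index=proteins, columns=cols)
    if missing_rule == "baseline":
        limit = baseline_mean - baseline_sd if detection_limit is None else detection_limit
        df = df.mask(df < limit)

    peptides = pd.Series(rng.integers(2, 30, size=n_proteins), index=proteins)
    mat = LfqMatrix(intensities=df, roles={c: roles[c] for c in cols}, peptide_counts=peptides)
    return mat, pd.Series(is_true, index=proteins, name="is_true")
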