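"""End-to-end demo pipeline: simulate -> mask -> normalize -> score ->
wavefront -> regulation -> interactome.

Every stage draws its randomness from a child seed derived from the single
root seed, so reruns with the same config and seed reproduce all outputs
byte-identically. A provenance manifest (stage list, output hashes, seeds,
version) and the resolved config are written beside the outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genomics import filter_reads
from .interactome import call_interactors, enrichment, impute_baseline, peptide_filter
from .io import write_gene_models_bed12
from .models import ReadSet, Region
from .normalize import depth_scale
from .regulation import differential, quantify_genes
from .scores import ScoreParams, metagene_profile, score_delta, score_table, zscore_matrix
from .simulate import (
    LabelingProtocol,
    PolDynamics,
    SimGenomeConfig,
    simulate_genome,
    simulate_lfq,
    simulate_nascent_reads,
)
from .wavefront import WavefrontParams, estimate_wavefronts

__all__ = ["DEFAULT_CONFIG", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "n_genes": 40,
    "gene_length_range": [50_000, 80_000],
    "intron_fraction": 0.85,
    "release_time": 10.0,
    "drb_depth": 60_000,
    "foursu_depth": 60_000,
    "n_replicates": 2,
    "initiation_rate": 20.0,
    "conditions": {
        "myc_on": {"velocity_range": [2770, 3770], "antisense_fraction": 0.05,
                   "survival_per_kb": 0.99},
        "myc_off": {"velocity_range": [2170, 3170], "antisense_fraction": 0.2,
                    "survival_per_kb": 0.95},
    },
    "rpkm_min": 1.0,
    "pseudo_count": 1.0,
    "wavefront": {"bin_size": 300, "n_background_bins": 100},
    "lfq": {
        "n_proteins": 300,
        "n_true": 20,
        "effect_log2fc": 3.0,
        "n_reps": 3,
        "fc_threshold": 1.0,
        "q_threshold": 0.1,
    },
}

_FLOAT_FMT = "%.6g"


def _stage_seed(root: int, k: int) -> int:
    return int(np.random.SeedSequence([root, k]).generate_state(1)[0] % (2**31))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | None = None, out_dir: str | Path = "polwave_out",
                 seed: int = 1) -> Path:
    """Run the full synthetic demo pipeline; returns the output directory."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    # --- simulate genome -------------------------------------------------
    genome_cfg = SimGenomeConfig(
        n_genes=cfg["n_genes"],
        gene_length_range=tuple(cfg["gene_length_range"]),
        intron_fraction=cfg["intron_fraction"],
        seed=_stage_seed(seed, 0),
    )
    genes = simulate_genome(genome_cfg)
    write_gene_models_bed12(genes, out / "genes.bed12")
    stages.append("simulate_genome")

    exon_mask = [Region(g.chrom, s, e) for g in genes for s, e in g.exons]
    conds = list(cfg["conditions"])
    t_r = float(cfg["release_time"])
    n_rep = int(cfg["n_replicates"])

    # --- per-condition kinetic truth and read sets -----------------------
    truth_all: dict[str, dict] = {}
    drb_sets: dict[str, list[ReadSet]] = {}
    foursu_sets: dict[str, list[ReadSet]] = {}
    for ci, cond in enumerate(conds):
        ccfg = cfg["conditions"][cond]
        rng = np.random.default_rng(_stage_seed(seed, 10 + ci))
        lo, hi = ccfg["velocity_range"]
        velocities = {g.gene_id: float(rng.uniform(lo, hi)) for g in genes}
        dyn = PolDynamics(
            initiation_rate=float(cfg["initiation_rate"]),
            velocity=velocities,
            survival_per_kb=float(ccfg.get("survival_per_kb", 1.0)),
            antisense_fraction=float(ccfg.get("antisense_fraction", 0.0)),
            start_peak_weight=0.1,
        )
        truth_all[cond] = {
            g.gene_id: {
                "velocity": velocities[g.gene_id],
                "survival_per_kb": float(ccfg.get("survival_per_kb", 1.0)),
                "antisense_fraction": float(ccfg.get("antisense_fraction", 0.0)),
            }
            for g in genes
        }
        drb_sets[cond] = []
        foursu_sets[cond] = []
        for r in range(n_rep):
            drb = simulate_nascent_reads(
                genes, dyn,
                LabelingProtocol(drb=True, release_time=t_r, depth=int(cfg["drb_depth"])),
                seed=_stage_seed(seed, 100 + 10 * ci + r),
            ).replace(sample_id=f"{cond}_drb_r{r + 1}", condition=cond)
            ss = simulate_nascent_reads(
                genes, dyn,
                LabelingProtocol(drb=False, depth=int(cfg["foursu_depth"])),
                seed=_stage_seed(seed, 200 + 10 * ci + r),
            ).replace(sample_id=f"{cond}_4su_r{r + 1}", condition=cond)
            drb_sets[cond].append(filter_reads(drb, exon_mask))
            foursu_sets[cond].append(filter_reads(ss, exon_mask))
    (out / "truth.json").write_text(json.dumps(truth_all, indent=1, sort_keys=True))
    stages.append("simulate_reads+mask")

    # --- depth normalization factors -------------------------------------
    all_4su = [rs for cond in conds for rs in foursu_sets[cond]]
    factors = depth_scale(all_4su)
    _write_tsv(
        pd.DataFrame(
            [{"sample_id": f.sample_id, "alpha": f.alpha, "basis": f.basis} for f in factors]
        ),
        out / "depth_factors.tsv",
    )
    stages.append("normalize")

    # --- processivity / directionality scores ----------------------------
    sp = ScoreParams(variant="fourSU", pseudo_count=float(cfg["pseudo_count"]))
    rep_tables = {}
    cond_tables = {}
    for cond in conds:
        pooled = _pool(foursu_sets[cond])
        cond_tables[cond] = score_table(pooled, genes, sp, condition=cond)
        _write_tsv(cond_tables[cond], out / f"scores_{cond}.tsv")
        for rs in foursu_sets[cond]:
            rep_tables[rs.sample_id] = score_table(rs, genes, sp, condition=cond)
    delta = score_delta(cond_tables[conds[0]], cond_tables[conds[1]])
    _write_tsv(delta, out / "score_delta.tsv")

    for score_col, stem in (("processivity", "zscores_processivity"),
                            ("directionality", "zscores_directionality")):
        mat = pd.DataFrame(
            {sid: t.set_index("gene_id")[score_col] for sid, t in rep_tables.items()}
        ).dropna()
        if len(mat):
            z, _ = zscore_matrix(mat)
            z.reset_index().to_csv(out / f"{stem}.tsv", sep="\t", index=False,
                                   float_format=_FLOAT_FMT)
    stages.append("score")

    # --- metagene profile -------------------------------------------------
    prof = metagene_profile(
        [_pool(foursu_sets[c]).replace(sample_id=c) for c in conds],
        genes, anchor="TSS", span=7500, min_gene_length=8000,
    )
    _write_tsv(prof, out / "metagene_tss.tsv")
    stages.append("metagene")

    # --- wavefront / elongation rates -------------------------------------
    wp = WavefrontParams(
        bin_size=int(cfg["wavefront"]["bin_size"]),
        n_background_bins=int(cfg["wavefront"]["n_background_bins"]),
        release_time=t_r,
        seed=_stage_seed(seed, 300),
    )
    for cond in conds:
        wf = estimate_wavefronts(_pool(drb_sets[cond]), genes, wp)
        _write_tsv(wf, out / f"wavefront_{cond}.tsv")
    stages.append("wavefront")

    # --- nascent regulation ------------------------------------------------
    matrix = quantify_genes(all_4su, genes)
    labels = {rs.sample_id: rs.condition for rs in all_4su}
    reg = differential(matrix, labels, condition_order=(conds[0], conds[1]),
                       pseudo_count=float(cfg["pseudo_count"]),
                       rpkm_min=float(cfg["rpkm_min"]))
    _write_tsv(reg, out / "regulation.tsv")
    stages.append("regulation")

    # --- interactome --------------------------------------------------------
    lcfg = cfg["lfq"]
    mat, truth = simulate_lfq(
        n_proteins=int(lcfg["n_proteins"]),
        n_true=int(lcfg["n_true"]),
        effect_log2fc=float(lcfg["effect_log2fc"]),
        n_reps=int(lcfg["n_reps"]),
        seed=_stage_seed(seed, 400),
    )
    mat = impute_baseline(peptide_filter(mat), seed=_stage_seed(seed, 401))
    stats = enrichment(mat)
    calls = call_interactors(stats, float(lcfg["fc_threshold"]), float(lcfg["q_threshold"]))
    _write_tsv(
        pd.DataFrame(
            [
                {"protein_id": c.protein_id, "log2fc": c.log2fc, "p": c.p,
                 "q": c.q, "called": c.called,
                 "is_true": bool(truth.get(c.protein_id, False))}
                for c in calls
            ]
        ),
        out / "interactome.tsv",
    )
    stages.append("interactome")

    # --- provenance ----------------------------------------------------------
    (out / "config_resolved.yaml").write_text(yaml.safe_dump({**cfg, "seed": seed}, sort_keys=True))
    outputs = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _pool(readsets: list[ReadSet]) -> ReadSet:
    """Concatenate replicate read sets (totals summed)."""
    first = readsets[0]
    return ReadSet(
        np.concatenate([rs.chroms for rs in readsets]),
        np.concatenate([rs.starts for rs in readsets]),
        np.concatenate([rs.ends for rs in readsets]),
        np.concatenate([rs.strands for rs in readsets]),
        mapped_total=sum(rs.mapped_total for rs in readsets),
        spikein_total=sum(rs.spikein_total for rs in readsets),
        sample_id=first.sample_id,
        condition=first.condition,
    )
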