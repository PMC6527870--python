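# polwave

Quantitative analysis of RNA polymerase II elongation from strand-specific
nascent-RNA sequencing (4sU and DRB-release 4sU labeling) and spike-in
ChIP (ChIP-RX), plus nascent gene-regulation calls and label-free
proteomics interactome scoring. The package is aimed at genomics analysts
who have aligned-read intervals (BED) and gene models (BED12/GTF) and want
per-gene Pol II kinetic statistics — and at method developers, since every
stage ships with a synthetic-data generator whose ground truth the
estimators can be validated against.

## What it computes

**Processivity score** — how efficiently initiated Pol II reaches distal
gene regions:

    P = log2( (N_distal + k) / (N_proximal + k) )

with pseudo-count `k = 1`. For nascent 4sU data the proximal window is
TSS+1–2 kb and the distal window TSS+5–7 kb (strand-matched reads, genes
> 8 kb); for ChIP data the windows are TSS+0.5–1.5 kb and TES−1 kb–TES+2 kb.
Because the distal window is twice as wide, uniform coverage gives
P ≈ log2 2, not 0; scores are interpreted in condition comparisons (ΔP).

**Promoter directionality** — sense versus promoter-upstream antisense
transcription:

    D = log2( (N_sense + k) / (N_antisense + k) )

with sense reads on the gene strand over TSS–TES and antisense reads on the
opposite strand over the 1 kb upstream of the TSS (genes ≥ 300 bp).

**Elongation rate (wavefront)** — after release from a DRB block, the front
of elongating Pol II sits at distance `v·t_r` into the gene at harvest time
`t_r`. Intronic signal is binned into 300-bp TSS-anchored bins, a background
density is estimated from TES-proximal intron bins of very long (≥ 60 kb)
genes, a bin is *transcribed* when its density strictly exceeds background,
and the transcription edge is the end of the most distal run of ≥ 2
consecutive transcribed bins. Then

    v = distance(TSS → edge) / t_r        [bp/min]

for genes ≥ 30 kb, with per-gene isoform selection by proximity of the TSS
to the start peak.

**Normalization** — spike-in scaling `α = 10⁶ / spike-in reads` (ChIP-RX
reads-per-million convention) and depth scaling to the smallest library.

**Nascent regulation** — intronic RPKM per gene and replicate, expression
filter on the all-sample mean, log2 fold change of replicate means
(pseudo-count 1), t-test on log-normalized values, Benjamini–Hochberg q.

**Interactome** — from log2 LFQ intensity matrices: proteins with < 2
razor/unique peptides dismissed; missing control values imputed from
N(5%-quantile of observed intensities, 0.1) when the paired IP sample
observed the protein; enrichment = mean(bait) − mean(control) with a
pooled t-test and BH adjustment; interactors called at strict thresholds
(e.g. log2FC > 2 and q < 0.1).

## Worked example

Simulate two conditions whose true median elongation rates are 3,270 and
2,670 bases/min (200 genes of 50–100 kb each, 10-min DRB release), then
recover both medians from the reads alone:

```python
from polwave.benchmarks import two_condition_shift

res = two_condition_shift(seed=2)
print(res["recovered_medians"])   # [3300.0, 2640.0]
print(res["rel_errors_pct"])      # [0.917..., 1.123...]
print(res["ranksum_p"])           # 2.66e-48
```

The recovered medians (3,300 and 2,640 bases/min) sit within ~1% of the
simulated truth, and the two-sided rank-sum test confirms the shift. The
velocities are quantized in steps of `bin_size / t_r` = 30 bases/min — the
resolution floor of the edge-based estimator.

The same stages are available from the shell:

```
polwave simulate --seed 3 --out sim/          # genome + reads + truth.json
polwave mask --reads sim/reads.bed --mask exons.bed --out masked.bed
polwave score --reads masked.bed --genes sim/genes.bed12 --out scores.tsv
polwave wavefront --reads masked.bed --genes sim/genes.bed12 \
    --release-time 10 --out rates.tsv
polwave run --seed 1 --out demo/              # full pipeline + manifest
```

`polwave run` writes score tables, wavefront velocities, regulation and
interactome calls, a resolved config, and a provenance manifest; rerunning
with the same seed reproduces every output byte-identically.

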