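# Methods

## Coordinate and counting conventions

All coordinates are 0-based half-open (BED). Two intervals overlap iff they
share ≥ 1 bp; touching endpoints do not overlap. Every "TSS+x" offset is
measured in the direction of transcription and mirrored genomically for
minus-strand genes (TSS = `end − 1` there); this is the only biologically
coherent reading of downstream/upstream window definitions and is applied
uniformly. Read counting uses raw overlap counts, never fractional overlap.
GTF input (1-based closed) is converted on read; BED I/O round-trips
byte-identically.

Exon and rRNA masking is applied to read sets before any scoring
(pipeline order: mask → normalize → score), since exonic signal carries
mature-RNA background into nascent-RNA quantities. Score windows are
genomic, so a flag-free caller can also pass unmasked reads when the
mature-RNA contribution is known to be negligible; the demo pipeline and
all benchmarks use exon-masked reads throughout.

## Processivity and directionality scores

`P = log2((distal + k)/(proximal + k))` and
`D = log2((sense + k)/(antisense + k))` with pseudo-count `k = 1` read, so
all scores are finite for any input. The pseudo-count value is a package
choice; it only matters for genes with near-empty windows. Window variants:

| variant | proximal | distal | strand | gene filter |
|---|---|---|---|---|
| fourSU | TSS+1–2 kb | TSS+5–7 kb | gene strand | > 8 kb |
| chip | TSS+0.5–1.5 kb | TES−1 kb–TES+2 kb | both | none |

The distal/proximal windows have unequal widths (2 kb vs 1 kb for fourSU),
so uniform coverage scores P = log2(2001/1001) ≈ 1, not 0. Scores are raw
counts, not per-bp densities, and are meant for condition contrasts
(`score_delta`) and row-wise Z-scored replicate matrices (`zscore_matrix`,
sd with n−1; zero-variance rows become zeros and are flagged).

The directionality antisense window is 1 kb upstream of the TSS by default;
a 1.5-kb variant exists in the literature and is available via
`ScoreParams(antisense_window=1500)`. The two are not reconciled — callers
choose one and state it. Genes < 300 bp are excluded from D; ineligible
genes are skipped with a reason code, never errors.

## Elongation-rate estimation (DRB-release wavefront)

Binning: gene bodies are tiled with `bin_size` (default 300 bp) bins on a
TSS-anchored grid, keeping only bins that lie fully inside introns; partial
bins crossing exon boundaries are dropped. Anchoring the grid at the TSS
(rather than restarting the tiling at each intron) puts every bin end on a
TSS-relative lattice, which makes bins comparable across genes and makes
the velocity resolution floor exact: recovered velocities are multiples of
`bin_size / t_r` (30 bp/min at defaults). Density is the read count per bin
(gene-strand reads).

Background: the mean density of `n_background_bins` (default 100) intron
bins sampled (seeded RNG, seed recorded in the output) from the last
`tes_region` (default 10 kb) of genes ≥ 60 kb — positions a 10-min wave
cannot reach at physiological velocities, so they measure noise. `max` and
95th-percentile variants are available via `threshold_stat`.

Calling: a bin is transcribed iff its density is **strictly** greater than
the background. A gene is analyzed only if ≥ 30 kb long and expressed:
the mean of `n_expressed_bins` (default 3) bins sampled from the first
`proximal_region` (default 3 kb) of intronic bins must exceed background.
The transcription edge is the end of the most distal run of ≥ 2 consecutive
transcribed bins; a single isolated transcribed bin beyond it is treated as
noise (that is what the 2-bin rule is for). Failure modes are encoded as
statuses (`too_short`, `not_expressed`, `no_edge`), never exceptions.

Distance is genomic TSS → edge by default (`distance_mode="genomic"`); a
cumulative binned-intronic mode exists for callers who prefer to count only
intronic bp. Velocity = distance / release time. For genes with several
isoforms, the isoform whose TSS is nearest the start peak (maximum-density
300-bp bin within TSS ± 2 kb) is selected; ties go to the longer isoform,
then lexicographic id, and genes with no promoter signal fall back to the
longest isoform with a warning.

## Normalization

Spike-in: `α = 10⁶ / spike-in mapped reads` (reads-per-million of the
exogenous genome). Depth: `α_i = min_j(N_j) / N_i`, scaling down to the
smallest library to avoid upsampling. Both are multiplicative weights —
reads are never subsampled, so results are deterministic. Defaults:
spike-in only for ChIP-RX comparisons, depth only for 4sU comparisons;
composition is possible but not implied.

## Nascent regulation

Intronic RPKM: exon-excluded read count / (intronic kb) / (mapped reads in
millions), per replicate; genes with zero intronic length are excluded and
reported. Replicates are averaged **after** normalization (a pre-averaging
flag is not provided; normalize-then-average keeps replicates on one
scale). Fold change uses pseudo-count 1. The per-gene test is a two-sided
pooled t-test on log2(RPKM + 1) — the significance machinery around the BH
adjustment is deliberately simple and swappable; the package explicitly
does not fit dispersion-modeled count tests. Default expression filter:
mean RPKM ≥ 1 across all samples (CLI-exposed).

## Interactome

Intensities are treated as log2-scale throughout: the imputation width
σ = 0.1 is only meaningful on a log scale (raw LFQ spans orders of
magnitude). The imputation mean is the 5% quantile (linear interpolation
between order statistics) of the **global pool** of observed intensities;
per-sample and per-protein pools are selectable, with no claim that either
matches any particular upstream pipeline. A missing control value is
imputed only when the paired bait replicate (equal replicate counts pair
columns in sorted order) observed the protein; other missing values stay
missing and the protein is flagged when a group has < 2 observed values.
Observed entries are never altered. Enrichment is a pooled-variance t-test
with the pooled variance floored at 1e-6 so zero-variance groups yield
finite statistics (flag-free; identical groups give p = 1). Multiple
imputation plus a moderated linear model would be the heavier alternative;
the single seeded imputation + plain t-test keeps the calls reproducible
from one seed and is validated by recovery on synthetic truth rather than
by numeric identity to any specific legacy pipeline. Calls use strict
inequalities: log2FC > threshold and q < threshold.

## Synthetic-data generators

The nascent-RNA generator is kinematic, not biochemical:

- Initiation is Poisson at `initiation_rate` λ (default 20 events/min per
  gene — an aggregate rate for a well-expressed gene chosen so a 10-min
  release yields a well-sampled front; real single-gene rates are lower).
- Each polymerase moves at the per-gene velocity `v` (bp/min) and passes
  each 1-kb checkpoint with survival probability `s` (geometric premature
  termination; checkpointed rather than continuous so the expected
  coverage decay `s^(x/1 kb)` stays closed-form).
- Labeling marks the RNA segment synthesized during the final `label_time`
  minutes before harvest (15 min steady-state, 10 min DRB mode). Harvest
  is at the end of labeling, so in DRB mode the true front is exactly
  `v · t_r` and the estimator's target quantity equals distance / t_r.
- DRB mode adds a synchronized release pulse at washout
  (`release_pulse_min`, default 10 equivalent minutes of initiation):
  DRB blocks the transition into productive elongation while initiation
  continues, so a promoter-proximal queue accumulates during the block and
  flushes as a bolus at washout. The pulse produces the sharp wavefront
  seen in release experiments; without it the front tapers linearly and
  has no defined edge.
- Promoter-proximal pausing is emulated as a static start peak (a fixed
  weight of sense reads placed within `start_peak_width` of the TSS), not
  as pause kinetics — sufficient for start-peak detection and for the
  "promoter signal unchanged, front shifted" phenotype.
- Antisense transcripts initiate 0–250 bp upstream of the TSS on the
  opposite strand with Exponential(mean 1 kb) lengths, so the 1-kb
  directionality window captures most antisense signal.
- Reads are fixed-length intervals sampled uniformly from labeled RNA,
  allocated across genes in proportion to labeled-RNA mass.

The gene-layout generator places non-overlapping genes with short exons
(100–400 bp, as in long mammalian genes) at a target intronic fraction
(default 0.85). The ChIP-RX generator samples primary reads per gene in
proportion to occupancy × length and emits spike-in reads on a disjoint
chromosome namespace. The LFQ generator gives every protein a base
abundance N(25, 2) on the log2 scale, elevates true interactors by the
effect size in bait samples, adds N(0, 0.3) replicate noise, and censors
values below the detection limit (mean − 1 sd) as missing — producing the
missing-at-baseline pattern in controls that the imputation step exists
for.

What the generators do **not** emulate: sequence content and alignment
artifacts (no FASTQ, no mappability structure), overlapping genes,
transcript 3′-end processing, pause-release kinetics, velocity variation
along a gene, batch effects in LFQ. Passing tests therefore demonstrate
estimator correctness under the stated kinematic model, not robustness to
every artifact of real libraries.

## Benchmark conditions and problem sizes

The reference experiments in `polwave.benchmarks` fix the validation
conditions: 200 genes of 50–100 kb for velocity recovery with true
velocities uniform in 2,000–3,500 bp/min (or uniform ±500 bp/min around
median 3,270 vs 2,670 bp/min for the two-condition contrast), t_r = 10 min,
~50 reads/kb behind the front; 30 genes of 10–14 kb at 20,000 reads per
condition for the score sweeps; depth 10⁵ for the spike-in invariance
check; 1,000 proteins × 3v3 replicates × 50 seeded runs for interactome
recovery. These sizes give stable medians while keeping any single
experiment in the seconds range on one CPU.

## Known limitations

- The edge caller reports the last *fully covered* bin pair, so recovered
  velocities are biased low by up to ~1 bin plus any exon that interrupts
  the front region; the benchmarks measure this bias (≈ 0.5–3% median).
- Overlapping genes are not disambiguated; reads in shared windows count
  for every overlapping gene.
- The background threshold assumes very long genes exist in the annotation;
  without ≥ 60-kb genes the wavefront stage refuses to run.
- Depth normalization to the minimum library discards no reads but gives
  conservative (down-scaled) signal for deeper libraries.
- The regulation test is a plain t-test; with 2 replicates per condition
  its power is limited and the package reports fold changes regardless.
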