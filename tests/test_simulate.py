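"""Ground-truth behavior of the synthetic-data generators: determinism,
wavefront geometry, geometric coverage decay, conservation laws."""

import numpy as np
import pytest

from polwave.genomics import count_region, offset_region
from polwave.models import Region
from polwave.simulate import (
    LabelingProtocol,
    PolDynamics,
    SimGenomeConfig,
    simulate_chiprx_reads,
    simulate_genome,
    simulate_lfq,
    simulate_nascent_reads,
)


@pytest.fixture(scope="module")
def small_genome():
    return simulate_genome(
        SimGenomeConfig(n_genes=10, gene_length_range=(20_000, 40_000), seed=1)
    )


class TestSimulateGenome:
    def test_seed_determinism(self):
        cfg = SimGenomeConfig(n_genes=10, seed=1)
        assert simulate_genome(cfg) == simulate_genome(cfg)

    def test_intron_fraction_zero_gives_single_exon(self):
        cfg = SimGenomeConfig(n_genes=5, intron_fraction=0.0, seed=2)
        assert all(len(g.exons) == 1 for g in simulate_genome(cfg))

    def test_genes_non_overlapping_and_within_chrom(self, small_genome):
        by_chrom = {}
        for g in small_genome:
            by_chrom.setdefault(g.chrom, []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.start)
            for a, b in zip(genes, genes[1:]):
                assert a.end <= b.start

    def test_intronic_share_near_target(self):
        genes = simulate_genome(
            SimGenomeConfig(n_genes=30, gene_length_range=(50_000, 80_000),
                            intron_fraction=0.85, seed=3)
        )
        share = np.mean([g.intronic_length / g.length for g in genes])
        assert 0.80 <= share <= 0.90

    def test_too_small_chromosome_raises(self):
        cfg = SimGenomeConfig(
            n_genes=10, gene_length_range=(50_000, 60_000),
            chrom_sizes={"c1": 100_000}, seed=0,
        )
        with pytest.raises(ValueError, match="cannot place"):
            simulate_genome(cfg)


class TestNascentReads:
    def test_seed_determinism(self, small_genome):
        dyn = PolDynamics(antisense_fraction=0.2)
        proto = LabelingProtocol(depth=5_000)
        a = simulate_nascent_reads(small_genome, dyn, proto, seed=9)
        b = simulate_nascent_reads(small_genome, dyn, proto, seed=9)
        assert np.array_equal(a.starts, b.starts)
        assert list(a.strands) == list(b.strands)

    def test_drb_reads_bounded_by_wavefront(self):
        genes = simulate_genome(
            SimGenomeConfig(n_genes=5, gene_length_range=(50_000, 60_000),
                            intron_fraction=0.0, seed=4)
        )
        dyn = PolDynamics(velocity=3000, survival_per_kb=1.0,
                          antisense_fraction=0.0, start_peak_weight=0.0)
        rs = simulate_nascent_reads(
            genes, dyn, LabelingProtocol(drb=True, release_time=10, depth=20_000), seed=5
        )
        for g in genes:
            on_gene = (rs.chroms.astype(str) == g.chrom) & (rs.starts >= g.start) & (rs.ends <= g.end)
            if g.strand == "+":
                three_prime = rs.ends[on_gene] - g.tss
            else:
                three_prime = g.tss - rs.starts[on_gene] + 1
            assert three_prime.max() <= 30_000

    def test_wavefront_99th_percentile_converges_to_v_tr(self):
        gene = simulate_genome(
            SimGenomeConfig(n_genes=1, gene_length_range=(40_000, 40_001),
                            intron_fraction=0.0, seed=6)
        )
        dyn = PolDynamics(velocity=3000, antisense_fraction=0.0, start_peak_weight=0.0)
        rs = simulate_nascent_reads(
            gene, dyn, LabelingProtocol(drb=True, release_time=10, depth=100_000), seed=7
        )
        g = gene[0]
        ends = rs.ends - g.start if g.strand == "+" else g.tss - rs.starts + 1
        p99 = np.percentile(ends, 99)
        assert abs(p99 - 30_000) / 30_000 <= 0.02

    def test_no_antisense_without_antisense_fraction(self, small_genome):
        dyn = PolDynamics(antisense_fraction=0.0)
        rs = simulate_nascent_reads(small_genome, dyn, LabelingProtocol(depth=5_000), seed=8)
        for g in small_genome:
            opp = "-" if g.strand == "+" else "+"
            assert rs.count_in(g.chrom, g.start - 2_000, g.end, opp) == 0

    def test_steady_state_coverage_decays_geometrically(self):
        genes = simulate_genome(
            SimGenomeConfig(n_genes=10, gene_length_range=(10_000, 12_000),
                            intron_fraction=0.0, seed=10)
        )
        dyn = PolDynamics(velocity=3000, survival_per_kb=0.5,
                          antisense_fraction=0.0, start_peak_weight=0.0)
        rs = simulate_nascent_reads(genes, dyn, LabelingProtocol(depth=10_000), seed=11)
        c1 = sum(count_region(rs, offset_region(g, "TSS", 1000, 2000), "same") for g in genes)
        c2 = sum(count_region(rs, offset_region(g, "TSS", 2000, 3000), "same") for g in genes)
        ratio = c2 / c1
        se = ratio * np.sqrt(1 / c1 + 1 / c2)
        assert abs(ratio - 0.5) <= 3 * se + 0.02

    def test_log_coverage_slope_recovers_survival(self):
        s = 0.8
        genes = simulate_genome(
            SimGenomeConfig(n_genes=10, gene_length_range=(12_000, 14_000),
                            intron_fraction=0.0, seed=12)
        )
        dyn = PolDynamics(velocity=3000, survival_per_kb=s,
                          antisense_fraction=0.0, start_peak_weight=0.0)
        rs = simulate_nascent_reads(genes, dyn, LabelingProtocol(depth=200_000), seed=13)
        kb = np.arange(1, 9)
        cov = np.array(
            [
                sum(
                    count_region(rs, offset_region(g, "TSS", int(k) * 1000, (int(k) + 1) * 1000), "same")
                    for g in genes
                )
                for k in kb
            ],
            dtype=float,
        )
        slope = np.polyfit(kb, np.log2(cov), 1)[0]
        assert abs(slope - np.log2(s)) / abs(np.log2(s)) <= 0.05

    def test_zero_depth_gives_empty_readset(self, small_genome):
        rs = simulate_nascent_reads(
            small_genome, PolDynamics(), LabelingProtocol(depth=0), seed=1
        )
        assert len(rs) == 0 and rs.mapped_total == 0


class TestChipRx:
    def test_depth_conservation_and_spike_accounting(self, small_genome):
        rs = simulate_chiprx_reads(small_genome, None, 5_000, 500, seed=3)
        assert len(rs) == 5_500
        assert rs.spikein_total == 500
        spike = rs.chroms.astype(str) == "spikechr1"
        assert spike.sum() == 500

    def test_no_spike_in(self, small_genome):
        rs = simulate_chiprx_reads(small_genome, None, 1_000, 0, seed=3)
        assert rs.spikein_total == 0

    def test_flat_occupancy_counts_proportional_to_length(self, small_genome):
        depth = 100_000
        rs = simulate_chiprx_reads(small_genome, None, depth, 0, seed=5)
        lengths = np.array([g.length for g in small_genome], dtype=float)
        p = lengths / lengths.sum()
        counts = np.array(
            [
                count_region(rs, Region(g.chrom, g.start, g.end, "."), "both")
                for g in small_genome
            ]
        )
        # multinomial oracle: each count within 4 sd of its expectation
        expect = depth * p
        sd = np.sqrt(depth * p * (1 - p))
        assert np.all(np.abs(counts - expect) <= 4 * sd)

    def test_zero_occupancy_rejected(self, small_genome):
        occ = {g.gene_id: 0.0 for g in small_genome}
        with pytest.raises(ValueError, match="zero total occupancy"):
            simulate_chiprx_reads(small_genome, occ, 100, 0, seed=1)


class TestLfq:
    def test_seed_determinism(self):
        a, _ = simulate_lfq(100, 10, 2.0, seed=4)
        b, _ = simulate_lfq(100, 10, 2.0, seed=4)
        assert a.intensities.equals(b.intensities)

    def test_missing_rule_none_gives_complete_matrix(self):
        mat, _ = simulate_lfq(100, 10, 2.0, missing_rule="none", seed=5)
        assert not mat.intensities.isna().any().any()

    def test_true_interactors_elevated_in_bait(self):
        mat, truth = simulate_lfq(200, 20, 3.0, missing_rule="none", seed=6)
        bait = mat.intensities[mat.bait_cols].mean(axis=1)
        ctrl = mat.intensities[mat.control_cols].mean(axis=1)
        diff = (bait - ctrl)[truth.to_numpy()]
        assert diff.mean() == pytest.approx(3.0, abs=0.15)

    def test_null_effect_rarely_called(self):
        """Under a null (no effect) the BH-controlled call rate stays low."""
        from polwave.interactome import call_interactors, enrichment, impute_baseline

        mat, _ = simulate_lfq(500, 0, 0.0, seed=7)
        stats = enrichment(impute_baseline(mat, seed=8))
        calls = call_interactors(stats, 1.0, 0.1)
        assert sum(c.called for c in calls) <= 0.1 * 500
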