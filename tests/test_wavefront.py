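"""Intron binning, background thresholding, edge calling (vs exhaustive
enumeration), velocity arithmetic, and isoform selection."""

import itertools

import numpy as np
import pytest

from polwave.models import GeneModel
from polwave.wavefront import (
    WavefrontParams,
    background_threshold,
    bin_intron_density,
    call_transcribed_bins,
    elongation_rate,
    estimate_wavefront,
    find_edge,
    gene_intron_bins,
    last_run_end_index,
    select_isoform,
)

from conftest import make_reads


def brute_force_edge(vec):
    """Independent oracle: the last bin of the most distal pair of
    consecutive transcribed bins."""
    best = None
    for j in range(1, len(vec)):
        if vec[j] and vec[j - 1]:
            best = j
    return best


class TestIntronBinning:
    def test_intron_at_tss_grid_tiles_three_bins(self):
        # exons (0,0) impossible; use tiny first exon? here intron starts at 0
        # via a gene whose first exon is upstream of chrom? Use offset gene:
        g = GeneModel("g", "t", "chr1", "+", 0, 1200, ((0, 100), (1000, 1200)))
        off, gs, ge = gene_intron_bins(g, 300)
        # intron [100,1000): grid bins [300,600),[600,900) fully inside
        assert list(off) == [300, 600]
        assert list(gs) == [300, 600]

    def test_partial_bins_dropped(self):
        g = GeneModel("g", "t", "chr1", "+", 0, 1000, ((0, 50), (800, 1000)))
        off, gs, ge = gene_intron_bins(g, 300)
        # intron [50,800): grid bins [300,600) fit; [0,300) and [600,900) cross exons
        assert list(off) == [300]

    def test_minus_strand_bins_mirror_plus(self):
        # mirror-image pair of genes; bin offsets must agree
        M = 100_000
        exons_p = ((0, 200), (5_000, 5_200), (9_800, 10_000))
        gp = GeneModel("p", "p", "chr1", "+", 0, 10_000, exons_p)
        exons_m = tuple(sorted((M - e, M - s) for s, e in exons_p))
        gm = GeneModel("m", "m", "chr1", "-", M - 10_000, M, exons_m)
        op, *_ = gene_intron_bins(gp, 300)
        om, gs_m, ge_m = gene_intron_bins(gm, 300)
        assert np.array_equal(op, om)
        # genomic intervals are the reflections of the plus-gene bins
        _, gs_p, ge_p = gene_intron_bins(gp, 300)
        assert np.array_equal(gs_m, M - ge_p)

    def test_density_counts_reads_per_bin(self):
        g = GeneModel("g", "t", "chr1", "+", 0, 1300, ((0, 100), (1150, 1300)))
        # intron [100,1150): bins [300,600),[600,900): one read in each
        reads = make_reads([(310, 360), (700, 750), (50, 80)])
        d = bin_intron_density(reads, g, WavefrontParams())
        assert list(d.density) == [1, 1]

    def test_intronless_gene_yields_no_bins(self, plus_gene):
        d = bin_intron_density(make_reads([(0, 10)]), plus_gene, WavefrontParams())
        assert len(d) == 0


class TestBackgroundThreshold:
    def _long_gene(self):
        return GeneModel(
            "bg", "bg", "chr1", "+", 0, 70_000, ((0, 100), (69_900, 70_000))
        )

    def test_zero_background_gives_zero_threshold(self):
        g = self._long_gene()
        thr = background_threshold(make_reads([(200, 250)]), [g], WavefrontParams())
        assert thr == 0.0

    def test_threshold_is_mean_of_sampled_bins(self):
        g = self._long_gene()
        # fill the TES-proximal 10 kb with 2 reads per 300-bp grid bin
        p = WavefrontParams(n_background_bins=10_000)  # take all bins
        off, gs, ge = gene_intron_bins(g, 300)
        sel = off >= g.length - p.tes_region
        intervals = []
        for s in gs[sel]:
            intervals += [(int(s) + 10, int(s) + 60), (int(s) + 100, int(s) + 150)]
        thr = background_threshold(make_reads(intervals), [g], p)
        assert thr == pytest.approx(2.0)

    def test_seeded_sampling_is_deterministic(self):
        g = self._long_gene()
        reads = make_reads([(65_000 + 17 * i, 65_050 + 17 * i) for i in range(100)])
        p = WavefrontParams(n_background_bins=5, seed=42)
        assert background_threshold(reads, [g], p) == background_threshold(reads, [g], p)

    def test_no_qualifying_gene_is_error(self, plus_gene):
        with pytest.raises(ValueError, match="background"):
            background_threshold(make_reads([(0, 10)]), [plus_gene], WavefrontParams())


class TestEdgeCalling:
    def test_strictly_greater_than_threshold(self):
        called = call_transcribed_bins(np.array([5, 5, 0]), 1.0)
        assert list(called) == [True, True, False]
        assert not call_transcribed_bins(np.array([1.0]), 1.0)[0]

    def test_long_leading_run(self):
        vec = [True] * 60 + [False] * 40
        assert find_edge(np.array(vec), WavefrontParams()) == 18_000

    def test_alternating_bins_have_no_edge(self):
        assert find_edge(np.array([True, False, True, False, True]), WavefrontParams()) is None

    def test_most_distal_run_wins(self):
        vec = np.array([True, True, False, False, True, True, False])
        assert find_edge(vec, WavefrontParams()) == 1_800

    def test_exhaustive_oracle_all_vectors_up_to_length_12(self):
        for n in range(1, 13):
            for vec in itertools.product([False, True], repeat=n):
                got = last_run_end_index(np.array(vec))
                assert got == brute_force_edge(vec), vec


class TestVelocity:
    @pytest.mark.parametrize("edge,t_r,v", [(30_000, 10, 3_000), (18_000, 6, 3_000)])
    def test_distance_over_release_time(self, edge, t_r, v):
        assert elongation_rate(edge, t_r) == v

    def test_nonpositive_release_time_rejected(self):
        with pytest.raises(ValueError):
            elongation_rate(1000, 0)

    def test_velocities_quantized_on_bin_lattice(self):
        """Recovered velocities land on multiples of bin_size / t_r."""
        rng = np.random.default_rng(2)
        g = GeneModel("g", "t", "chr1", "+", 0, 40_000, ((0, 100), (39_900, 40_000)))
        p = WavefrontParams(release_time=10, seed=0)
        intervals = [
            (int(x), int(x) + 50) for x in rng.integers(100, 25_000, size=3_000)
        ]
        reads = make_reads(intervals)
        bg = GeneModel("bg", "bg", "chr1", "+", 50_000, 120_000,
                       ((50_000, 50_100), (119_900, 120_000)))
        thr = background_threshold(reads, [bg], p)
        res = estimate_wavefront(reads, g, p, thr)
        assert res.status == "ok"
        assert (res.velocity * p.release_time) % p.bin_size == 0


class TestIsoformSelection:
    def test_single_isoform_returned_unchanged(self, plus_gene):
        assert select_isoform([plus_gene], make_reads([])) is plus_gene

    def test_isoform_with_peak_at_its_tss_chosen(self):
        iso_a = GeneModel("g", "a", "chr1", "+", 0, 30_000, ((0, 30_000),))
        iso_b = GeneModel("g", "b", "chr1", "+", 10_000, 30_000, ((10_000, 30_000),))
        reads = make_reads([(10_010, 10_060)] * 50)  # peak at iso_b's TSS
        assert select_isoform([iso_a, iso_b], reads).transcript_id == "b"

    def test_no_reads_falls_back_to_longest(self):
        iso_a = GeneModel("g", "a", "chr1", "+", 0, 30_000, ((0, 30_000),))
        iso_b = GeneModel("g", "b", "chr1", "+", 10_000, 30_000, ((10_000, 30_000),))
        with pytest.warns(UserWarning, match="longest"):
            chosen = select_isoform([iso_a, iso_b], make_reads([(500_000, 500_100)]))
        assert chosen.transcript_id == "a"

    def test_matches_exhaustive_search_on_random_fixtures(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            isoforms = []
            for k in range(3):
                start = int(rng.integers(0, 20_000))
                end = start + int(rng.integers(25_000, 40_000))
                isoforms.append(
                    GeneModel("g", f"t{k}", "chr1", "+", start, end, ((start, end),))
                )
            intervals = [
                (int(x), int(x) + 50) for x in rng.integers(0, 30_000, size=200)
            ]
            reads = make_reads(intervals)
            chosen = select_isoform(isoforms, reads)
            # oracle: exhaustive per-isoform peak search
            def peak_dist(iso):
                edges = np.arange(iso.tss - 2000, iso.tss + 2000 + 300, 300)
                counts = reads.count_in_bins("chr1", edges, "+")
                if counts.sum() == 0:
                    return None
                centers = edges[:-1] + 150 - iso.tss
                return abs(int(centers[int(np.argmax(counts))]))
            dists = {iso.transcript_id: peak_dist(iso) for iso in isoforms}
            valid = {t: d for t, d in dists.items() if d is not None}
            if valid:
                best = min(
                    valid,
                    key=lambda t: (
                        valid[t],
                        -next(i.length for i in isoforms if i.transcript_id == t),
                        t,
                    ),
                )
                assert chosen.transcript_id == best
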