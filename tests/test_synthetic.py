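"""Statistical and structural properties of the synthetic-data generators."""

import numpy as np
import pytest

import rdcnv
from rdcnv.synthetic import gc_multiplier


class TestMakeGenome:
    def test_single_chromosome_near_requested_mean(self):
        g = rdcnv.make_genome(1, 1_000_000, seed=7)
        assert len(g.chromosomes) == 1
        name, length = g.chromosomes[0]
        assert 600_000 <= length <= 1_400_000
        assert length % 100 == 0

    def test_many_autosomes(self):
        g = rdcnv.make_genome(24, 100_000_000, seed=1)
        assert len(g.chromosomes) == 24
        assert len(set(g.names)) == 24
        assert g.total_length == sum(l for _, l in g.chromosomes)

    def test_deterministic_for_fixed_seed(self):
        assert rdcnv.make_genome(5, 2_000_000, seed=3) == rdcnv.make_genome(
            5, 2_000_000, seed=3)

    @pytest.mark.parametrize("n_chrom,mean_length", [(0, 1_000_000), (1, 500)])
    def test_rejects_degenerate_arguments(self, n_chrom, mean_length):
        with pytest.raises(ValueError):
            rdcnv.make_genome(n_chrom, mean_length, seed=0)


class TestImplantCnvs:
    def test_zero_events_is_empty(self, small_genome):
        assert rdcnv.implant_cnvs(small_genome, 0, seed=1) == []

    def test_pairwise_non_overlapping_by_all_pairs_scan(self):
        g = rdcnv.make_genome(3, 20_000_000, seed=4)
        truth = rdcnv.implant_cnvs(g, 150, seed=5, size_range=(1_000, 500_000))
        for i, a in enumerate(truth):
            for b in truth[i + 1:]:
                if a.chrom == b.chrom:
                    assert a.end <= b.start or b.end <= a.start

    def test_deletion_fraction_within_binomial_noise(self):
        g = rdcnv.make_genome(1, 50_000_000, seed=6)
        truth = rdcnv.implant_cnvs(
            g, 100, deletion_fraction=0.65, seed=7, size_range=(5_000, 100_000))
        n_del = sum(1 for t in truth if t.is_deletion)
        # 3 sigma around 65 of 100: sigma = sqrt(100 * .65 * .35) = 4.77
        assert abs(n_del - 65) <= 3 * 4.77

    def test_sizes_respect_range_and_bounds(self):
        g = rdcnv.make_genome(1, 50_000_000, seed=8)
        truth = rdcnv.implant_cnvs(g, 50, seed=9, size_range=(5_000, 4_900_000))
        for t in truth:
            assert 5_000 <= t.size <= 4_900_000
            assert 0 <= t.start < t.end <= g.length_of(t.chrom)
            assert t.copy_number != 2

    def test_infeasible_packing_reported(self, small_genome):
        with pytest.raises(RuntimeError):
            rdcnv.implant_cnvs(
                small_genome, 50, seed=1, size_range=(900_000, 1_000_000))


class TestSimulateDepth:
    def test_closed_form_mean_no_bias(self, small_genome):
        d = rdcnv.simulate_depth(
            small_genome, [], coverage=30, read_length=150, bin_size=100,
            gc_amplitude=0.0, seed=1)
        # expected per-bin mean: 30 * 100 / 150 = 20 reads
        assert d.mean_count() == pytest.approx(20.0, rel=0.01)

    def test_poisson_variance_to_mean(self, small_genome):
        d = rdcnv.simulate_depth(
            small_genome, [], coverage=30, read_length=150, bin_size=100,
            gc_amplitude=0.0, seed=2)
        counts = d.genome_counts()
        assert counts.size >= 10_000
        assert 0.9 <= counts.var() / counts.mean() <= 1.1

    def test_heterozygous_deletion_halves_depth(self):
        g = rdcnv.GenomeLayout((("chr1", 1_000_000),))
        t = rdcnv.TruthCNV("chr1", 200_000, 280_000, copy_number=1)
        d = rdcnv.simulate_depth(
            g, [t], coverage=30, read_length=150, bin_size=100,
            gc_amplitude=0.0, seed=3)
        c = d.chroms["chr1"].raw_count
        inside = c[2_000:2_800]      # 800 bins in the event
        flank = np.concatenate([c[:2_000], c[2_800:]])
        assert inside.mean() / flank.mean() == pytest.approx(0.5, abs=0.03)

    def test_coverage_scales_mean_threefold(self, small_genome):
        d10 = rdcnv.simulate_depth(small_genome, [], coverage=10,
                                   read_length=150, bin_size=100, seed=4)
        d30 = rdcnv.simulate_depth(small_genome, [], coverage=30,
                                   read_length=150, bin_size=100, seed=4)
        assert d30.mean_count() / d10.mean_count() == pytest.approx(3.0, rel=0.02)

    def test_gc_wave_shape_recovered_by_stratified_regression(self):
        g = rdcnv.GenomeLayout((("chr1", 10_000_000),))
        amp = 0.3
        d = rdcnv.simulate_depth(g, [], coverage=30, read_length=150,
                                 bin_size=100, gc_amplitude=amp, seed=5)
        c = d.chroms["chr1"]
        assert c.n_bins >= 10_000
        med = np.median(c.gc_fraction)
        expected = gc_multiplier(c.gc_fraction, med, amp)
        # mean depth per 1%-GC stratum recovers the implanted multiplier
        strata = (c.gc_fraction * 100).astype(int)
        for s in np.unique(strata):
            mask = strata == s
            if mask.sum() < 500:
                continue
            observed = c.raw_count[mask].mean() / 20.0
            assert observed == pytest.approx(expected[mask].mean(), rel=0.05)

    def test_q0_hotspots_above_half_elsewhere_zero(self, small_genome):
        hot = [("chr1", 100_000, 150_000)]
        d = rdcnv.simulate_depth(small_genome, [], coverage=30, read_length=150,
                                 bin_size=100, q0_hotspots=hot, seed=6)
        q0 = d.chroms["chr1"].q0_fraction
        assert (q0[1_000:1_500] > 0.5).all()
        assert q0[:1_000].sum() == 0 and q0[1_500:].sum() == 0

    def test_truth_outside_genome_rejected(self, small_genome):
        bad = rdcnv.TruthCNV("chr1", 1_999_000, 2_001_000, copy_number=1)
        with pytest.raises(ValueError):
            rdcnv.simulate_depth(small_genome, [bad], coverage=30, seed=1)

    def test_deterministic(self, small_genome):
        d1 = rdcnv.simulate_depth(small_genome, [], coverage=10, seed=9)
        d2 = rdcnv.simulate_depth(small_genome, [], coverage=10, seed=9)
        for name in small_genome.names:
            np.testing.assert_array_equal(
                d1.chroms[name].raw_count, d2.chroms[name].raw_count)


class TestSynthCallset:
    def test_zero_calls(self, small_genome):
        assert rdcnv.synth_callset(small_genome, 0, seed=1) == []

    def test_type_proportions_recovered(self, small_genome):
        calls = rdcnv.synth_callset(
            small_genome, 10_000, deletion_fraction=0.65, seed=2)
        n_del = sum(1 for c in calls if c.type == rdcnv.DELETION)
        # 4 sigma of Binomial(10000, .65)
        assert abs(n_del - 6_500) <= 4 * np.sqrt(10_000 * 0.65 * 0.35)

    def test_attributes_consistent_with_type(self, small_genome):
        for c in rdcnv.synth_callset(small_genome, 500, seed=3):
            if c.type == rdcnv.DELETION:
                assert c.normalized_rd < 1
            else:
                assert c.normalized_rd > 1
            assert 0 <= c.p_value <= 1 and 0 <= c.q0 <= 1


class TestMakeAnnotation:
    def test_zero_genes(self, small_genome):
        assert rdcnv.make_annotation(small_genome, 0, seed=1) == []

    def test_unique_stable_ids_and_valid_intervals(self, small_genome):
        genes = rdcnv.make_annotation(small_genome, 300, seed=2)
        assert len({g.gene_id for g in genes}) == 300
        for g in genes:
            assert 0 <= g.start < g.end <= small_genome.length_of(g.chrom)

    def test_density_window_counts_sum_to_total(self, small_genome):
        genes = rdcnv.make_annotation(small_genome, 250, seed=3)
        track = rdcnv.gene_density(genes, small_genome, window=1_000_000)
        assert sum(track.chrom_totals.values()) == 250
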