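"""Rebinning, GC correction and the mean/sd bin-size rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rdcnv
from rdcnv.depth import BinnedDepth, ChromDepth


def flat_depth(counts, gc=None, q0=None, bin_size=100):
    counts = np.asarray(counts, dtype=float)
    gc = np.full(len(counts), 0.45) if gc is None else np.asarray(gc)
    q0 = np.zeros(len(counts)) if q0 is None else np.asarray(q0)
    return BinnedDepth(bin_size=bin_size, chroms={
        "chr1": ChromDepth(raw_count=counts, gc_fraction=gc, q0_fraction=q0)})


class TestRebin:
    def test_identity_factor(self):
        d = flat_depth([1, 2, 3, 4])
        assert rdcnv.rebin(d, 1) is d

    def test_group_sums(self):
        d = flat_depth([1, 2, 3, 4])
        out = rdcnv.rebin(d, 2)
        np.testing.assert_array_equal(out.chroms["chr1"].raw_count, [3, 7])
        assert out.bin_size == 200

    def test_partial_tail_dropped_total_conserved(self):
        d = flat_depth([5, 1, 2, 9, 7])
        out = rdcnv.rebin(d, 2)
        np.testing.assert_array_equal(out.chroms["chr1"].raw_count, [6, 11])
        assert out.chroms["chr1"].raw_count.sum() == 17  # 7 in the dropped tail

    def test_fraction_averaging(self):
        d = flat_depth([1, 1], gc=[0.3, 0.5], q0=[0.0, 1.0])
        out = rdcnv.rebin(d, 2)
        assert out.chroms["chr1"].gc_fraction[0] == pytest.approx(0.4)
        assert out.chroms["chr1"].q0_fraction[0] == pytest.approx(0.5)

    def test_rejects_nonpositive_factor(self):
        with pytest.raises(ValueError):
            rdcnv.rebin(flat_depth([1]), 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(2, 4), st.integers(2, 4), st.integers(0, 3))
    def test_rebin_composes(self, a, b, extra):
        n = a * b * 5 + extra
        rng = np.random.default_rng(n)
        d = flat_depth(rng.poisson(10, n), gc=rng.uniform(0.3, 0.6, n))
        lhs = rdcnv.rebin(rdcnv.rebin(d, a), b)
        rhs = rdcnv.rebin(d, a * b)
        # equal on lengths divisible by a*b; the generic case may differ in
        # the dropped tail only
        m = min(lhs.chroms["chr1"].n_bins, rhs.chroms["chr1"].n_bins)
        np.testing.assert_allclose(
            lhs.chroms["chr1"].raw_count[:m], rhs.chroms["chr1"].raw_count[:m])


class TestGcCorrect:
    def test_flat_gc_is_identity(self):
        rng = np.random.default_rng(0)
        d = flat_depth(rng.poisson(20, 5_000))
        out = rdcnv.gc_correct(d)
        np.testing.assert_allclose(
            out.chroms["chr1"].corrected_count, d.chroms["chr1"].raw_count,
            rtol=1e-12)

    def test_quadratic_bias_flattened(self):
        g = rdcnv.GenomeLayout((("chr1", 10_000_000),))
        d = rdcnv.simulate_depth(g, [], coverage=30, read_length=150,
                                 bin_size=100, gc_amplitude=0.3, seed=12)
        out = rdcnv.gc_correct(d)
        c = out.chroms["chr1"]
        mean = out.mean_count()
        # the wave is quadratic around the median GC: check its curvature
        x = c.gc_fraction - np.median(c.gc_fraction)
        curv_raw = np.polyfit(x, c.raw_count, 2)[0]
        curv_corr = np.polyfit(x, c.corrected_count, 2)[0]
        assert abs(curv_raw) > 10 * abs(curv_corr)
        slope_corr = np.polyfit(c.gc_fraction, c.corrected_count, 1)[0]
        assert abs(slope_corr) < 0.02 * mean

    def test_mean_preserved_and_nonnegative(self):
        g = rdcnv.GenomeLayout((("chr1", 5_000_000),))
        d = rdcnv.simulate_depth(g, [], coverage=30, read_length=150,
                                 bin_size=100, gc_amplitude=0.25, seed=13)
        out = rdcnv.gc_correct(d)
        assert out.mean_count(corrected=True) == pytest.approx(
            d.mean_count(corrected=False), rel=1e-3)
        assert (out.chroms["chr1"].corrected_count >= 0).all()

    def test_idempotent(self):
        g = rdcnv.GenomeLayout((("chr1", 2_000_000),))
        d = rdcnv.simulate_depth(g, [], coverage=30, read_length=150,
                                 bin_size=100, gc_amplitude=0.25, seed=14)
        once = rdcnv.gc_correct(d)
        # correcting a signal whose waves are already removed changes nothing
        rebuilt = BinnedDepth(bin_size=once.bin_size, chroms={
            "chr1": ChromDepth(
                raw_count=once.chroms["chr1"].corrected_count,
                gc_fraction=once.chroms["chr1"].gc_fraction,
                q0_fraction=once.chroms["chr1"].q0_fraction)})
        twice = rdcnv.gc_correct(rebuilt)
        np.testing.assert_allclose(
            twice.chroms["chr1"].corrected_count,
            once.chroms["chr1"].corrected_count, rtol=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            rdcnv.gc_correct(flat_depth(np.zeros(100)))

    def test_dead_zones_excluded_from_mean(self):
        # bins with q0 == 1 carry zero counts but must not deflate the mean
        counts = np.concatenate([np.full(1000, 20.0), np.zeros(100)])
        q0 = np.concatenate([np.zeros(1000), np.ones(100)])
        d = flat_depth(counts, q0=q0)
        assert d.mean_count() == pytest.approx(20.0)


class TestSelectBinSize:
    @staticmethod
    def poisson_depth(lam, n_bins=200_000, seed=0):
        rng = np.random.default_rng(seed)
        return flat_depth(rng.poisson(lam, n_bins))

    def test_mean20_keeps_100bp(self):
        # Poisson(20): mean/sd = sqrt(20) = 4.47, inside [4, 5]
        choice = rdcnv.select_bin_size(self.poisson_depth(20), [100, 1000])
        assert choice.bin_size == 100
        assert 4.0 <= choice.ratio <= 5.0

    def test_mean2_needs_1000bp(self):
        # Poisson(2): sqrt(2) = 1.41; after x10 rebin sqrt(20) = 4.47
        choice = rdcnv.select_bin_size(self.poisson_depth(2), [100, 1000])
        assert choice.bin_size == 1000
        assert 4.0 <= choice.ratio <= 5.0

    def test_predicted_candidate_across_lambdas(self):
        # analytic rule: ratio at factor f is sqrt(lambda * f)
        for lam, candidates, expect in [
            (4, [100, 200, 600, 1000], 600),   # sqrt(4*6) = 4.90
            (8, [100, 300, 1000], 300),        # sqrt(8*3) = 4.90
        ]:
            choice = rdcnv.select_bin_size(
                self.poisson_depth(lam, seed=lam), candidates)
            predicted = min(
                (c for c in candidates if 4 <= np.sqrt(lam * c / 100) <= 5),
                default=min(candidates,
                            key=lambda c: abs(np.sqrt(lam * c / 100) - 4.5)))
            assert choice.bin_size == predicted == expect

    def test_single_candidate_returned(self):
        choice = rdcnv.select_bin_size(self.poisson_depth(7, 10_000), [100])
        assert choice.bin_size == 100

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            rdcnv.select_bin_size(self.poisson_depth(5, 1_000), [])
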