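"""Binning arithmetic, count conservation, GC-trend removal and
copy-number normalisation invariants."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st
from scipy import stats

from embryoscreen import (
    BinProfile,
    KaryotypeSpec,
    ReadSimConfig,
    count_reads,
    gc_correct,
    mito_stats,
    normalize_cn,
    simulate_reads,
)
from embryoscreen.exceptions import InputMismatchError, NoSignalError
from embryoscreen.synthetic import gc_bias_weight
from tests.conftest import tiny_genome


def reads_df(pairs):
    return pd.DataFrame(
        {"chrom": [c for c, _ in pairs], "start": [p for _, p in pairs]}
    )


class TestCountReads:
    def test_direct_placement(self):
        g = tiny_genome(n_bins=5, bin_size=20)
        prof = count_reads(reads_df([("c1", 0), ("c1", 10), ("c1", 21)]), g)
        assert prof.raw_counts.tolist() == [2, 1, 0, 0, 0]

    def test_empty_input(self):
        g = tiny_genome()
        prof = count_reads(reads_df([]), g)
        assert prof.raw_counts.sum() == 0
        assert prof.genome_mean_depth == 0.0

    def test_count_conservation_exact(self):
        g = tiny_genome(n_bins=50, bin_size=100)
        rng = np.random.default_rng(0)
        pairs = [("c1", int(p)) for p in rng.integers(0, 5000, 500)]
        pairs += [("chrM", int(p)) for p in rng.integers(0, g.mito_length, 30)]
        pairs += [("c1", 99999)] * 3  # out of bounds
        pairs += [("weird", 5)] * 2  # unknown contig, below tolerance
        prof = count_reads(reads_df(pairs), g, unknown_chrom_tolerance=0.05)
        assert (
            prof.raw_counts.sum() + prof.mito_read_count + prof.dropped_reads
            == len(pairs)
        )

    def test_unknown_contig_fraction_rejected(self):
        g = tiny_genome()
        pairs = [("c1", 0)] * 90 + [("alien", 0)] * 10
        with pytest.raises(InputMismatchError):
            count_reads(reads_df(pairs), g, unknown_chrom_tolerance=0.01)

    def test_uniform_poisson_bound(self):
        g = tiny_genome(n_bins=100, bin_size=1000)
        rng = np.random.default_rng(1)
        pos = rng.integers(0, 100_000, 100_000)
        prof = count_reads(reads_df([("c1", int(p)) for p in pos]), g)
        assert np.all(np.abs(prof.raw_counts - 1000) < 5 * np.sqrt(1000))


def biased_profile(n_bins=1000, seed=0, flat_counts=False):
    """Counts exactly proportional to the bias curve on a smooth GC track."""
    rng = np.random.default_rng(seed)
    gc = np.clip(0.45 + 0.12 * np.sin(np.arange(n_bins) / 25) +
                 rng.normal(0, 0.02, n_bins), 0.25, 0.65)
    g = tiny_genome(n_bins=n_bins, bin_size=1000, gc=gc)
    w = gc_bias_weight(gc, ReadSimConfig())
    counts = np.full(n_bins, 1000.0) if flat_counts else 1000.0 * w
    prof = BinProfile(sample_id="s", raw_counts=counts.round().astype(int))
    return g, prof


class TestGcCorrect:
    def test_recovers_injected_bias_curve(self):
        g, prof = biased_profile()
        corr = gc_correct(prof, g, method="loess", span=0.15).gc_corrected
        assert (corr.max() - corr.min()) / corr.mean() < 0.01

    def test_flat_counts_unchanged(self):
        g, prof = biased_profile(flat_counts=True)
        corr = gc_correct(prof, g, method="loess").gc_corrected
        ratio = corr / prof.raw_counts
        assert ratio.min() > 0.99 and ratio.max() < 1.01

    def test_residual_gc_independence(self):
        # simulated euploid sample with GC bias on: post-correction r ~ 0
        from embryoscreen import make_synthetic_genome, SyntheticGenomeSpec
        spec = SyntheticGenomeSpec(
            autosome_lengths=(50_000_000, 50_000_000), include_sex_chromosomes=False
        )
        g = make_synthetic_genome(spec, seed=2, bin_size=100_000)
        cfg = ReadSimConfig(n_reads=1_000_000, seed=3)
        prof = count_reads(simulate_reads(g, KaryotypeSpec(), cfg), g)
        corr = gc_correct(prof, g).gc_corrected
        r = stats.pearsonr(corr, g.gc_per_bin).statistic
        assert abs(r) < 0.05

    def test_mass_conservation(self):
        g, prof = biased_profile()
        corr = gc_correct(prof, g).gc_corrected
        assert abs(corr.sum() - prof.raw_counts.sum()) < 1e-3 * prof.raw_counts.sum()

    def test_degenerate_gc_is_identity_with_warning(self):
        g = tiny_genome(n_bins=100, bin_size=1000, gc=np.full(100, 0.5))
        prof = BinProfile("s", np.full(100, 50))
        with pytest.warns(UserWarning):
            corr = gc_correct(prof, g)
        assert np.array_equal(corr.gc_corrected, prof.raw_counts)

    def test_too_few_nonzero_bins_rejected(self):
        g = tiny_genome(n_bins=60, bin_size=1000)
        counts = np.zeros(60, dtype=int)
        counts[:20] = 5
        with pytest.raises(NoSignalError):
            gc_correct(BinProfile("s", counts), g)

    def test_stratified_fallback_on_tiny_genome(self):
        g, prof = biased_profile(n_bins=150)
        corr = gc_correct(prof, g, method="auto").gc_corrected  # < 200 bins
        assert (corr.max() - corr.min()) / corr.mean() < 0.25


class TestNormalizeCn:
    def test_constant_counts_give_exact_diploid(self):
        g = tiny_genome(n_bins=100, bin_size=1000)
        prof = BinProfile("s", np.full(100, 7), gc_corrected=np.full(100, 7.0))
        out = normalize_cn(prof, g)
        assert np.allclose(out.cn_ratio, 2.0, atol=1e-12)
        assert out.sample_mad == 0.0

    def test_trisomy_algebra_noise_free(self):
        # one chromosome at 1.5x spanning < half the genome: median untouched
        g = tiny_genome(n_bins=30, bin_size=1000)
        counts = np.full(30, 100.0)
        counts[:10] *= 1.5
        out = normalize_cn(BinProfile("s", counts, gc_corrected=counts), g)
        assert np.allclose(out.cn_ratio[:10], 3.0)
        assert np.allclose(out.cn_ratio[10:], 2.0)

    @given(c=st.floats(min_value=1e-6, max_value=1e6))
    @settings(deadline=None, max_examples=40)
    def test_scale_invariance(self, c):
        g = tiny_genome(n_bins=20, bin_size=1000)
        base = np.linspace(50, 150, 20)
        a = normalize_cn(BinProfile("s", base, gc_corrected=base), g).cn_ratio
        b = normalize_cn(BinProfile("s", base, gc_corrected=base * c), g).cn_ratio
        assert np.allclose(a, b, atol=1e-12, rtol=1e-9)

    def test_autosomal_median_is_two(self):
        rng = np.random.default_rng(5)
        g = tiny_genome(n_bins=101, bin_size=1000)
        counts = rng.gamma(50, 2, 101)
        out = normalize_cn(BinProfile("s", counts, gc_corrected=counts), g)
        assert abs(np.median(out.cn_ratio) - 2.0) < 1e-9

    def test_sex_chromosomes_excluded_from_baseline(self):
        g = tiny_genome(n_bins=20, bin_size=1000, with_sex=True)
        corr = np.full(60, 100.0)
        corr[20:40] = 50.0  # X at half depth (XY-like)
        corr[40:] = 50.0    # Y
        out = normalize_cn(BinProfile("s", corr, gc_corrected=corr), g)
        assert np.allclose(out.cn_ratio[:20], 2.0)
        assert np.allclose(out.cn_ratio[20:], 1.0)

    def test_zero_median_rejected(self):
        g = tiny_genome(n_bins=10, bin_size=1000)
        z = np.zeros(10)
        with pytest.raises(NoSignalError):
            normalize_cn(BinProfile("s", z, gc_corrected=z), g)

    def test_euploid_simulation_mean_near_two(self):
        from embryoscreen import make_synthetic_genome, SyntheticGenomeSpec
        spec = SyntheticGenomeSpec(
            autosome_lengths=(50_000_000, 50_000_000), include_sex_chromosomes=False
        )
        g = make_synthetic_genome(spec, seed=9)
        cfg = ReadSimConfig(n_reads=300_000, seed=10)
        prof = count_reads(simulate_reads(g, KaryotypeSpec(), cfg), g)
        out = normalize_cn(gc_correct(prof, g), g)
        assert 1.95 <= out.cn_ratio.mean() <= 2.05


class TestMitoStats:
    def test_ratio_arithmetic(self):
        prof = BinProfile("s", np.zeros(1), genome_mean_depth=0.07,
                          mito_mean_depth=10.0, mito_fraction_covered=0.99)
        ratio, frac = mito_stats(prof)
        assert ratio == pytest.approx(142.857142857)
        assert frac == 0.99

    def test_linearity_in_mito_depth(self):
        prof = BinProfile("s", np.zeros(1), genome_mean_depth=0.1,
                          mito_mean_depth=5.0)
        doubled = replace(prof, mito_mean_depth=10.0)
        assert mito_stats(doubled)[0] == 2 * mito_stats(prof)[0]

    def test_zero_genome_depth_rejected(self):
        prof = BinProfile("s", np.zeros(1), genome_mean_depth=0.0,
                          mito_mean_depth=1.0)
        with pytest.raises(NoSignalError):
            mito_stats(prof)

    def test_simulated_ratio_near_configured(self):
        from embryoscreen import make_synthetic_genome, SyntheticGenomeSpec
        spec = SyntheticGenomeSpec(
            autosome_lengths=(50_000_000, 50_000_000), include_sex_chromosomes=False
        )
        g = make_synthetic_genome(spec, seed=1)
        cfg = ReadSimConfig(n_reads=300_000, mito_mean_depth_ratio=100.0, seed=12)
        prof = count_reads(simulate_reads(g, KaryotypeSpec(), cfg), g)
        ratio, frac = mito_stats(prof)
        assert 90 <= ratio <= 110
        assert frac > 0.9
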