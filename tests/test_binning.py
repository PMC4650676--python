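import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scwga_cnv import (
    BinnedCounts,
    build_genome,
    count_reads,
    make_fixed_bins,
    make_variable_bins,
    normalize_counts,
    ratio_vector,
    uniformity_summary,
)


def one_chrom_genome(length, window=10_000, seed=0):
    return build_genome(n_chromosomes=2, chrom_length=[length, length],
                        window_size=window, x_length=None, seed=seed)


class TestFixedBins:
    def test_exact_tiling_counts(self):
        g = one_chrom_genome(10_000_000)
        bins = make_fixed_bins(g, 500_000)
        assert (bins.chrom == "chr1").sum() == 20

    def test_short_terminal_bin_kept_or_dropped(self):
        g = one_chrom_genome(1_250_000)
        bins = make_fixed_bins(g, 500_000)
        chr1 = bins.chrom_slice("chr1")
        assert chr1.stop - chr1.start == 3
        assert bins.end[chr1.stop - 1] - bins.start[chr1.stop - 1] == 250_000
        dropped = make_fixed_bins(g, 500_000, drop_short_last=True)
        chr1 = dropped.chrom_slice("chr1")
        assert chr1.stop - chr1.start == 2

    def test_tiling_partition_exact(self, default_genome):
        bins = make_fixed_bins(default_genome, 500_000)
        for chrom in default_genome.chrom_names:
            sl = bins.chrom_slice(chrom)
            assert bins.start[sl][0] == 0
            assert bins.end[sl][-1] == default_genome.length(chrom)
            np.testing.assert_array_equal(bins.start[sl][1:], bins.end[sl][:-1])

    def test_bin_gc_is_weighted_window_mean(self):
        from scwga_cnv import GenomeModel

        g = GenomeModel(
            chrom_names=["chr1"], chrom_lengths=np.array([120]), window_size=60,
            gc={"chr1": np.array([0.3, 0.5])},
        )
        bins = make_fixed_bins(g, 120)
        assert bins.gc[0] == pytest.approx(0.4)

    def test_invalid_bin_size_rejected(self, small_genome):
        with pytest.raises(ValueError):
            make_fixed_bins(small_genome, 0)
        with pytest.raises(ValueError):
            make_fixed_bins(small_genome, small_genome.window_size // 2)


class TestVariableBins:
    def test_uniform_track_gives_equal_bins(self):
        g = one_chrom_genome(10_000_000)
        track = {c: np.ones(g.n_windows(c)) for c in g.chrom_names}
        bins = make_variable_bins(g, track, target_reads_per_bin=100)
        sizes = bins.sizes
        assert np.all(sizes[:-1] == sizes[0])  # equal-length except merged last

    def test_denser_half_gives_shorter_bins(self):
        g = one_chrom_genome(1_000_000, window=10_000)
        n = g.n_windows("chr1")
        track = {c: np.ones(g.n_windows(c)) for c in g.chrom_names}
        track["chr1"] = np.concatenate([np.full(n // 2, 2.0), np.full(n - n // 2, 1.0)])
        bins = make_variable_bins(g, track, target_reads_per_bin=10)
        sl = bins.chrom_slice("chr1")
        left = bins.sizes[sl][bins.start[sl] < 500_000]
        right = bins.sizes[sl][bins.start[sl] >= 500_000]
        assert left.mean() * 1.8 < right.mean()  # ~half the length where twice as dense

    def test_target_above_total_gives_single_bin(self):
        g = one_chrom_genome(1_000_000)
        track = {c: np.ones(g.n_windows(c)) for c in g.chrom_names}
        bins = make_variable_bins(g, track, target_reads_per_bin=10_000)
        for chrom in g.chrom_names:
            sl = bins.chrom_slice(chrom)
            assert sl.stop - sl.start == 1
            assert bins.end[sl][0] == g.length(chrom)

    def test_variable_bins_reduce_expected_count_cv(self):
        # CV of expected reads: variable bins < fixed bins on a non-uniform track
        g = one_chrom_genome(10_000_000, window=10_000, seed=4)
        rng = np.random.default_rng(0)
        track = {c: np.exp(rng.normal(0, 0.8, g.n_windows(c))) for c in g.chrom_names}
        fixed = make_fixed_bins(g, 500_000)
        variable = make_variable_bins(
            g, track, target_reads_per_bin=sum(t.sum() for t in track.values()) / len(fixed)
        )

        def expected_per_bin(bins):
            out = []
            for chrom in g.chrom_names:
                sl = bins.chrom_slice(chrom)
                edges = np.concatenate([bins.start[sl], [bins.end[sl][-1]]]) // 10_000
                cs = np.concatenate([[0.0], np.cumsum(track[chrom])])
                out.append(np.diff(cs[edges]))
            return np.concatenate(out)

        cv = lambda v: v.std() / v.mean()
        assert cv(expected_per_bin(variable)) < cv(expected_per_bin(fixed))

    def test_zero_expectation_chromosome_skipped(self):
        g = one_chrom_genome(1_000_000)
        track = {"chr1": np.ones(g.n_windows("chr1")), "chrX": np.zeros(g.n_windows("chrX"))}
        with pytest.warns(UserWarning, match="zero total"):
            bins = make_variable_bins(g, track, target_reads_per_bin=10)
        assert set(bins.chrom) == {"chr1"}


class TestCountReads:
    def test_half_open_assignment(self):
        g = one_chrom_genome(10_000_000)
        bins = make_fixed_bins(g, 500_000)
        counts = count_reads({"chr1": np.array([0, 499_999, 500_000])}, bins)
        sl = bins.chrom_slice("chr1")
        assert counts.counts[sl][0] == 2
        assert counts.counts[sl][1] == 1
        assert counts.counts[sl][2:].sum() == 0

    def test_empty_read_set(self, small_genome):
        bins = make_fixed_bins(small_genome, 500_000)
        counts = count_reads({}, bins)
        assert counts.counts.sum() == 0
        assert counts.total_reads == 0

    def test_uniform_reads_binomial_oracle(self):
        g = one_chrom_genome(10_000_000)
        bins = make_fixed_bins(g, 500_000)
        rng = np.random.default_rng(11)
        pos = rng.integers(0, 10_000_000, size=10_000)
        counts = count_reads({"chr1": pos}, bins)
        sl = bins.chrom_slice("chr1")
        sd = np.sqrt(10_000 * (1 / 20) * (19 / 20))
        assert np.all(np.abs(counts.counts[sl] - 500) < 5 * sd)

    def test_count_conservation_with_unknown_chrom(self, small_genome):
        bins = make_fixed_bins(small_genome, 500_000)
        reads = {"chr1": np.array([10, 20]), "chrUn": np.array([5])}
        with pytest.warns(UserWarning, match="unknown"):
            counts = count_reads(reads, bins)
        assert counts.total_reads == 3
        assert counts.counts.sum() == 2
        with pytest.raises(ValueError):
            count_reads(reads, bins, unknown_chrom="error")


class TestNormalizeAndRatios:
    def test_ten_million_convention(self, small_genome):
        bins = make_fixed_bins(small_genome, 500_000)
        counts = BinnedCounts("s", bins, np.full(len(bins), 500_000), 20_000_000)
        scaled = normalize_counts(counts)
        np.testing.assert_allclose(scaled, counts.counts * 0.5)
        assert scaled.sum() == pytest.approx(10_000_000)

    def test_small_example(self, small_genome):
        bins = make_fixed_bins(small_genome, 500_000)
        c = np.zeros(len(bins))
        c[:3] = [1, 1, 2]
        counts = BinnedCounts("s", bins, c, 4)
        np.testing.assert_allclose(normalize_counts(counts, target_total=8)[:3], [2, 2, 4])

    def test_zero_total_rejected(self, small_genome):
        bins = make_fixed_bins(small_genome, 500_000)
        with pytest.raises(ValueError):
            normalize_counts(BinnedCounts("s", bins, np.zeros(len(bins)), 0))

    def test_ratio_examples_and_scale_invariance(self, small_genome):
        bins = make_fixed_bins(small_genome, 500_000)
        n = len(bins)
        counts = BinnedCounts("s", bins, np.tile([10, 30], n // 2), 20 * n)
        rv = ratio_vector(counts, scope="all")
        np.testing.assert_allclose(rv.values[:2], [0.5, 1.5])
        assert rv.values.mean() == pytest.approx(1.0, abs=1e-9)
        scaled = BinnedCounts("s", bins, counts.counts * 7, counts.total_reads * 7)
        np.testing.assert_allclose(ratio_vector(scaled, scope="all").values, rv.values)

    def test_autosome_scope_excludes_x_from_baseline(self, small_genome):
        bins = make_fixed_bins(small_genome, 500_000)
        c = np.where(bins.autosomal, 100, 50)
        rv = ratio_vector(BinnedCounts("s", bins, c, int(c.sum())), scope="autosomes")
        assert rv.values[bins.autosomal].mean() == pytest.approx(1.0)
        assert rv.values[~bins.autosomal].mean() == pytest.approx(0.5)


class TestUniformitySummary:
    def test_constant_ratios(self, small_genome):
        bins = make_fixed_bins(small_genome, 500_000)
        counts = BinnedCounts("s", bins, np.full(len(bins), 7), 7 * len(bins))
        q = uniformity_summary(ratio_vector(counts, scope="all"))
        assert q.q1 == q.median == q.q3 == pytest.approx(1.0)
        assert q.iqr == pytest.approx(0.0)

    def test_quartiles_match_percentile_oracle(self, small_genome):
        bins = make_fixed_bins(small_genome, 500_000)
        n = len(bins)
        vals = np.arange(1, n + 1, dtype=float)
        counts = BinnedCounts("s", bins, vals, int(vals.sum()))
        rv = ratio_vector(counts, scope="all")
        q = uniformity_summary(rv)
        assert q.q1 == pytest.approx(np.percentile(rv.values, 25))
        assert q.q3 == pytest.approx(np.percentile(rv.values, 75))

    def test_wider_dispersion_wider_iqr(self, small_genome):
        bins = make_fixed_bins(small_genome, 500_000)
        n = len(bins)
        rng = np.random.default_rng(2)
        base = rng.poisson(100, n).astype(float) + 1
        narrow = BinnedCounts("a", bins, base, int(base.sum()))
        wide_vals = (base - base.mean()) * 3 + base.mean()
        wide = BinnedCounts("b", bins, wide_vals - wide_vals.min() + 1, 1)
        q_n = uniformity_summary(ratio_vector(narrow, scope="all"))
        q_w = uniformity_summary(ratio_vector(wide, scope="all"))
        assert q_w.iqr > q_n.iqr


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    length=st.integers(min_value=100_000, max_value=3_000_000),
    bin_size=st.sampled_from([100_000, 250_000, 500_000]),
)
def test_tiling_and_conservation_properties(length, bin_size):
    g = build_genome(n_chromosomes=2, chrom_length=[length, length],
                     window_size=10_000, x_length=None, seed=0)
    bins = make_fixed_bins(g, bin_size)
    for chrom in g.chrom_names:
        sl = bins.chrom_slice(chrom)
        assert bins.start[sl][0] == 0 and bins.end[sl][-1] == length
        assert np.all(bins.start[sl][1:] == bins.end[sl][:-1])  # no gaps/overlaps
    rng = np.random.default_rng(length + bin_size)
    reads = {c: rng.integers(0, length, 500) for c in g.chrom_names}
    counts = count_reads(reads, bins)
    assert counts.counts.sum() == 1000 == counts.total_reads
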