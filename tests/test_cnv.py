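import numpy as np
import pytest

from scwga_cnv import (
    CNVSpec,
    SegmentationParams,
    call_cnvs,
    cbs_segment,
    log2_cnr_signal,
    lowess_correct,
    make_fixed_bins,
    round_copy,
    segment_copy_number,
    segment_sample,
    simulate_sample,
)
from scwga_cnv.cnv import Segment, best_split, candidate_pairs


def brute_force_best_split(x, min_width):
    """Independent oracle: plain-loop enumeration of all circular arc pairs
    with the pooled two-sample t^2 statistic."""
    n = len(x)
    total = x.sum()
    ss_tot = np.sum(x**2) - total**2 / n
    best = None
    for i in range(min_width, n - min_width + 1):
        for j in range(i + min_width, n + 1):
            if j != n and n - j < min_width:
                continue
            k = j - i
            s_in = x[i:j].sum()
            d = s_in / k - (total - s_in) / (n - k)
            between = d * d * k * (n - k) / n
            s2 = max(ss_tot - between, 0.0) / max(n - 2, 1)
            t2 = between / max(s2, 1e-300)
            if best is None or t2 > best[2] + 1e-9:
                best = (i, j, t2)
    return best


def make_segment(chrom, start_bp, end_bp, n_bins, mean, copy=None):
    return Segment(chrom=chrom, start_bin=0, end_bin=n_bins, start_bp=start_bp,
                   end_bp=end_bp, n_bins=n_bins, mean=mean, copy_number=copy)


class TestSegmentationParams:
    @pytest.mark.parametrize(
        "kwargs",
        [{"alpha": 0.0}, {"alpha": 1.0}, {"nperm": 10}, {"min_width": 1}, {"undo_sd": -1}],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SegmentationParams(**kwargs)


class TestCbsSegment:
    def test_constant_vector_single_segment(self):
        segs = cbs_segment(np.zeros(200), SegmentationParams(seed=0))
        assert len(segs) == 1
        assert segs[0][:2] == (0, 200)

    def test_clean_step_found_at_boundary(self):
        rng = np.random.default_rng(10)
        x = np.concatenate([rng.normal(0, 0.05, 50), rng.normal(1, 0.05, 50)])
        segs = cbs_segment(x, SegmentationParams(seed=1))
        assert len(segs) == 2
        assert abs(segs[0][1] - 50) <= 1
        assert segs[0][2] == pytest.approx(0, abs=0.05)
        assert segs[1][2] == pytest.approx(1, abs=0.05)

    def test_first_split_matches_brute_force(self):
        # exhaustive max-statistic oracle over all arc pairs (small vectors)
        rng = np.random.default_rng(2)
        for _ in range(40):
            n = int(rng.integers(10, 31))
            x = rng.normal(0, 1, n)
            if rng.random() < 0.5:  # implant a shift so both regimes occur
                a, b = sorted(rng.integers(0, n, 2))
                x[a:b] += rng.normal(0, 2)
            found = best_split(x, 5)
            oracle = brute_force_best_split(x, 5)
            assert (found is None) == (oracle is None)
            if found is not None:
                assert found[:2] == oracle[:2]
                assert found[2] == pytest.approx(oracle[2], rel=1e-9)

    def test_pure_noise_rarely_splits(self):
        rng = np.random.default_rng(3)
        n_split = sum(
            len(cbs_segment(rng.standard_normal(100), SegmentationParams(seed=k))) > 1
            for k in range(50)
        )
        assert n_split <= 5  # ~alpha-level type-I control

    def test_short_chromosome_flagged(self):
        segs = cbs_segment(np.array([1.0, 2.0, 3.0]), SegmentationParams(min_width=5))
        assert len(segs) == 1
        assert segs[0][3] == "short_chromosome"

    def test_min_width_respected_in_candidates(self):
        pi, pj = candidate_pairs(20, 5)
        pieces_ok = (
            (pi >= 5)
            & ((pj - pi) >= 5)
            & ((pj == 20) | (20 - pj >= 5))
        )
        assert np.all(pieces_ok)
        # each candidate is a distinct partition (no prefix/complement aliases)
        assert len({(a, b) for a, b in zip(pi, pj)}) == pi.size

    def test_sd_undo_merges_sub_noise_steps(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1.0, 200)
        x[100:] += 0.1  # far below one noise sd
        params = SegmentationParams(seed=5, undo_sd=1.0)
        segs = cbs_segment(x, params)
        assert len(segs) == 1

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            cbs_segment(np.array([1.0, np.nan, 2.0, 3.0, 4.0]), SegmentationParams())

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 150)
        x[60:90] += 1.5
        a = cbs_segment(x, SegmentationParams(seed=7))
        b = cbs_segment(x, SegmentationParams(seed=7))
        assert a == b


class TestSegmentSample:
    def test_partition_covers_every_bin(self, default_genome, default_bins):
        rng = np.random.default_rng(8)
        signal = rng.normal(0, 0.2, len(default_bins))
        segs = segment_sample(signal, default_bins, SegmentationParams(seed=9))
        covered = np.zeros(len(default_bins), dtype=int)
        for s in segs:
            covered[s.start_bin : s.end_bin] += 1
        assert np.all(covered == 1)

    def test_segment_bp_coordinates_match_bins(self, default_bins):
        signal = np.zeros(len(default_bins))
        segs = segment_sample(signal, default_bins, SegmentationParams(seed=0))
        for s in segs:
            assert s.start_bp == default_bins.start[s.start_bin]
            assert s.end_bp == default_bins.end[s.end_bin - 1]


class TestCopyNumber:
    def test_copy_number_arithmetic(self, default_bins):
        counts = np.full(len(default_bins), 100.0)
        sl = default_bins.chrom_slice("chrX")
        counts[sl] = 50.0
        segs = [
            make_segment("chr1", 0, 40_000_000, 80, 0.0),
            make_segment("chrX", 0, 30_000_000, 60, -1.0),
        ]
        segs[0].start_bin, segs[0].end_bin = 0, 80
        segs[1].start_bin, segs[1].end_bin = sl.start, sl.stop
        segs = segment_copy_number(segs, counts, default_bins)
        assert segs[0].copy_number == pytest.approx(2.0, rel=1e-3)
        assert segs[1].copy_number == pytest.approx(1.0, rel=1e-3)  # male X

    def test_fifty_percent_gain_gives_copy_three(self, default_bins):
        counts = np.full(len(default_bins), 100.0)
        counts[:10] = 151.57  # adjust so autosomal mean gives exactly 1.5x
        seg = make_segment("chr1", 0, 5_000_000, 10, 0.6)
        seg.start_bin, seg.end_bin = 0, 10
        auto_mean = counts[default_bins.autosomal].mean()
        [seg] = segment_copy_number([seg], counts, default_bins)
        assert seg.copy_number == pytest.approx(2 * 151.57 / auto_mean)

    def test_rounding_rules(self):
        segs = [
            make_segment("chr1", 0, 10, 2, 0.0, copy=1.02),
            make_segment("chr1", 10, 20, 2, 0.0, copy=2.5),
            make_segment("chr1", 20, 30, 2, 0.0, copy=-0.1),
        ]
        with pytest.warns(UserWarning, match="negative"):
            segs = round_copy(segs)
        assert [s.copy_integer for s in segs] == [1, 3, 0]

    def test_rounding_requires_copy_number(self):
        with pytest.raises(ValueError):
            round_copy([make_segment("chr1", 0, 10, 2, 0.0)])


class TestCallCnvs:
    def test_flat_profile_yields_no_calls(self):
        segs = [make_segment("chr1", 0, 40_000_000, 80, 0.001 * i) for i in range(6)]
        assert call_cnvs(segs) == []

    def test_three_bin_deletion_filtered(self):
        segs = [
            make_segment("chr1", 0, 40_000_000, 80, 0.0),
            make_segment("chr2", 0, 10_000_000, 20, 0.01),
            make_segment("chr2", 10_000_000, 11_500_000, 3, -1.0),  # 1.5 Mb, 3 bins
            make_segment("chr2", 11_500_000, 40_000_000, 57, -0.01),
        ]
        calls = call_cnvs(segs)
        assert all(c.segment.n_bins != 3 for c in calls)
        assert calls == []

    def test_large_deviant_segment_called_with_direction(self):
        segs = [make_segment(f"chr{i}", 0, 40_000_000, 80, 0.01 * i) for i in range(5)]
        segs.append(make_segment("chr6", 0, 20_500_000, 41, -1.0))
        calls = call_cnvs(segs)
        assert len(calls) == 1
        assert calls[0].direction == "loss"
        assert calls[0].segment.n_bins == 41

    def test_mad_undefined_with_one_segment(self):
        with pytest.warns(UserWarning, match="MAD"):
            assert call_cnvs([make_segment("chr1", 0, 10_000_000, 20, -1.0)]) == []

    def test_baseline_mode_uses_fixed_center(self):
        segs = [
            make_segment("chr1", 0, 40_000_000, 80, -0.5),
            make_segment("chr2", 0, 40_000_000, 80, -0.5),
            make_segment("chr3", 0, 40_000_000, 80, -0.5),
        ]
        assert call_cnvs(segs) == []  # MAD mode: all deviations zero
        calls = call_cnvs(segs, mode="baseline", baseline_mean=0.0)
        assert len(calls) == 3  # vs a fixed diploid baseline all are losses


class TestEndToEndRecovery:
    def test_implanted_events_recovered(self, default_genome):
        # one X monosomy plus a 20.5 Mb deletion; a 1.5 Mb implant must not call
        truth = CNVSpec(
            events=[("chr3", 10_000_000, 30_500_000, 1), ("chr4", 5_000_000, 6_500_000, 1)]
        )
        s = simulate_sample(default_genome, "wga4", cnv=truth, seed=77)
        bs = s.counts.bin_set
        corrected = lowess_correct(s.counts.counts, bs.gc)
        segs = segment_sample(log2_cnr_signal(corrected, bs), bs, SegmentationParams(seed=77))
        segs = round_copy(segment_copy_number(segs, corrected, bs))
        calls = call_cnvs(segs)
        losses = [(c.segment.chrom, c.segment.start_bp, c.segment.end_bp) for c in calls]
        assert ("chr3", 10_000_000, 30_500_000) in losses
        assert any(c == "chrX" for c, *_ in losses)
        assert not any(c == "chr4" for c, *_ in losses)
        chr3_call = next(c for c in calls if c.segment.chrom == "chr3")
        assert chr3_call.segment.copy_integer == 1
        assert chr3_call.direction == "loss"
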