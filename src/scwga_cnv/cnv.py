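"""Circular binary segmentation (CBS) and CNV calling from binned counts.

Segmentation treats each current segment as a circle and searches all arc
boundary pairs (i, j) for the arc whose mean differs most from its complement
(two-sample pooled-variance t statistic).  The best split is accepted when
its permutation p-value — the fraction of within-segment permutations whose
best statistic is at least as large — falls below ``alpha``; the procedure
recurses on the resulting pieces and finishes with an "sd-undo" pass that
merges adjacent segments whose means differ by less than ``undo_sd`` noise
standard deviations.  Significance is assessed by full permutation (no
hybrid tail approximation), with the RNG seeded per segment so results are
reproducible and independent of recursion order.

Copy number of a segment is twice its mean count over the autosomal mean
count; a CNV is called for segments that (1) span at least 4 bins, (2) exceed
2 Mb, and (3) deviate from the per-sample median segment mean by more than 2
robust MADs.
"""

from __future__ import annotations

import dataclasses
import warnings
import zlib

import numpy as np
import pandas as pd

from .binning import BinnedCounts, BinSet

MAD_SCALE = 1.4826  # consistency constant for a normal distribution (R's mad)


@dataclasses.dataclass
class SegmentationParams:
    alpha: float = 0.02
    nperm: int = 1000
    min_width: int = 5
    undo_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.nperm < 100:
            raise ValueError("nperm must be >= 100")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")
        if self.undo_sd < 0:
            raise ValueError("undo_sd must be >= 0")


@dataclasses.dataclass
class Segment:
    chrom: str
    start_bin: int  # global bin index, inclusive
    end_bin: int  # global bin index, exclusive
    start_bp: int
    end_bp: int
    n_bins: int
    mean: float  # mean of the segmented signal (log2 CNR)
    copy_number: float | None = None
    copy_integer: int | None = None
    flag: str = ""

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclasses.dataclass
class CNVCall:
    segment: Segment
    direction: str  # "gain" | "loss"
    size_bp: int
    deviation: float
    mad: float
    flags: dict[str, bool]


# ---------------------------------------------------------------------------
# split search


def candidate_pairs(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    """All circular-arc boundary pairs (i, j), arc = [i, j), such that every
    nonempty piece of the resulting partition has at least ``min_width`` bins.

    A prefix arc [0, j) partitions identically to the complement arc [j, n),
    so only the latter is enumerated; every candidate is a unique partition.
    """
    pairs_i, pairs_j = [], []
    for i in range(min_width, n - min_width + 1):
        for j in range(i + min_width, n + 1):
            if j != n and n - j < min_width:
                continue
            pairs_i.append(i)
            pairs_j.append(j)
    return np.asarray(pairs_i, dtype=np.intp), np.asarray(pairs_j, dtype=np.intp)


def _pair_t2(x_rows: np.ndarray, pi: np.ndarray, pj: np.ndarray) -> np.ndarray:
    """Squared pooled-variance t statistic for each (arc, complement) pair.

    ``x_rows`` is (batch, n); returns (batch, n_pairs).
    """
    b, n = x_rows.shape
    cs = np.concatenate([np.zeros((b, 1)), np.cumsum(x_rows, axis=1)], axis=1)
    total = cs[:, -1:]
    ss_tot = np.sum(x_rows**2, axis=1, keepdims=True) - total**2 / n
    k = (pj - pi).astype(np.float64)
    sum_in = cs[:, pj] - cs[:, pi]
    d = sum_in / k - (total - sum_in) / (n - k)
    between = d**2 * (k * (n - k) / n)
    s2 = np.maximum(ss_tot - between, 0.0) / max(n - 2, 1)
    s2 = np.maximum(s2, 1e-300)
    return between / s2


def best_split(x: np.ndarray, min_width: int) -> tuple[int, int, float] | None:
    """Arc (i, j) maximizing the t^2 statistic; ties break to the first pair
    in (i, j) lexicographic order.  None when no candidate pair exists."""
    n = x.shape[0]
    pi, pj = candidate_pairs(n, min_width)
    if pi.size == 0:
        return None
    t2 = _pair_t2(x[None, :], pi, pj)[0]
    a = int(np.argmax(t2))
    return int(pi[a]), int(pj[a]), float(t2[a])


def _permutation_pvalue_accepts(
    x: np.ndarray,
    obs_t2: float,
    pi: np.ndarray,
    pj: np.ndarray,
    params: SegmentationParams,
    rng: np.random.Generator,
) -> bool:
    """True when the permutation p-value of the observed best statistic is
    below alpha.  Permutations run in chunks with early rejection once the
    exceedance count can no longer come in under alpha."""
    nperm = params.nperm
    # accept iff (1 + exceed) / (1 + nperm) < alpha
    max_exceed = int(np.ceil(params.alpha * (1 + nperm))) - 2
    if max_exceed < 0:
        return False
    exceed = 0
    done = 0
    chunk = 250
    while done < nperm:
        b = min(chunk, nperm - done)
        perms = rng.permuted(np.broadcast_to(x, (b, x.shape[0])), axis=1)
        t2 = _pair_t2(perms, pi, pj)
        exceed += int(np.sum(t2.max(axis=1) >= obs_t2 - 1e-12))
        if exceed > max_exceed:
            return False
        done += b
    return True


def _segment_one_chrom(
    x: np.ndarray, params: SegmentationParams, chrom_key: int
) -> list[int]:
    """Recursive CBS on one chromosome's signal; returns sorted interior
    changepoints (bin indices within the chromosome)."""
    n = x.shape[0]
    boundaries: set[int] = set()
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        seg = x[lo:hi]
        m = hi - lo
        if m < 2 * params.min_width:
            continue
        pi, pj = candidate_pairs(m, params.min_width)
        found = best_split(seg, params.min_width)
        if found is None:
            continue
        i, j, t2 = found
        rng = np.random.default_rng([params.seed & 0x7FFFFFFF, chrom_key, lo, hi])
        if not _permutation_pvalue_accepts(seg, t2, pi, pj, params, rng):
            continue
        cuts = [c for c in (i, j) if 0 < c < m]
        pieces = sorted({0, *cuts, m})
        for c in cuts:
            boundaries.add(lo + c)
        for a, b in zip(pieces, pieces[1:]):
            stack.append((lo + a, lo + b))
    return sorted(boundaries)


def _sd_undo(x: np.ndarray, cuts: list[int], undo_sd: float) -> list[int]:
    """Merge adjacent segments whose mean difference is below ``undo_sd``
    noise sds; the noise sd is the robust MAD of successive differences / sqrt(2)."""
    if not cuts or undo_sd <= 0:
        return cuts
    diffs = np.abs(np.diff(x))
    if diffs.size == 0:
        return cuts
    noise_sd = MAD_SCALE * float(np.median(diffs)) / np.sqrt(2.0)
    if noise_sd <= 0:
        return cuts
    bounds = [0, *cuts, x.shape[0]]
    while len(bounds) > 2:
        means = [x[a:b].mean() for a, b in zip(bounds, bounds[1:])]
        gaps = np.abs(np.diff(means))
        k = int(np.argmin(gaps))
        if gaps[k] < undo_sd * noise_sd:
            del bounds[k + 1]
        else:
            break
    return bounds[1:-1]


def _refine_boundaries(x: np.ndarray, cuts: list[int], max_shift: int = 3) -> list[int]:
    """Reassign boundary bins to the adjacent segment whose mean they are
    closer to (at most ``max_shift`` bins per boundary).

    The minimum segment width blurs events shorter than ``min_width`` bins
    into diluted segments that absorb flanking bins; this pass restores sharp
    boundaries so size-based call filters see the true event extent.
    """
    if not cuts:
        return cuts
    bounds = [0, *cuts, x.shape[0]]

    def core_mean(a: int, b: int, drop_head: bool) -> float:
        # mean of a segment excluding its boundary-adjacent bins, so a
        # diluted edge cannot bias its own reassignment test
        k = min(max_shift, b - a - 1)
        return x[a + k : b].mean() if drop_head else x[a : b - k].mean()

    for i in range(1, len(bounds) - 1):
        shift = 0
        while shift < max_shift and bounds[i] - 1 > bounds[i - 1]:
            ma = core_mean(bounds[i - 1], bounds[i], drop_head=False)
            mb = core_mean(bounds[i], bounds[i + 1], drop_head=True)
            v = x[bounds[i] - 1]
            if abs(v - mb) < abs(v - ma):
                bounds[i] -= 1
                shift += 1
            else:
                break
        if shift == 0:
            while shift < max_shift and bounds[i] < bounds[i + 1] - 1:
                ma = core_mean(bounds[i - 1], bounds[i], drop_head=False)
                mb = core_mean(bounds[i], bounds[i + 1], drop_head=True)
                v = x[bounds[i]]
                if abs(v - ma) < abs(v - mb):
                    bounds[i] += 1
                    shift += 1
                else:
                    break
    return bounds[1:-1]


def cbs_segment(
    values: np.ndarray, params: SegmentationParams, chrom: str = "chr"
) -> list[tuple[int, int, float, str]]:
    """Segment one chromosome's per-bin signal.

    Returns (start_bin, end_bin, mean, flag) tuples partitioning the input.
    Chromosomes shorter than ``min_width`` come back as a single flagged
    segment.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1 or x.shape[0] == 0:
        raise ValueError("values must be a non-empty 1-d array")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n = x.shape[0]
    if n < params.min_width:
        return [(0, n, float(x.mean()), "short_chromosome")]
    chrom_key = zlib.crc32(chrom.encode()) & 0x7FFFFFFF
    cuts = _segment_one_chrom(x, params, chrom_key)
    cuts = _sd_undo(x, cuts, params.undo_sd)
    cuts = _refine_boundaries(x, cuts)
    bounds = [0, *cuts, n]
    return [(a, b, float(x[a:b].mean()), "") for a, b in zip(bounds, bounds[1:])]


def segment_sample(
    values: np.ndarray, bin_set: BinSet, params: SegmentationParams
) -> list[Segment]:
    """Run CBS chromosome by chromosome over a genome-wide signal vector."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape[0] != len(bin_set):
        raise ValueError("signal length != number of bins")
    segments: list[Segment] = []
    for chrom in bin_set.chrom_order:
        sl = bin_set.chrom_slice(chrom)
        if sl.stop == sl.start:
            continue
        for a, b, mean, flag in cbs_segment(values[sl], params, chrom=chrom):
            segments.append(
                Segment(
                    chrom=chrom,
                    start_bin=sl.start + a,
                    end_bin=sl.start + b,
                    start_bp=int(bin_set.start[sl.start + a]),
                    end_bp=int(bin_set.end[sl.start + b - 1]),
                    n_bins=b - a,
                    mean=mean,
                    flag=flag,
                )
            )
    return segments


# ---------------------------------------------------------------------------
# copy number and calling


def log2_cnr_signal(counts: np.ndarray, bin_set: BinSet, pseudocount: float = 0.5) -> np.ndarray:
    """log2 copy-number-ratio signal for segmentation.

    Counts (GC-corrected) are offset by a pseudocount so empty bins stay
    finite, then divided by the autosomal mean and log2-transformed.
    """
    counts = np.asarray(counts, dtype=np.float64)
    baseline = counts[bin_set.autosomal].mean()
    if baseline <= 0:
        raise ValueError("zero autosomal mean")
    return np.log2((counts + pseudocount) / baseline)


def segment_copy_number(
    segments: list[Segment], counts: np.ndarray, bin_set: BinSet
) -> list[Segment]:
    """Copy number = 2 x (segment mean count) / (autosomal mean count)."""
    counts = np.asarray(counts, dtype=np.float64)
    baseline = counts[bin_set.autosomal].mean()
    if baseline <= 0:
        raise ValueError("zero autosomal mean count")
    for seg in segments:
        seg.copy_number = 2.0 * counts[seg.start_bin : seg.end_bin].mean() / baseline
    return segments


def round_copy(segments: list[Segment]) -> list[Segment]:
    """Round copy number to the nearest integer, half away from zero, floored at 0."""
    for seg in segments:
        if seg.copy_number is None:
            raise ValueError("copy_number not set; run segment_copy_number first")
        if seg.copy_number < 0:
            warnings.warn("negative copy number floored at 0")
            seg.copy_integer = 0
        else:
            seg.copy_integer = int(np.floor(seg.copy_number + 0.5))
    return segments


def call_cnvs(
    segments: list[Segment],
    min_bins: int = 4,
    min_size_bp: int = 2_000_000,
    mad_mult: float = 2.0,
    mode: str = "mad",
    baseline_mean: float = 0.0,
    baseline_copy: int | None = 2,
) -> list[CNVCall]:
    """Filter segments into CNV calls.

    A call requires: at least ``min_bins`` bins; more than ``min_size_bp`` in
    size; a segment-mean deviation larger than ``mad_mult`` robust MADs of
    this sample's segment means (``mode="mad"``, deviation from the median)
    or from a fixed baseline mean (``mode="baseline"``); and — when segments
    carry integer copy numbers and ``baseline_copy`` is set — a rounded copy
    number different from the baseline ploidy.  The last guard matters on
    small genomes, where the per-sample MAD of segment means can collapse
    and the deviation criterion alone would admit wobbles whose own copy
    estimate still reads diploid.  Direction follows the sign of the
    deviation.
    """
    if mode not in ("mad", "baseline"):
        raise ValueError("mode must be 'mad' or 'baseline'")
    if len(segments) < 2 and mode == "mad":
        warnings.warn("fewer than 2 segments; MAD undefined, no CNV calls")
        return []
    means = np.array([s.mean for s in segments])
    center = float(np.median(means)) if mode == "mad" else baseline_mean
    mad = MAD_SCALE * float(np.median(np.abs(means - np.median(means))))
    calls: list[CNVCall] = []
    for seg in segments:
        dev = seg.mean - center
        flags = {
            "min_bins": seg.n_bins >= min_bins,
            "min_size": seg.size_bp > min_size_bp,
            "deviation": abs(dev) > mad_mult * mad,
        }
        if baseline_copy is not None and seg.copy_integer is not None:
            flags["copy_change"] = seg.copy_integer != baseline_copy
        if all(flags.values()):
            calls.append(
                CNVCall(
                    segment=seg,
                    direction="gain" if dev > 0 else "loss",
                    size_bp=seg.size_bp,
                    deviation=float(dev),
                    mad=mad,
                    flags=flags,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# I/O


def segments_to_frame(sample_id: str, segments: list[Segment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": sample_id,
            "chrom": [s.chrom for s in segments],
            "start": [s.start_bp for s in segments],
            "end": [s.end_bp for s in segments],
            "n_bins": [s.n_bins for s in segments],
            "seg_mean": [round(s.mean, 6) for s in segments],
            "copy": [None if s.copy_number is None else round(s.copy_number, 4) for s in segments],
            "copy_integer": [s.copy_integer for s in segments],
            "flag": [s.flag for s in segments],
        }
    )


def calls_to_bed(calls: list[CNVCall]) -> pd.DataFrame:
    """BED6+: chrom, start, end, name=gain/loss, score=|deviation|/MAD, strand."""
    return pd.DataFrame(
        {
            "chrom": [c.segment.chrom for c in calls],
            "start": [c.segment.start_bp for c in calls],
            "end": [c.segment.end_bp for c in calls],
            "name": [c.direction for c in calls],
            "score": [
                round(abs(c.deviation) / c.mad, 3) if c.mad > 0 else np.inf for c in calls
            ],
            "strand": ".",
        }
    )
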