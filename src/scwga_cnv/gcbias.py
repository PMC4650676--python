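"""GC-composition profiles, relative-coverage curves and LOWESS GC correction.

Read (or window) GC content is histogrammed in 1 %-wide GC classes with
totals normalized to the 10-million-read convention.  Relative coverage in a
GC class is the sample frequency divided by the reference-genome frequency:
1 means the class is covered at the expected average rate, above/below 1 means
over-/under-representation (the amplification GC bias).

The GC trend in per-bin counts is removed with locally weighted linear
regression (LOWESS) of log2 counts on bin GC: each count is rescaled by the
ratio of the overall mean to the fitted trend at its GC.  Fitting in log space
makes multiplicative bias additive, so an exponential GC bias is removed
essentially exactly, and the ratio form preserves real copy-number signal —
replacing counts by the regression values outright would erase CNVs (that
literal mode is available behind a flag for comparison).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .genome import GenomeModel

NORMALIZED_TOTAL = 10_000_000.0
N_CLASSES = 100  # 1% GC classes covering [0, 1]


@dataclasses.dataclass
class GCHistogram:
    """Read/window frequency per 1% GC class, normalized to 10 million."""

    freq: np.ndarray  # length 100, class k covers [k, k+1)% GC
    label: str = ""

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=np.float64)
        if self.freq.shape != (N_CLASSES,):
            raise ValueError(f"expected {N_CLASSES} GC classes")
        if np.any(self.freq < 0):
            raise ValueError("negative frequencies")

    @property
    def centers(self) -> np.ndarray:
        """Class centers as GC fractions."""
        return (np.arange(N_CLASSES) + 0.5) / N_CLASSES

    def mean_gc(self) -> float:
        total = self.freq.sum()
        if total <= 0:
            raise ValueError("empty histogram")
        return float(np.sum(self.freq * self.centers) / total)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"gc_percent": np.arange(N_CLASSES), "frequency": self.freq}
        ).to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class RelativeCoverageCurve:
    """Per-GC-class sample/reference frequency ratio with a validity mask."""

    ratio: np.ndarray
    valid: np.ndarray
    label: str = ""

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "gc_percent": np.arange(N_CLASSES),
                "relative_coverage": np.where(self.valid, self.ratio, np.nan),
            }
        ).to_csv(path, sep="\t", index=False)


def _gc_histogram(gc: np.ndarray, weights: np.ndarray, label: str) -> GCHistogram:
    gc = np.asarray(gc, dtype=np.float64)
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError("GC fractions outside [0, 1]")
    hist, _ = np.histogram(gc, bins=N_CLASSES, range=(0.0, 1.0), weights=weights)
    total = hist.sum()
    if total <= 0:
        raise ValueError("empty GC histogram")
    return GCHistogram(hist * (NORMALIZED_TOTAL / total), label=label)


def reference_gc_histogram(genome: GenomeModel) -> GCHistogram:
    """Histogram of window GC over the whole genome, length-weighted."""
    gc, w = [], []
    for chrom in genome.chrom_names:
        starts, ends = genome.window_bounds(chrom)
        gc.append(genome.gc[chrom])
        w.append((ends - starts).astype(np.float64))
    return _gc_histogram(np.concatenate(gc), np.concatenate(w), "reference")


def sample_gc_histogram(
    read_gc: np.ndarray | None = None,
    bin_counts: np.ndarray | None = None,
    bin_gc: np.ndarray | None = None,
    label: str = "sample",
) -> GCHistogram:
    """Sample GC composition from per-read GC or from per-bin counts + bin GC."""
    if read_gc is not None:
        return _gc_histogram(np.asarray(read_gc), None, label)
    if bin_counts is None or bin_gc is None:
        raise ValueError("provide read_gc, or bin_counts together with bin_gc")
    return _gc_histogram(
        np.asarray(bin_gc), np.asarray(bin_counts, dtype=np.float64), label
    )


def relative_coverage(
    sample: GCHistogram,
    reference: GCHistogram,
    floor_fraction: float = 1e-4,
) -> RelativeCoverageCurve:
    """Classwise sample/reference frequency ratio.

    Classes holding less than ``floor_fraction`` of the reference mass are
    masked: with almost no reference sequence at that GC the ratio is
    dominated by sampling noise.
    """
    floor = floor_fraction * reference.freq.sum()
    valid = reference.freq > floor
    ratio = np.zeros(N_CLASSES)
    ratio[valid] = sample.freq[valid] / reference.freq[valid]
    return RelativeCoverageCurve(ratio=ratio, valid=valid, label=sample.label)


def gc_residual_correlation(counts: np.ndarray, gc: np.ndarray) -> float:
    """Pearson correlation between (corrected) counts and GC.

    When the counts are constant to within numerical precision (relative
    spread below 1e-9) there is no detectable GC dependence and the
    correlation coefficient is undefined; 0 is returned.
    """
    counts = np.asarray(counts, dtype=np.float64)
    mean = counts.mean()
    if mean == 0 or counts.std() / abs(mean) < 1e-9:
        return 0.0
    return float(np.corrcoef(counts, gc)[0, 1])


def lowess_correct(
    counts: np.ndarray,
    gc: np.ndarray,
    span: float = 0.3,
    iterations: int = 1,
    mode: str = "ratio",
    floor_quantile: float = 0.01,
    trim_sd: float = 2.0,
) -> np.ndarray:
    """Remove the GC trend from per-bin counts by LOWESS.

    Fits ``log2(count)`` over positive-count bins against bin GC with
    robustified locally weighted linear regression (``span`` = fraction of
    bins per local fit), interpolates the trend to every bin, and rescales
    each count by mean(count) / trend(gc); zero-count bins stay zero.  The
    fitted trend is floored at its ``floor_quantile`` quantile so near-empty
    GC extremes cannot blow counts up; the corrected vector is renormalized
    to preserve the mean count.  ``mode="replace"`` instead returns the
    back-transformed regression values themselves (the literal smoothing,
    which flattens real copy-number signal; for comparison only).

    Bins carrying real copy-number changes would otherwise contaminate the
    trend in their own GC range (soft bisquare reweighting never rejects a
    coherent half-copy cluster), so the fit is re-estimated after masking
    bins whose log residual exceeds ``trim_sd`` robust standard deviations
    (set ``trim_sd=0`` to disable).
    """
    counts = np.asarray(counts, dtype=np.float64)
    gc = np.asarray(gc, dtype=np.float64)
    if counts.shape != gc.shape:
        raise ValueError("counts and gc must have the same shape")
    if counts.shape[0] < 20:
        raise ValueError("need at least 20 bins for a LOWESS fit")
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError("GC fractions outside [0, 1]")
    if np.any(counts < 0):
        raise ValueError("negative counts")
    if mode not in ("ratio", "replace"):
        raise ValueError("mode must be 'ratio' or 'replace'")
    if np.ptp(gc) == 0.0:
        warnings.warn("degenerate GC (all bins equal); returning counts unchanged")
        return counts.copy()

    pos = counts > 0
    if pos.sum() < 20:
        raise ValueError("need at least 20 bins with positive counts")

    def fit_trend(mask: np.ndarray) -> np.ndarray:
        fit = _sm_lowess(
            np.log2(counts[mask]), gc[mask], frac=span, it=iterations, return_sorted=True
        )
        return np.interp(gc, fit[:, 0], fit[:, 1])

    log_trend = fit_trend(pos)
    if trim_sd > 0:
        for _ in range(3):
            resid = np.where(pos, np.log2(np.where(pos, counts, 1.0)) - log_trend, 0.0)
            sd = 1.4826 * np.median(np.abs(resid[pos] - np.median(resid[pos])))
            if sd <= 1e-6:
                break
            keep = pos & (np.abs(resid) <= trim_sd * sd)
            if keep.sum() < 20 or keep.sum() == pos.sum():
                break
            log_trend = fit_trend(keep)
    trend = np.power(2.0, log_trend)
    if mode == "replace":
        return trend
    # guard against trend collapse at sparse GC extremes without touching
    # bins whose trend is merely in the low tail
    trend = np.maximum(trend, 0.5 * np.quantile(trend, floor_quantile))
    corrected = counts * (counts.mean() / trend)
    corrected *= counts.mean() / corrected.mean()
    return corrected
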