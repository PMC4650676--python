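"""Genomic bins and per-bin read counting.

Supports fixed-size bins (the 500 kb reproducibility grid) and variable-length
bins with uniform expected read counts (the copy-number grid).  Bins never
span a chromosome boundary; coordinates are 0-based half-open and a read is
assigned to the unique bin containing its start coordinate.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import GenomeModel


@dataclasses.dataclass
class BinSet:
    """Ordered, non-overlapping genomic bins with per-bin GC.

    ``chrom`` / ``start`` / ``end`` are parallel arrays sorted by (chromosome
    order, start).  ``autosomal`` marks bins on autosomes; ``kind`` is
    ``"fixed"`` or ``"variable"`` and ``nominal_size`` is the bin size in bp
    (fixed) or the target expected reads per bin (variable).
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    gc: np.ndarray
    autosomal: np.ndarray
    kind: str
    nominal_size: float
    chrom_order: list[str]

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.gc = np.asarray(self.gc, dtype=np.float64)
        self.autosomal = np.asarray(self.autosomal, dtype=bool)
        if np.any(self.start >= self.end):
            raise ValueError("bin start must be < end")
        for c in self.chrom_order:
            sel = self.chrom == c
            if np.any(self.start[sel][1:] < self.end[sel][:-1]):
                raise ValueError(f"overlapping bins on {c}")

    def __len__(self) -> int:
        return self.start.shape[0]

    @property
    def sizes(self) -> np.ndarray:
        return self.end - self.start

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def to_bed(self, path: str | Path) -> None:
        """BED4: chrom, start, end, gc."""
        pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "gc": np.round(self.gc, 6),
            }
        ).to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def from_bed(
        cls,
        path: str | Path,
        sex_chromosomes: tuple[str, ...] = ("chrX",),
        kind: str = "fixed",
    ) -> "BinSet":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "gc"])
        chrom_order = list(dict.fromkeys(df["chrom"]))
        sizes = (df["end"] - df["start"]).to_numpy()
        return cls(
            chrom=df["chrom"].to_numpy(dtype=object),
            start=df["start"].to_numpy(),
            end=df["end"].to_numpy(),
            gc=df["gc"].to_numpy(),
            autosomal=~df["chrom"].isin(sex_chromosomes).to_numpy(),
            kind=kind,
            nominal_size=float(np.median(sizes)),
            chrom_order=chrom_order,
        )


@dataclasses.dataclass
class BinnedCounts:
    """Per-bin read counts for one sample on a given :class:`BinSet`."""

    sample_id: str
    bin_set: BinSet
    counts: np.ndarray
    total_reads: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape[0] != len(self.bin_set):
            raise ValueError("counts length != number of bins")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "chrom": self.bin_set.chrom,
                "start": self.bin_set.start,
                "end": self.bin_set.end,
                self.sample_id: self.counts,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class RatioVector:
    """Per-bin count ratios relative to the mean count over a baseline scope.

    ``values[i] = counts[i] / mean(counts over scope bins)``; the mean of
    ``values`` over the scope is 1 by construction.  The scope is all bins or
    autosomal bins only (the latter is the copy-number-ratio convention, so an
    intact male X sits near 0.5).
    """

    sample_id: str
    values: np.ndarray
    scope_mask: np.ndarray
    scope: str

    @property
    def scope_values(self) -> np.ndarray:
        return self.values[self.scope_mask]


@dataclasses.dataclass
class QuartileSummary:
    sample_id: str
    q1: float
    median: float
    q3: float
    log10: bool

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


# ---------------------------------------------------------------------------
# bin construction


def make_fixed_bins(
    genome: GenomeModel, bin_size: int, drop_short_last: bool = False
) -> BinSet:
    """Tile every chromosome with fixed-size bins.

    The terminal remainder bin is kept by default (its true, shorter size is
    recorded); ``drop_short_last`` removes it.  Per-bin GC is the
    length-weighted mean of the genome's GC windows over the bin.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if bin_size < genome.window_size:
        raise ValueError("bin_size must be >= the GC-track window size")
    chroms, starts, ends, gcs, auto = [], [], [], [], []
    for chrom in genome.chrom_names:
        length = genome.length(chrom)
        s = np.arange(0, length, bin_size, dtype=np.int64)
        e = np.minimum(s + bin_size, length)
        if drop_short_last and e[-1] - s[-1] < bin_size:
            s, e = s[:-1], e[:-1]
        if s.size == 0:
            continue
        chroms.append(np.full(s.size, chrom, dtype=object))
        starts.append(s)
        ends.append(e)
        gcs.append(genome.interval_gc(chrom, s, e))
        auto.append(np.full(s.size, genome.is_autosome(chrom)))
    return BinSet(
        chrom=np.concatenate(chroms),
        start=np.concatenate(starts),
        end=np.concatenate(ends),
        gc=np.concatenate(gcs),
        autosomal=np.concatenate(auto),
        kind="fixed",
        nominal_size=float(bin_size),
        chrom_order=list(genome.chrom_names),
    )


def make_variable_bins(
    genome: GenomeModel,
    expected_track: Mapping[str, np.ndarray],
    target_reads_per_bin: float,
) -> BinSet:
    """Variable-length bins with uniform expected read counts.

    ``expected_track`` gives a non-negative expected read density per GC-track
    window.  Bins are grown greedily left-to-right on each chromosome and
    closed at the first window boundary where the accumulated expectation
    reaches the target; the chromosome-final partial bin is merged into its
    predecessor (or, if the whole chromosome falls short of one target, the
    chromosome becomes a single bin).  Chromosomes with zero total expectation
    are skipped with a warning.
    """
    if target_reads_per_bin <= 0:
        raise ValueError("target_reads_per_bin must be positive")
    chroms, starts, ends, gcs, auto = [], [], [], [], []
    for chrom in genome.chrom_names:
        e_track = np.asarray(expected_track[chrom], dtype=np.float64)
        if e_track.shape[0] != genome.n_windows(chrom):
            raise ValueError(f"{chrom}: expected_track has wrong window count")
        if np.any(e_track < 0):
            raise ValueError(f"{chrom}: negative expectations")
        total = e_track.sum()
        if total <= 0:
            warnings.warn(f"{chrom}: zero total expectation, skipped")
            continue
        _, win_end = genome.window_bounds(chrom)
        cs = np.cumsum(e_track)
        boundaries = []  # window indices (inclusive) closing each bin
        tgt = target_reads_per_bin
        while tgt <= cs[-1]:
            idx = int(np.searchsorted(cs, tgt - 1e-12))
            boundaries.append(idx)
            tgt = cs[idx] + target_reads_per_bin
        if not boundaries:
            boundaries = [len(cs) - 1]
        elif boundaries[-1] < len(cs) - 1:
            # merge the trailing partial bin into its predecessor
            boundaries[-1] = len(cs) - 1
        b_end = win_end[np.array(boundaries)]
        b_start = np.concatenate([[0], b_end[:-1]])
        chroms.append(np.full(b_end.size, chrom, dtype=object))
        starts.append(b_start)
        ends.append(b_end)
        gcs.append(genome.interval_gc(chrom, b_start, b_end))
        auto.append(np.full(b_end.size, genome.is_autosome(chrom)))
    if not chroms:
        raise ValueError("no chromosome produced bins")
    return BinSet(
        chrom=np.concatenate(chroms),
        start=np.concatenate(starts),
        end=np.concatenate(ends),
        gc=np.concatenate(gcs),
        autosomal=np.concatenate(auto),
        kind="variable",
        nominal_size=float(target_reads_per_bin),
        chrom_order=list(genome.chrom_names),
    )


# ---------------------------------------------------------------------------
# counting and normalization


def count_reads(
    read_positions: Mapping[str, np.ndarray],
    bin_set: BinSet,
    sample_id: str = "sample",
    unknown_chrom: str = "warn",
) -> BinnedCounts:
    """Count reads per bin by start coordinate (0-based, half-open).

    ``read_positions`` maps chromosome -> array of read start coordinates.
    Reads on unknown chromosomes are skipped with a warning (or rejected when
    ``unknown_chrom="error"``); reads falling outside every bin contribute to
    ``total_reads`` only.
    """
    counts = np.zeros(len(bin_set), dtype=np.int64)
    total = 0
    for chrom, pos in read_positions.items():
        pos = np.asarray(pos, dtype=np.int64)
        total += pos.size
        if chrom not in bin_set.chrom_order:
            if unknown_chrom == "error":
                raise ValueError(f"unknown chromosome in reads: {chrom}")
            warnings.warn(f"skipping {pos.size} reads on unknown chromosome {chrom}")
            continue
        sl = bin_set.chrom_slice(chrom)
        if sl.stop == sl.start:
            continue
        starts = bin_set.start[sl]
        ends = bin_set.end[sl]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        np.add.at(counts, sl.start + idx[ok], 1)
    return BinnedCounts(sample_id=sample_id, bin_set=bin_set, counts=counts, total_reads=total)


def normalize_counts(counts: BinnedCounts, target_total: float = 10_000_000) -> np.ndarray:
    """Scale per-bin counts so the in-bin total equals ``target_total``.

    The 10-million-read convention puts samples of different depth on a common
    scale before GC profiling and ratio computation.
    """
    s = counts.counts.sum()
    if s <= 0:
        raise ValueError("cannot normalize a sample with zero in-bin reads")
    return counts.counts * (target_total / s)


def ratio_vector(counts: BinnedCounts, scope: str = "all") -> RatioVector:
    """Per-bin ratio of counts to the mean count over the chosen scope."""
    if scope not in ("all", "autosomes"):
        raise ValueError("scope must be 'all' or 'autosomes'")
    mask = (
        np.ones(len(counts.bin_set), dtype=bool)
        if scope == "all"
        else counts.bin_set.autosomal.copy()
    )
    if not mask.any():
        raise ValueError("no bins in scope")
    mean = counts.counts[mask].mean()
    if mean <= 0:
        raise ValueError("zero mean count over scope; ratios undefined")
    return RatioVector(
        sample_id=counts.sample_id,
        values=counts.counts / mean,
        scope_mask=mask,
        scope=scope,
    )


def uniformity_summary(ratio: RatioVector, log10: bool = False) -> QuartileSummary:
    """Quartiles (linear interpolation) of the per-bin ratios over the scope.

    With ``log10=True``, zero-ratio bins are excluded before taking logs.
    """
    vals = ratio.scope_values
    if vals.size == 0:
        raise ValueError("empty ratio vector")
    if log10:
        vals = vals[vals > 0]
        if vals.size == 0:
            raise ValueError("no positive ratios for log scale")
        vals = np.log10(vals)
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return QuartileSummary(ratio.sample_id, float(q1), float(med), float(q3), log10)


def aggregate_counts(counts: BinnedCounts, factor: int) -> BinnedCounts:
    """Sum consecutive fixed bins ``factor``-fold into coarser fixed bins.

    Exact summation within chromosomes; the trailing group on each chromosome
    may span fewer fine bins.  Requires a fixed-size bin set.
    """
    if counts.bin_set.kind != "fixed":
        raise ValueError("aggregation requires fixed-size bins")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    bs = counts.bin_set
    chroms, starts, ends, gcs, auto, newc = [], [], [], [], [], []
    for chrom in bs.chrom_order:
        sl = bs.chrom_slice(chrom)
        n = sl.stop - sl.start
        if n == 0:
            continue
        group = np.arange(n) // factor
        n_groups = int(group[-1]) + 1
        c = np.zeros(n_groups, dtype=counts.counts.dtype)
        np.add.at(c, group, counts.counts[sl])
        s = bs.start[sl][np.flatnonzero(np.diff(group, prepend=-1))]
        e = np.zeros(n_groups, dtype=np.int64)
        e[group] = bs.end[sl]  # last write per group wins
        chroms.append(np.full(n_groups, chrom, dtype=object))
        starts.append(s)
        ends.append(e)
        w = (bs.end[sl] - bs.start[sl]).astype(float)
        gsum = np.zeros(n_groups)
        wsum = np.zeros(n_groups)
        np.add.at(gsum, group, bs.gc[sl] * w)
        np.add.at(wsum, group, w)
        gcs.append(gsum / wsum)
        auto.append(np.full(n_groups, bs.autosomal[sl][0]))
        newc.append(c)
    coarse = BinSet(
        chrom=np.concatenate(chroms),
        start=np.concatenate(starts),
        end=np.concatenate(ends),
        gc=np.concatenate(gcs),
        autosomal=np.concatenate(auto),
        kind="fixed",
        nominal_size=bs.nominal_size * factor,
        chrom_order=bs.chrom_order,
    )
    return BinnedCounts(
        sample_id=counts.sample_id,
        bin_set=coarse,
        counts=np.concatenate(newc),
        total_reads=counts.total_reads,
    )


def read_counts_tsv(path: str | Path, bin_set: BinSet | None = None) -> BinnedCounts:
    """Read a per-bin counts TSV (chrom, start, end, <sample_id>)."""
    df = pd.read_csv(path, sep="\t")
    sample_id = df.columns[-1]
    if bin_set is None:
        chrom_order = list(dict.fromkeys(df["chrom"]))
        sizes = (df["end"] - df["start"]).to_numpy()
        bin_set = BinSet(
            chrom=df["chrom"].to_numpy(dtype=object),
            start=df["start"].to_numpy(),
            end=df["end"].to_numpy(),
            gc=np.full(len(df), np.nan),
            autosomal=~df["chrom"].isin(["chrX", "chrY"]).to_numpy(),
            kind="fixed",
            nominal_size=float(np.median(sizes)),
            chrom_order=chrom_order,
        )
    counts = df[sample_id].to_numpy()
    return BinnedCounts(
        sample_id=sample_id, bin_set=bin_set, counts=counts, total_reads=int(counts.sum())
    )


def read_bed_positions(path: str | Path) -> dict[str, np.ndarray]:
    """Read BED3 read positions; only chrom and start are used."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "start"])
    return {
        chrom: grp["start"].to_numpy(dtype=np.int64)
        for chrom, grp in df.groupby("chrom", sort=False)
    }
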