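"""Reference-genome model: chromosome sizes plus a windowed GC track.

The genome is represented as an ordered set of chromosomes, each tiled
left-to-right by fixed-size windows (the last window of a chromosome may be
short), with one GC fraction per window.  This is the coordinate universe for
binning, GC profiling and simulation.  Coordinates are 0-based, half-open
throughout (BED convention).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass
class GenomeModel:
    """Chromosome names/lengths and a per-window GC fraction track.

    Parameters
    ----------
    chrom_names :
        Ordered chromosome names.
    chrom_lengths :
        Lengths in bp, same order, all positive.
    window_size :
        Tiling window size in bp for the GC track.
    gc :
        Mapping chromosome name -> array of per-window GC fractions in [0, 1];
        the number of windows per chromosome is ``ceil(length / window_size)``.
    sex_chromosomes :
        Names treated as non-autosomal (e.g. the X).
    """

    chrom_names: list[str]
    chrom_lengths: np.ndarray
    window_size: int
    gc: dict[str, np.ndarray]
    sex_chromosomes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.chrom_lengths = np.asarray(self.chrom_lengths, dtype=np.int64)
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if np.any(self.chrom_lengths <= 0):
            raise ValueError("chromosome lengths must be positive")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        self.sex_chromosomes = frozenset(self.sex_chromosomes)
        unknown = self.sex_chromosomes - set(self.chrom_names)
        if unknown:
            raise ValueError(f"sex chromosomes not in genome: {sorted(unknown)}")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            track = np.asarray(self.gc[name], dtype=np.float64)
            self.gc[name] = track
            if track.shape[0] != self.n_windows(name):
                raise ValueError(
                    f"{name}: GC track has {track.shape[0]} windows, expected "
                    f"{self.n_windows(name)} for length {length}"
                )
            if np.any((track < 0.0) | (track > 1.0)):
                raise ValueError(f"{name}: GC fractions outside [0, 1]")

    # -- basic geometry -------------------------------------------------

    def length(self, chrom: str) -> int:
        return int(self.chrom_lengths[self.chrom_names.index(chrom)])

    def n_windows(self, chrom: str) -> int:
        return int(-(-self.length(chrom) // self.window_size))

    def window_bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Window (start, end) arrays; the last window may be short."""
        starts = np.arange(self.n_windows(chrom), dtype=np.int64) * self.window_size
        ends = np.minimum(starts + self.window_size, self.length(chrom))
        return starts, ends

    def is_autosome(self, chrom: str) -> bool:
        return chrom not in self.sex_chromosomes

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chrom_names if c not in self.sex_chromosomes]

    # -- GC queries ------------------------------------------------------

    def _gc_cumulative(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Breakpoints and cumulative GC-bp integral for interval averaging."""
        starts, ends = self.window_bounds(chrom)
        widths = (ends - starts).astype(np.float64)
        cum = np.concatenate([[0.0], np.cumsum(self.gc[chrom] * widths)])
        points = np.concatenate([[0.0], ends.astype(np.float64)])
        return points, cum

    def interval_gc(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Length-weighted mean GC of arbitrary intervals on one chromosome.

        Exact for any interval: the cumulative GC integral is piecewise linear
        in the coordinate, so interval means come from two interpolations.
        """
        points, cum = self._gc_cumulative(chrom)
        starts = np.asarray(starts, dtype=np.float64)
        ends = np.asarray(ends, dtype=np.float64)
        if np.any(starts >= ends):
            raise ValueError("interval start must be < end")
        if np.any(ends > self.length(chrom)):
            raise ValueError(f"interval beyond end of {chrom}")
        hi = np.interp(ends, points, cum)
        lo = np.interp(starts, points, cum)
        return (hi - lo) / (ends - starts)

    def mean_gc(self) -> float:
        """Genome-wide length-weighted mean window GC."""
        num = 0.0
        den = 0.0
        for chrom in self.chrom_names:
            starts, ends = self.window_bounds(chrom)
            widths = (ends - starts).astype(np.float64)
            num += float(np.sum(self.gc[chrom] * widths))
            den += float(np.sum(widths))
        return num / den

    # -- serialization ---------------------------------------------------

    def to_dir(self, path: str | Path) -> None:
        """Write chrom sizes TSV and GC track BEDGraph (0-based half-open)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"chrom": self.chrom_names, "length": self.chrom_lengths}
        ).to_csv(path / "chrom_sizes.tsv", sep="\t", index=False)
        rows = []
        for chrom in self.chrom_names:
            starts, ends = self.window_bounds(chrom)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": ends,
                        "gc": np.round(self.gc[chrom], 6),
                    }
                )
            )
        pd.concat(rows).to_csv(
            path / "gc_track.bedgraph", sep="\t", index=False, header=False
        )
        with open(path / "meta.tsv", "w") as fh:
            fh.write("window_size\t%d\n" % self.window_size)
            fh.write("sex_chromosomes\t%s\n" % ",".join(sorted(self.sex_chromosomes)))

    @classmethod
    def from_dir(cls, path: str | Path) -> "GenomeModel":
        path = Path(path)
        sizes = pd.read_csv(path / "chrom_sizes.tsv", sep="\t")
        meta = dict(
            line.rstrip("\n").split("\t", 1)
            for line in open(path / "meta.tsv")
            if line.strip()
        )
        window_size = int(meta["window_size"])
        sex = frozenset(s for s in meta.get("sex_chromosomes", "").split(",") if s)
        track = pd.read_csv(
            path / "gc_track.bedgraph",
            sep="\t",
            names=["chrom", "start", "end", "gc"],
        )
        gc = {
            chrom: grp.sort_values("start")["gc"].to_numpy(dtype=np.float64)
            for chrom, grp in track.groupby("chrom", sort=False)
        }
        return cls(
            chrom_names=list(sizes["chrom"]),
            chrom_lengths=sizes["length"].to_numpy(),
            window_size=window_size,
            gc=gc,
            sex_chromosomes=sex,
        )


def build_genome(
    n_chromosomes: int = 6,
    chrom_length: int | Sequence[int] = 40_000_000,
    window_size: int = 10_000,
    gc_mean: float = 0.42,
    gc_sd: float = 0.08,
    gc_corr_bp: float = 1_000_000.0,
    x_length: int | None = 30_000_000,
    seed: int = 0,
) -> GenomeModel:
    """Generate a synthetic genome with a spatially autocorrelated GC track.

    The GC landscape is smoothed Gaussian noise with correlation length
    ``gc_corr_bp`` (isochore-like, ~1 Mb by default), rescaled to the target
    mean and standard deviation and clipped to (0, 1).  The last chromosome is
    designated X; autosomes share ``chrom_length`` (or take per-chromosome
    lengths from a sequence) and the X takes ``x_length`` when given.

    Deterministic for a fixed seed.
    """
    if n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes (one autosome plus X)")
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if isinstance(chrom_length, (int, np.integer)):
        lengths = [int(chrom_length)] * n_chromosomes
        if x_length is not None:
            lengths[-1] = int(x_length)
    else:
        lengths = [int(v) for v in chrom_length]
        if len(lengths) != n_chromosomes:
            raise ValueError("chrom_length sequence length != n_chromosomes")
    if any(v <= 0 for v in lengths):
        raise ValueError("chromosome lengths must be positive")
    if not 0.0 < gc_mean < 1.0:
        raise ValueError("gc_mean must lie in (0, 1)")
    if gc_sd < 0 or gc_corr_bp <= 0:
        raise ValueError("gc_sd must be >= 0 and gc_corr_bp > 0")

    names = [f"chr{i + 1}" for i in range(n_chromosomes - 1)] + ["chrX"]
    rng = np.random.default_rng(seed)
    # Sample white noise on a coarse grid (5 points per correlation length),
    # smooth, rescale and interpolate down to window midpoints.
    grid_bp = gc_corr_bp / 5.0
    from scipy.ndimage import gaussian_filter1d

    raw = {}
    for name, length in zip(names, lengths):
        n_grid = max(int(np.ceil(length / grid_bp)) + 2, 8)
        field = gaussian_filter1d(rng.standard_normal(n_grid), sigma=5.0, mode="wrap")
        n_win = -(-length // window_size)
        mid = (np.arange(n_win) + 0.5) * window_size
        grid_x = (np.arange(n_grid) + 0.5) * grid_bp
        raw[name] = np.interp(mid, grid_x, field)
    # Global rescale so the genome-wide mean/sd hit their targets.
    allv = np.concatenate([raw[n] for n in names])
    scale = gc_sd / allv.std() if allv.std() > 0 else 0.0
    offset = gc_mean - allv.mean() * scale
    gc = {n: np.clip(raw[n] * scale + offset, 0.01, 0.99) for n in names}
    return GenomeModel(
        chrom_names=names,
        chrom_lengths=np.array(lengths, dtype=np.int64),
        window_size=int(window_size),
        gc=gc,
        sex_chromosomes=frozenset({"chrX"}),
    )
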