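"""Synthetic read-count generator for whole-genome-amplification methods.

Emulates the statistical signatures of shallow single-cell sequencing after
bulk (no amplification), GenomePlex/WGA4, MALBAC, or MDA amplification:

* a method-specific GC-bias curve (MALBAC prefers high-GC regions, WGA4 and
  MDA are near-flat);
* a *shared* multiplicative bias field, identical across all cells amplified
  with the same method — the reproducible, method-built-in bias that makes
  cells of one method correlate and cluster together;
* a *private* per-cell bias field plus gamma overdispersion — the cell-to-cell
  noise that drives MAPD (small for WGA4/MALBAC, extreme for MDA);
* optional bin dropout (near-zero amplification of a region).

Expected reads per bin are proportional to
``copy_number x gc_curve(GC) x exp(shared) x exp(private) x gamma`` and the
realized counts are a single multinomial draw, so the simulated total equals
the requested total exactly.  Bias fields are piecewise constant on
``noise_block_bp`` blocks (the scale at which amplification noise
decorrelates along the genome).
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .binning import BinnedCounts, BinSet, make_fixed_bins
from .genome import GenomeModel


@dataclasses.dataclass
class MethodProfile:
    """Amplification-method preset.

    ``gc_anchors`` are (GC fraction, relative amplification factor) points;
    the curve is a monotone (PCHIP) interpolation of log-factor between them,
    clamped flat outside the anchor range.  ``shared_bias_sd`` and
    ``private_bias_sd`` are log-scale standard deviations of the shared and
    per-cell bias fields; ``dispersion`` is the variance of a mean-1 gamma
    multiplier (negative-binomial-style overdispersion); ``dropout_rate`` is
    the fraction of noise blocks amplified only at ``dropout_floor``.
    """

    name: str
    gc_anchors: Sequence[tuple[float, float]]
    shared_bias_sd: float = 0.0
    private_bias_sd: float = 0.0
    dispersion: float = 0.0
    dropout_rate: float = 0.0
    dropout_floor: float = 0.01
    noise_block_bp: int = 500_000
    shared_seed: int | None = None

    def __post_init__(self) -> None:
        gc = np.array([a[0] for a in self.gc_anchors], dtype=float)
        f = np.array([a[1] for a in self.gc_anchors], dtype=float)
        if np.any(f <= 0):
            raise ValueError("amplification factors must be positive")
        if np.any(np.diff(gc) <= 0):
            raise ValueError("gc_anchors must have strictly increasing GC")
        if min(self.shared_bias_sd, self.private_bias_sd, self.dispersion) < 0:
            raise ValueError("bias sds and dispersion must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        self._gc_lo, self._gc_hi = float(gc[0]), float(gc[-1])
        self._logcurve = (
            PchipInterpolator(gc, np.log(f)) if gc.size > 1 else (lambda x: np.log(f[0]) * np.ones_like(x))
        )

    def gc_bias_curve(self, gc: np.ndarray) -> np.ndarray:
        """Relative amplification factor at the given GC fractions."""
        x = np.clip(np.asarray(gc, dtype=float), self._gc_lo, self._gc_hi)
        return np.exp(self._logcurve(x))

    def shared_field_seed(self) -> int:
        if self.shared_seed is not None:
            return int(self.shared_seed)
        return zlib.crc32(self.name.encode()) & 0x7FFFFFFF


#: Default presets, calibrated so that on the default synthetic genome the
#: qualitative structure of real WGA data holds: MALBAC-like mean read GC sits
#: several points above the genome mean while WGA4-like stays within one
#: point; 500 kb MAPD orders bulk < WGA4 ~ MALBAC < MDA with only MDA beyond
#: the 0.45 usability threshold; cells of one method correlate more with each
#: other than with cells of other methods (MALBAC r > 0.9) while MDA cells
#: are nearly uncorrelated.  The reproducible (shared) bias is carried mostly
#: by the GC response — as in real data — so LOWESS correction removes it and
#: leaves profiles clean enough for segmentation; the residual non-GC shared
#: field is kept small for the same reason.
PRESETS: dict[str, MethodProfile] = {
    "bulk": MethodProfile("bulk", [(0.0, 1.0), (1.0, 1.0)]),
    "wga4": MethodProfile(
        "wga4",
        [(0.20, 1.06), (0.30, 1.03), (0.42, 1.0), (0.55, 0.97), (0.70, 0.95)],
        shared_bias_sd=0.03,
        private_bias_sd=0.06,
        dispersion=0.004,
    ),
    "malbac": MethodProfile(
        "malbac",
        [(0.20, 0.25), (0.30, 0.48), (0.42, 1.0), (0.50, 1.7), (0.60, 3.3), (0.75, 6.0)],
        shared_bias_sd=0.02,
        private_bias_sd=0.05,
        dispersion=0.004,
    ),
    "mda": MethodProfile(
        "mda",
        [(0.0, 1.0), (1.0, 1.0)],
        shared_bias_sd=0.02,
        private_bias_sd=0.80,
        dispersion=0.05,
        dropout_rate=0.02,
    ),
}


def get_profile(name_or_profile: str | MethodProfile) -> MethodProfile:
    if isinstance(name_or_profile, MethodProfile):
        return name_or_profile
    try:
        return PRESETS[name_or_profile]
    except KeyError:
        raise ValueError(f"unknown method preset: {name_or_profile!r}") from None


@dataclasses.dataclass
class CNVSpec:
    """Ground-truth copy-number events on top of a baseline ploidy.

    ``events`` are (chromosome, start bp, end bp, integer copy number),
    non-overlapping within a chromosome.  Sex chromosomes carry ``sex_copy``
    (1 for a male X) unless overridden by an event.
    """

    events: list[tuple[str, int, int, int]] = dataclasses.field(default_factory=list)
    baseline_ploidy: int = 2
    sex_copy: int = 1

    def validate(self, genome: GenomeModel) -> None:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, copy in self.events:
            if chrom not in genome.chrom_names:
                raise ValueError(f"CNV event on unknown chromosome {chrom}")
            if not 0 <= start < end <= genome.length(chrom):
                raise ValueError(f"CNV event outside {chrom}: [{start}, {end})")
            if copy < 0:
                raise ValueError("copy_number must be >= 0")
            per_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in per_chrom.items():
            ivals.sort()
            for (s0, e0), (s1, e1) in zip(ivals, ivals[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping CNV events on {chrom}")

    def copy_at_midpoints(
        self, genome: GenomeModel, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        base = self.baseline_ploidy if genome.is_autosome(chrom) else self.sex_copy
        copy = np.full(starts.shape[0], base, dtype=np.int64)
        mid = (np.asarray(starts) + np.asarray(ends)) // 2
        for c, s, e, k in self.events:
            if c == chrom:
                copy[(mid >= s) & (mid < e)] = k
        return copy

    def to_bed(self, path: str | Path) -> None:
        pd.DataFrame(self.events, columns=["chrom", "start", "end", "copy"]).to_csv(
            path, sep="\t", index=False, header=False
        )


@dataclasses.dataclass
class SimulatedSample:
    """One simulated sample: binned counts or read positions plus its truth."""

    sample_id: str
    method: str
    truth: CNVSpec
    seed: int
    counts: BinnedCounts | None = None
    read_positions: dict[str, np.ndarray] | None = None

    def write_positions_bed(self, path: str | Path) -> None:
        if self.read_positions is None:
            raise ValueError("sample was simulated in counts mode")
        frames = [
            pd.DataFrame({"chrom": chrom, "start": pos, "end": pos + 1})
            for chrom, pos in self.read_positions.items()
        ]
        pd.concat(frames).to_csv(path, sep="\t", index=False, header=False)


def truth_copy_track(genome: GenomeModel, cnv: CNVSpec, bin_set: BinSet) -> np.ndarray:
    """Integer copy number per bin: the copy of the event covering the bin
    midpoint, else the baseline (``sex_copy`` on sex chromosomes)."""
    cnv.validate(genome)
    out = np.empty(len(bin_set), dtype=np.int64)
    for chrom in bin_set.chrom_order:
        sl = bin_set.chrom_slice(chrom)
        if sl.stop == sl.start:
            continue
        out[sl] = cnv.copy_at_midpoints(
            genome, chrom, bin_set.start[sl], bin_set.end[sl]
        )
    return out


def _block_fields(
    genome: GenomeModel,
    chrom: str,
    profile: MethodProfile,
    rng_private: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block (shared log-bias, private multiplicative factor) for a chromosome.

    The shared field is drawn from a seed derived from the method alone, so
    every cell of one method sees the same realization; the private field
    (log-normal bias x gamma overdispersion x dropout) comes from the sample's
    own RNG.
    """
    n_blocks = -(-genome.length(chrom) // profile.noise_block_bp)
    rng_shared = np.random.default_rng(
        [profile.shared_field_seed(), zlib.crc32(chrom.encode()) & 0x7FFFFFFF]
    )
    shared = (
        rng_shared.standard_normal(n_blocks) * profile.shared_bias_sd
        if profile.shared_bias_sd > 0
        else np.zeros(n_blocks)
    )
    private = np.ones(n_blocks)
    if profile.private_bias_sd > 0:
        private *= np.exp(rng_private.standard_normal(n_blocks) * profile.private_bias_sd)
    if profile.dispersion > 0:
        k = 1.0 / profile.dispersion
        private *= rng_private.gamma(k, 1.0 / k, n_blocks)
    if profile.dropout_rate > 0:
        drop = rng_private.random(n_blocks) < profile.dropout_rate
        private[drop] *= profile.dropout_floor
    return shared, private


def simulate_sample(
    genome: GenomeModel,
    profile: str | MethodProfile,
    cnv: CNVSpec | None = None,
    total_reads: int = 29_400_000,
    bin_size_for_counts: int | str = 500_000,
    seed: int = 0,
    sample_id: str | None = None,
    copy_background: float = 0.05,
) -> SimulatedSample:
    """Simulate one sample as per-bin counts or single-bp read positions.

    With an integer ``bin_size_for_counts`` the expected read weight is
    evaluated per fixed bin and a multinomial draw allocates ``total_reads``
    across bins (the sum is exact).  With ``"positions"`` the weight is
    evaluated per GC-track window, reads are allocated to windows and placed
    uniformly within them.  Bins/windows at copy 0 keep a background weight of
    ``copy_background`` copies (residual contamination / mapping noise floor).
    """
    profile = get_profile(profile)
    cnv = cnv if cnv is not None else CNVSpec()
    cnv.validate(genome)
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    rng = np.random.default_rng(seed)
    sid = sample_id or f"{profile.name}_s{seed}"

    positions_mode = bin_size_for_counts == "positions"
    if positions_mode:
        bin_set = None
        units: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
        for chrom in genome.chrom_names:
            s, e = genome.window_bounds(chrom)
            units.append((chrom, s, e, genome.gc[chrom]))
    else:
        bin_set = make_fixed_bins(genome, int(bin_size_for_counts))
        units = []
        for chrom in genome.chrom_names:
            sl = bin_set.chrom_slice(chrom)
            units.append((chrom, bin_set.start[sl], bin_set.end[sl], bin_set.gc[sl]))

    weights = []
    for chrom, starts, ends, gc in units:
        copy = cnv.copy_at_midpoints(genome, chrom, starts, ends).astype(float)
        copy = np.maximum(copy, copy_background)
        w = copy * profile.gc_bias_curve(gc) * (ends - starts) / 1e6
        shared, private = _block_fields(genome, chrom, profile, rng)
        block = starts // profile.noise_block_bp
        w *= np.exp(shared[block]) * private[block]
        weights.append(w)
    w_all = np.concatenate(weights)
    p = w_all / w_all.sum()
    alloc = rng.multinomial(int(total_reads), p)

    if positions_mode:
        read_positions: dict[str, np.ndarray] = {}
        offset = 0
        for chrom, starts, ends, _ in units:
            n = starts.shape[0]
            c = alloc[offset : offset + n]
            offset += n
            rep_start = np.repeat(starts, c)
            rep_len = np.repeat(ends - starts, c)
            pos = rep_start + (rng.random(rep_start.shape[0]) * rep_len).astype(np.int64)
            read_positions[chrom] = pos
        return SimulatedSample(sid, profile.name, cnv, seed, read_positions=read_positions)

    counts = BinnedCounts(
        sample_id=sid, bin_set=bin_set, counts=alloc, total_reads=int(total_reads)
    )
    return SimulatedSample(sid, profile.name, cnv, seed, counts=counts)


def read_gc_fractions(
    genome: GenomeModel, read_positions: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Per-read GC fraction, taken from the GC window containing each read start."""
    out = []
    for chrom, pos in read_positions.items():
        idx = np.asarray(pos, dtype=np.int64) // genome.window_size
        out.append(genome.gc[chrom][idx])
    return np.concatenate(out) if out else np.empty(0)
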