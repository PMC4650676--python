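# Methods

This note documents the models, parameter choices and numerical decisions
behind `scwga-cnv`: what the synthetic data emulate, how each analysis stage
is defined, and what the package's tests do and do not demonstrate about
real sequencing data.

## Coordinate and normalization conventions

All genomic coordinates are 0-based, half-open (BED convention). A read is
assigned to the unique bin containing its start coordinate; read length is
irrelevant at the bin sizes used (≥ 50 kb). Bins never span chromosome
boundaries; the terminal remainder bin of a chromosome is kept (with its
true, shorter length) unless explicitly dropped. Sample read totals are
normalized to 10 million for GC profiling; all ratio statistics (ratio
vectors, CNR, MAPD) are scale-free, so the normalization constant never
affects them.

## Synthetic genome

`build_genome` produces an ordered set of chromosomes (default: five 40 Mb
autosomes plus a 30 Mb X, the last chromosome always designated X) tiled by
fixed-size GC windows (default 10 kb; any window size down to read scale is
supported). The GC landscape is smoothed Gaussian noise with a 1 Mb
correlation length — isochore-scale structure, which matters because (a)
adjacent bins must have similar GC (so GC bias does not masquerade as
bin-to-bin noise in MAPD) and (b) 500 kb bins must retain enough GC spread
(sd ≈ 0.07) for GC bias to dominate the between-cell correlation of
GC-biased methods, as it does in real data. The field is rescaled to mean
0.42 / sd 0.08 and clipped to (0, 1), giving a genome whose windows mostly
span 20–60 % GC. Everything is deterministic given the seed.

## Amplification-method model

Expected reads in a bin (or GC window, in read-position mode) are

    w_i ∝ copy_i × f_method(GC_i) × exp(S_i) × exp(P_i) × G_i × len_i

where `copy_i` is the ground-truth copy number (floored at a small
background, default 0.05 copies, so homozygous deletions keep a mapping-
noise floor), `f_method` is a monotone (PCHIP, log-space) interpolation of
per-method GC anchor points, `S` is a *shared* log-normal bias field drawn
once per method (identical across all cells of that method), `P` is a
*private* per-cell log-normal field, and `G` a mean-1 gamma multiplier
(negative-binomial-style overdispersion; real WGA read-count noise sits far
above Poisson). `S`, `P`, `G` are piecewise constant on 500 kb blocks
— the scale at which amplification noise is modeled as decorrelating.
Realized counts are one multinomial draw of the requested total over bins
(or windows), so totals are conserved exactly and Poisson-like counting
noise emerges naturally. Default depth is 29.4 million reads per sample.

Preset parameters (log-scale sds):

| preset | GC curve           | shared sd | private sd | gamma var | dropout |
|--------|--------------------|-----------|------------|-----------|---------|
| bulk   | flat               | 0         | 0          | 0         | 0       |
| wga4   | mild, tilted down  | 0.03      | 0.06       | 0.004     | 0       |
| malbac | steep, rising      | 0.02      | 0.05       | 0.004     | 0       |
| mda    | flat               | 0.02      | 0.80       | 0.05      | 0.02    |

Design rationale, and what it implies:

- **Reproducible bias is carried by the GC response.** The within-method
  correlation of MALBAC-like cells (> 0.95 on ratio vectors) comes almost
  entirely from their steep common GC curve; the non-GC shared field is kept
  small. This mirrors real data, where GC bias is the dominant reproducible
  artifact and is exactly what LOWESS correction removes. An earlier variant
  with a large iid non-GC shared field produced CNV-mimicking reproducible
  structure that segmentation correctly split — but no GC correction could
  remove it, which is incompatible with clean copy-number profiles. The
  cost: WGA4-like cells, whose curve is nearly flat, correlate only weakly
  with each other (r ≈ 0.1–0.2, versus ~0.9 reported for real GenomePlex
  data whose reproducible bias is largely non-GC, e.g. fragmentation-site
  preference). The simulator reproduces the categorical structure
  (within-method > between-method; MALBAC high; MDA ≈ 0), not that value.
- **WGA4's curve tilts slightly *down* with GC** (mean read GC ≈ −0.1 points
  vs the genome). A same-direction tilt as MALBAC, even a mild one, would
  correlate the two methods with each other more strongly than WGA4 cells
  correlate among themselves.
- **MDA** is modeled as a near-flat mean GC response with extreme private
  noise and 2 % block dropout: cells correlate with nothing and their MAPD
  (~1.1 at 500 kb) sits far beyond the 0.45 usability limit. Real MDA also
  shows a modest high-GC mean shift; the presets prioritize the noise/
  reproducibility signature, which is what the analysis stages consume.
- Resulting 500 kb MAPD ordering on defaults: bulk (≈ 0.005) < WGA4
  (≈ 0.12) ≈ MALBAC (≈ 0.20) < MDA (≈ 1.1). The ordering and the
  pass/fail split, not the absolute values, are the calibrated property;
  the bulk value reflects pure multinomial noise at ~64 k reads/bin on the
  small genome.

What the simulator deliberately does **not** model: sequence-level reads
(no FASTQ, errors, mappability), amplification chemistry mechanics,
per-cell GC-curve variability, and spatially heavy-tailed artifacts
(chimeras, foldbacks). Passing tests therefore demonstrate correctness of
the analysis machinery under a controlled bias/noise model, not performance
on any particular real library.

## GC profiling

Reference and sample GC compositions are histogrammed in 1 % GC classes and
normalized to 10 million; the reference histogram weights windows by length.
Relative coverage is the classwise sample/reference ratio, masked where the
reference holds < 0.01 % of its mass (ratios there are sampling noise). The
identity Σ ref_freq × relcov = sample total holds exactly with the mask
disabled.

## LOWESS GC correction

The GC trend is fit by robust locally weighted linear regression
(statsmodels LOWESS; span 0.3 of the bins, one robustness iteration) of
log₂(count) on bin GC over positive-count bins, then interpolated to all
bins. Fitting in log space makes multiplicative bias additive — an
exponential GC bias is linear in log₂ and is removed exactly by a local
linear fit. Corrected counts are `count × mean(count) / trend(GC)`,
renormalized to preserve the mean; zero-count bins stay zero; the trend is
floored at half its 1st-percentile so sparse GC extremes cannot explode
counts. Replacing counts *by* the regression values (which flattens real
CNV signal along with the bias) is available as `mode="replace"` for
comparison only.

One non-obvious necessity: bins carrying real copy-number changes must be
**masked out of the trend fit**. A 20 Mb deletion plus an X monosomy put
~20 % of a small genome's bins at half depth, concentrated in whatever GC
range they occupy; the initial fit is dragged toward them there, and soft
bisquare reweighting never rejects a coherent half-copy cluster (its
residual, ≈ −1 in log₂, is well inside the 6-MAD bisquare window). The fit
is therefore re-estimated up to three times after masking bins whose
residual exceeds 2 robust standard deviations. On CNV-free samples the mask
removes only distribution tails and the trend is essentially unchanged.
Limitations remain at GC extremes occupied *only* by altered bins: there
the trend is an extrapolation and corrected values inherit extra variance.

## Reproducibility analysis

Per-bin ratio vectors (bin count / mean count over the scope, autosomes by
default) are compared by Pearson correlation; bins zero in every sample are
excluded; a constant vector yields undefined (NaN) correlations, reported
as missing rather than zero. Clustering is agglomerative on distance
1 − r (average linkage by default), with missing distances imputed as the
maximum observed distance, and the tree exported as Newick. Correlations
are validated in-tree against a direct two-pass covariance computation.

## MAPD

CNR_i is bin i's count over the mean autosomal bin count. MAPD is the
median of |log₂ CNR_{i+1} − log₂ CNR_i| over within-chromosome neighbor
pairs; zero-CNR bins are excluded together with both adjacencies. The
statistic is exactly scale-invariant and robust: a single real copy-number
step touches only its boundary adjacencies and cannot move the median until
steps outnumber half the adjacencies. For iid Gaussian log₂ CNR with sd σ,
MAPD → √2 Φ⁻¹(0.75) σ ≈ 0.9539 σ (median of |N(0, 2σ²)|), which the tests
verify to 3 % at 5,797 bins. Usability classification is MAPD ≤ 0.45
(boundary inclusive). MAPD-vs-bin-size tables aggregate fine-bin counts by
exact summation (coarse sizes must be multiples of the fine size) or
re-count read positions.

## Segmentation (CBS)

Circular binary segmentation on log₂ CNR (corrected counts plus a 0.5
pseudocount against empty bins, over the autosomal mean). Within each
current segment of n bins, every arc [i, j) whose induced pieces all hold
at least `min_width` bins is scored with the two-sample pooled-variance t²
between arc and complement (computed from cumulative sums; a prefix arc is
the same partition as its complement suffix and is enumerated once). The
best split is accepted when its permutation p-value — the fraction of
within-segment permutations whose *best* statistic is at least the observed
one, computed with (1+exceedances)/(1+nperm) — is below alpha; permutations
run in 250-perm chunks with early rejection once acceptance is impossible,
which leaves decisions exactly equal to the full-permutation run.
Recursion proceeds on the resulting pieces. Defaults: alpha = 0.02,
nperm = 1000, min_width = 5, undo_sd = 1.0; the permutation RNG is seeded
per (seed, chromosome, segment), so results are reproducible and
independent of recursion order. The hybrid tail approximation used by the
reference R implementation is deliberately not implemented: at these bin
counts full permutation is affordable and simpler to reason about.

Two post-passes follow. **sd-undo** repeatedly merges the adjacent pair of
segments with the smallest mean difference while that difference is below
`undo_sd` × noise sd, the noise sd estimated as 1.4826 × median |successive
difference| / √2. **Boundary refinement** then reassigns up to three
boundary bins per cut to the neighboring segment whose *core* mean (edges
excluded) they are closer to. Refinement exists because `min_width` blurs
events shorter than five bins: a 3-bin deletion is forced into a ≥ 5-bin
segment diluted with flanking bins, which would otherwise pass the > 2 Mb
call filter that the true 1.5 Mb event must fail. Type-I error of the whole
procedure on pure-noise 100-bin chromosomes is ~1–3 % at alpha = 0.02.

## Copy number and CNV calls

Segment copy number is 2 × (segment mean corrected count) / (autosomal mean
corrected count), rounded half-away-from-zero and floored at 0. A segment
becomes a CNV call when it (1) spans ≥ 4 bins, (2) exceeds 2 Mb, (3)
deviates from the sample's median segment mean by more than 2 × MAD of the
segment means (MAD with the R convention's 1.4826 normal-consistency
factor), and (4) its rounded copy differs from the diploid baseline.
Criterion (4) is this package's addition: on a six-chromosome genome a
sample has only ~8 segments, the MAD of their means can collapse to ~0.01
in log₂, and criterion (3) alone then promotes sub-integer wobbles — whose
own copy estimate still rounds to 2 — into calls. A variant that measures
deviation from a fixed baseline instead of the median (`mode="baseline"`),
and disabling (4) (`baseline_copy=None`), are available. Call direction
follows the sign of the deviation; a male X at one copy is reported as a
loss call, matching how X monosomy is read off copy-number profiles.

On defaults, 50 simulated WGA4-like cells carrying an X monosomy and a
20.5 Mb heterozygous deletion yield ≥ 95 % event recall with boundaries
within one 500 kb bin and ~100 % call precision under overlap matching
(a call is correct when at least half its span lies in a true event of the
same direction — occasional fragmentation of the 41-bin deletion into 2–3
copy-1 pieces is a breakpoint error, not a false discovery). MDA-preset
noise drives recall to zero at this event size, which is why the pipeline
refuses CNV calling for samples failing the MAPD threshold.

## Pipeline

`run_pipeline` wires the stages end-to-end from a YAML-serializable config:
genome (synthetic parameters or a serialized directory), sample roster
(method, depth, truth events), bin size, GC correction, MAPD thresholding,
segmentation and call criteria, one global seed from which per-sample seeds
derive. Samples failing MAPD at the CNV bin size are excluded from
segmentation and calling (overridable), and the report records them. All
artifacts are plain text (TSV/BED/BEDGraph/SEG-like/Newick/JSON); reruns
with the same config and seed are byte-identical, and the report embeds the
full config (path-independent) so a run can be reproduced from its report
alone.

## Problem sizes used in tests

The test suite and the acceptance script run on the default desk-scale
genome (230 Mb, 460 × 500 kb bins) with 29.4 M reads per sample in
counts mode — chosen so a full pipeline run takes seconds while keeping
per-bin depth high enough that amplification bias, not counting noise,
dominates, as in the shallow-sequencing regime the methods target. The
closed-form MAPD check uses 5,797 bins, the reproducibility and recovery
experiments use 3–6 and 50 cells respectively, and CBS type-I control uses
100-bin chromosomes with 1000 permutations.
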