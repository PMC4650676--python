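"""End-to-end pipeline: simulate -> bin -> GC profile/correct -> QC -> CNV.

A :class:`PipelineConfig` (YAML-serializable) describes the genome, the
sample roster, binning, GC correction, MAPD QC and segmentation parameters;
:func:`run_pipeline` executes every stage, writes all tabular artifacts under
the output directory, and returns a :class:`RunReport` whose numbers are all
traceable to emitted files.  Reruns with the same config and seed are
byte-identical.  Samples failing the MAPD detection-limit threshold at the
CNV bin size are excluded from CNV calling by default (recorded in the
report), since their noise floor exceeds what segmentation can interpret.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .binning import make_fixed_bins, ratio_vector, uniformity_summary
from .cnv import (
    SegmentationParams,
    call_cnvs,
    calls_to_bed,
    log2_cnr_signal,
    round_copy,
    segment_copy_number,
    segment_sample,
    segments_to_frame,
)
from .gcbias import (
    lowess_correct,
    reference_gc_histogram,
    relative_coverage,
    sample_gc_histogram,
)
from .genome import GenomeModel, build_genome
from .mapd import MAPD_THRESHOLD, cnr_vector, compute_mapd, mapd_vs_binsize
from .repro import cluster_samples, pairwise_correlation
from .simulate import CNVSpec, simulate_sample


@dataclasses.dataclass
class SampleSpec:
    sample_id: str
    method: str
    reads: int = 29_400_000
    cnv_events: list[tuple[str, int, int, int]] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class PipelineConfig:
    """Everything needed to rerun an analysis, including the global seed."""

    out_dir: str
    seed: int = 0
    genome: dict[str, Any] = dataclasses.field(default_factory=dict)
    samples: list[SampleSpec] = dataclasses.field(default_factory=list)
    bin_size: int = 500_000
    mapd_bin_sizes: list[int] = dataclasses.field(
        default_factory=lambda: [500_000, 1_000_000]
    )
    gc_correction: bool = True
    lowess_span: float = 0.3
    mapd_threshold: float = MAPD_THRESHOLD
    correlation_scope: str = "autosomes"
    linkage_method: str = "average"
    segmentation: dict[str, Any] = dataclasses.field(default_factory=dict)
    cnv_criteria: dict[str, Any] = dataclasses.field(
        default_factory=lambda: {"min_bins": 4, "min_size_bp": 2_000_000, "mad_mult": 2.0}
    )
    call_cnvs_on_qc_fail: bool = False

    def __post_init__(self) -> None:
        if not self.samples:
            return
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        sizes = sorted(self.mapd_bin_sizes)
        if sizes != list(self.mapd_bin_sizes):
            self.mapd_bin_sizes = sizes

    def validate(self) -> None:
        if not self.samples:
            raise ValueError("config has an empty sample list")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["samples"] = [dataclasses.asdict(s) for s in self.samples]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        samples = []
        for s in d.pop("samples", []):
            s = dict(s)
            s["cnv_events"] = [tuple(e) for e in s.get("cnv_events", [])]
            samples.append(SampleSpec(**s))
        return cls(samples=samples, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def demo_config(out_dir: str | Path, seed: int = 0) -> PipelineConfig:
    """Demo roster: one bulk sample plus two cells per WGA method.

    The second WGA4 cell carries a 20.5 Mb heterozygous deletion on chr3 (a
    mosaic sub-chromosomal CNV present in one cell only); every sample is
    male, so the X sits at one copy.
    """
    deletion = [("chr3", 10_000_000, 30_500_000, 1)]
    samples = [SampleSpec("bulk_1", "bulk")]
    for method in ("malbac", "wga4", "mda"):
        samples.append(SampleSpec(f"{method}_cell1", method))
        samples.append(
            SampleSpec(
                f"{method}_cell2",
                method,
                cnv_events=deletion if method == "wga4" else [],
            )
        )
    return PipelineConfig(out_dir=str(out_dir), seed=seed, samples=samples)


@dataclasses.dataclass
class RunReport:
    config: dict[str, Any]
    version: str
    samples: list[dict[str, Any]]
    n_bins: int
    correlation_file: str
    clustering_file: str
    qc_failed: list[str]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _sample_seed(global_seed: int, index: int) -> int:
    return (global_seed * 100_003 + 7 * index + 1) % (2**31)


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sub in ("genome", "counts", "corrected", "gc", "segments", "calls"):
        (out / sub).mkdir(exist_ok=True)

    genome_cfg = dict(config.genome)
    genome_dir = genome_cfg.pop("dir", None)
    if genome_dir:
        genome = GenomeModel.from_dir(genome_dir)
    else:
        genome = build_genome(**{"seed": config.seed, **genome_cfg})
    genome.to_dir(out / "genome")
    bin_set = make_fixed_bins(genome, config.bin_size)
    bin_set.to_bed(out / "bins.bed")

    ref_hist = reference_gc_histogram(genome)
    ref_hist.to_tsv(out / "gc" / "reference.hist.tsv")

    samples_out: list[dict[str, Any]] = []
    ratio_vectors = []
    mapd_rows = []
    qc_failed: list[str] = []
    per_sample = {}
    for idx, spec in enumerate(config.samples):
        seed = _sample_seed(config.seed, idx)
        sim = simulate_sample(
            genome,
            spec.method,
            cnv=CNVSpec(events=[tuple(e) for e in spec.cnv_events]),
            total_reads=spec.reads,
            bin_size_for_counts=config.bin_size,
            seed=seed,
            sample_id=spec.sample_id,
        )
        counts = sim.counts
        counts.to_tsv(out / "counts" / f"{spec.sample_id}.tsv")

        hist = sample_gc_histogram(
            bin_counts=counts.counts, bin_gc=bin_set.gc, label=spec.sample_id
        )
        hist.to_tsv(out / "gc" / f"{spec.sample_id}.hist.tsv")
        relative_coverage(hist, ref_hist).to_tsv(out / "gc" / f"{spec.sample_id}.relcov.tsv")

        if config.gc_correction and spec.method != "bulk":
            corrected = lowess_correct(counts.counts, bin_set.gc, span=config.lowess_span)
        else:
            corrected = counts.counts.astype(float)
        corr_counts = dataclasses.replace(counts, counts=corrected)
        corr_counts.to_tsv(out / "corrected" / f"{spec.sample_id}.tsv")

        mapd_table = mapd_vs_binsize(
            genome,
            config.mapd_bin_sizes,
            counts=counts,
            threshold=config.mapd_threshold,
        )
        mapd_rows.append(mapd_table)
        at_cnv_size = compute_mapd(cnr_vector(counts), threshold=config.mapd_threshold)
        qc_pass = at_cnv_size.mapd <= config.mapd_threshold

        rv = ratio_vector(counts, scope=config.correlation_scope)
        ratio_vectors.append(rv)
        quart = uniformity_summary(rv, log10=True)

        per_sample[spec.sample_id] = (corr_counts, qc_pass, at_cnv_size, hist, quart, seed)
        if not qc_pass:
            qc_failed.append(spec.sample_id)

    import pandas as pd

    pd.concat(mapd_rows, ignore_index=True).to_csv(
        out / "mapd.tsv", sep="\t", index=False, float_format="%.6f"
    )

    corr = pairwise_correlation(ratio_vectors)
    corr.to_tsv(out / "correlation.tsv")
    tree = cluster_samples(corr, method=config.linkage_method)
    tree.write_newick(out / "clustering.newick")

    seg_params = SegmentationParams(**{"seed": config.seed, **config.segmentation})
    for spec in config.samples:
        corr_counts, qc_pass, at_cnv_size, hist, quart, seed = per_sample[spec.sample_id]
        n_calls = None
        if qc_pass or config.call_cnvs_on_qc_fail:
            signal = log2_cnr_signal(corr_counts.counts, bin_set)
            segments = segment_sample(signal, bin_set, seg_params)
            segments = round_copy(segment_copy_number(segments, corr_counts.counts, bin_set))
            segments_to_frame(spec.sample_id, segments).to_csv(
                out / "segments" / f"{spec.sample_id}.seg.tsv", sep="\t", index=False
            )
            calls = call_cnvs(segments, **config.cnv_criteria)
            calls_to_bed(calls).to_csv(
                out / "calls" / f"{spec.sample_id}.calls.bed",
                sep="\t",
                index=False,
                header=False,
            )
            n_calls = len(calls)
        samples_out.append(
            {
                "sample_id": spec.sample_id,
                "method": spec.method,
                "seed": seed,
                "reads": spec.reads,
                "mean_gc": round(hist.mean_gc(), 4),
                "quartiles_log10": {
                    "q1": round(quart.q1, 4),
                    "median": round(quart.median, 4),
                    "q3": round(quart.q3, 4),
                    "iqr": round(quart.iqr, 4),
                },
                "mapd": round(at_cnv_size.mapd, 4),
                "qc_pass": qc_pass,
                "n_cnv_calls": n_calls,
            }
        )

    config_dict = config.to_dict()
    config_dict["out_dir"] = "."  # path-independent provenance
    report = RunReport(
        config=config_dict,
        version=_pkg_version,
        samples=samples_out,
        n_bins=len(bin_set),
        correlation_file="correlation.tsv",
        clustering_file="clustering.newick",
        qc_failed=qc_failed,
    )
    report.to_json(out / "report.json")
    return report
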