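"""End-to-end orchestration: hqc -> merge -> ldbin -> segment -> regions.

One config carries every stage parameter (with the conventional defaults
for this kind of two-platform haploid study), one master seed drives every
stochastic step (per-stage generators are derived by stable hashing of the
stage name, so reruns of a single stage reproduce the full run), and a run
manifest records parameters, per-stage record counts and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hqc as hqc_mod
from . import ldbins as ld_mod
from . import merge as merge_mod
from . import regions as regions_mod
from . import segment as seg_mod
from .io import (
    GenomeMetadata,
    GenotypeMatrix,
    IntensityMatrix,
    MarkerAnnotation,
    read_marker_annotation,
    read_matrix,
    write_bed,
    write_matrix,
    write_marker_annotation,
)


@dataclass
class PipelineConfig:
    """Paths, stage parameters and the master seed for one pipeline run."""

    # inputs
    annotation_A: str = ""
    annotation_B: str = ""
    genotypes_A: str = ""
    genotypes_B: str = ""
    intensities_A: str = ""
    intensities_B: str = ""
    genome: str = ""
    outdir: str = "chmarray_out"
    master_seed: int = 0
    # haploid QC
    het_level: float = 0.01
    het_significance: float | None = 0.01
    hqc_bin_width: float = 0.1
    hqc_threshold_A: float | None = None  # None -> derive from the het curve
    hqc_threshold_B: float | None = None
    marker_min_call_rate: float = 0.90
    sample_min_call_rate: float = 0.96
    # merge
    freq_tolerance: float = 0.1
    rare_maf: float = 0.05
    # LD bins
    maf_min: float = 0.05
    ld_window_bp: int = 300_000
    r2_threshold: float = 0.80
    # segmentation
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 10_000
    cbs_min_width: int = 2
    loss_threshold_A: float | None = None  # None -> derive from coverage profile
    loss_threshold_B: float | None = None
    gain_threshold: float = 0.5
    min_segment_size_bp: int = 50
    # regions
    min_overlap_bp: int = 1
    size_corr_min_length_bp: int = 10_000
    merge_bookended: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PipelineInputs:
    ann_A: MarkerAnnotation
    ann_B: MarkerAnnotation
    geno_A: GenotypeMatrix
    geno_B: GenotypeMatrix
    int_A: IntensityMatrix
    int_B: IntensityMatrix
    genome: GenomeMetadata


@dataclass
class PipelineResult:
    """In-memory results of a full run (also serialized to the outdir)."""

    manifest: dict
    geno_A_hqc: GenotypeMatrix
    geno_B_hqc: GenotypeMatrix
    hqc_reports: dict
    merged: GenotypeMatrix
    merged_annotation: MarkerAnnotation
    merge_report: merge_mod.MergeReport
    bins: list
    segments: dict  # platform -> classified CNV segment frame
    loss_thresholds: dict
    concordance: regions_mod.ConcordanceReport
    size_correlation: tuple[float, int]
    regions: pd.DataFrame
    genome_fraction: float


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (int(master_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


def load_inputs(config: PipelineConfig) -> PipelineInputs:
    return PipelineInputs(
        ann_A=read_marker_annotation(config.annotation_A, "A"),
        ann_B=read_marker_annotation(config.annotation_B, "B"),
        geno_A=read_matrix(config.genotypes_A, "genotype"),
        geno_B=read_matrix(config.genotypes_B, "genotype"),
        int_A=read_matrix(config.intensities_A, "intensity"),
        int_B=read_matrix(config.intensities_B, "intensity"),
        genome=GenomeMetadata.from_yaml(config.genome),
    )


def run_stages(config: PipelineConfig, inputs: PipelineInputs) -> PipelineResult:
    """Execute all stages in memory; see :func:`run_pipeline` for file I/O."""
    counts: dict[str, dict] = {}

    # ---- haploid QC ------------------------------------------------------
    try:
        ga, rep_a, curve_a = hqc_mod.run_hqc(
            inputs.geno_A, inputs.int_A, inputs.ann_A, platform="A",
            fixed_threshold=config.hqc_threshold_A,
            het_level=config.het_level, het_significance=config.het_significance,
            bin_width=config.hqc_bin_width,
            marker_min=config.marker_min_call_rate,
        )
        gb, rep_b, curve_b = hqc_mod.run_hqc(
            inputs.geno_B, inputs.int_B, inputs.ann_B, platform="B",
            fixed_threshold=config.hqc_threshold_B,
            het_level=config.het_level, het_significance=config.het_significance,
            bin_width=config.hqc_bin_width,
            marker_min=config.marker_min_call_rate,
        )
        ga, gb, retained = hqc_mod.filter_samples_joint(
            ga, gb, sample_min=config.sample_min_call_rate
        )
        rep_a.samples_retained = retained
        rep_b.samples_retained = retained
    except Exception as exc:
        raise RuntimeError(f"stage hqc failed: {exc}") from exc
    counts["hqc"] = {
        "n_samples_retained": len(retained),
        "n_markers_A": len(ga.markers),
        "n_markers_B": len(gb.markers),
        "threshold_A": rep_a.threshold,
        "threshold_B": rep_b.threshold,
    }

    # ---- merge -----------------------------------------------------------
    try:
        rec = merge_mod.reconcile_strands(
            inputs.ann_A, inputs.ann_B, ga, gb,
            freq_tolerance=config.freq_tolerance, rare_maf=config.rare_maf,
        )
        merged, merged_ann, merge_report = merge_mod.merge_calls(ga, gb, inputs.ann_A, rec)
    except Exception as exc:
        raise RuntimeError(f"stage merge failed: {exc}") from exc
    counts["merge"] = {
        "n_markers_merged": len(merged.markers),
        "n_shared": merge_report.n_shared_snps,
        "n_flipped": merge_report.n_flipped,
        "discordance_fraction": merge_report.discordance_fraction,
    }

    # ---- LD bins ---------------------------------------------------------
    try:
        pairs = ld_mod.pairwise_r2(
            merged, merged_ann, maf_min=config.maf_min, window_bp=config.ld_window_bp
        )
        common = ld_mod.common_snp_ids(merged, maf_min=config.maf_min)
        marker_tbl = merged_ann.df[merged_ann.df["marker_id"].isin(set(common))]
        bins = ld_mod.greedy_bins(pairs, marker_tbl, r2_threshold=config.r2_threshold)
    except Exception as exc:
        raise RuntimeError(f"stage ldbin failed: {exc}") from exc
    counts["ldbin"] = {
        "n_common_snps": len(common),
        "n_bins": len(bins),
        "n_singleton_bins": sum(1 for b in bins if b.is_singleton),
        "singleton_fraction": ld_mod.singleton_fraction(bins) if bins else float("nan"),
    }

    # ---- segmentation ----------------------------------------------------
    segments: dict[str, pd.DataFrame] = {}
    neutrals: dict[str, pd.DataFrame] = {}
    loss_thresholds: dict[str, float] = {}
    try:
        for platform, intens, ann, override in (
            ("A", inputs.int_A, inputs.ann_A, config.loss_threshold_A),
            ("B", inputs.int_B, inputs.ann_B, config.loss_threshold_B),
        ):
            intens_r = intens.subset_samples(retained)
            raw = seg_mod.segment_intensity_matrix(
                intens_r, ann, platform,
                alpha=config.cbs_alpha, n_perm=config.cbs_n_perm,
                min_width=config.cbs_min_width,
                seed=stage_seed(config.master_seed, f"segment_{platform}"),
            )
            raw = seg_mod.split_at_centromere(raw, inputs.genome, intens_r, ann)
            profile = seg_mod.coverage_profile(raw)
            thr = float(override) if override is not None else seg_mod.find_loss_threshold(profile)
            cnv, neutral = seg_mod.classify_and_filter(
                raw, thr, gain_threshold=config.gain_threshold,
                min_size_bp=config.min_segment_size_bp,
            )
            segments[platform] = cnv
            neutrals[platform] = neutral
            loss_thresholds[platform] = thr
    except Exception as exc:
        raise RuntimeError(f"stage segment failed: {exc}") from exc
    counts["segment"] = {
        "loss_threshold_A": loss_thresholds["A"],
        "loss_threshold_B": loss_thresholds["B"],
        "n_cnv_segments_A": len(segments["A"]),
        "n_cnv_segments_B": len(segments["B"]),
        "n_loss_A": int((segments["A"]["state"] == "loss").sum()) if len(segments["A"]) else 0,
        "n_loss_B": int((segments["B"]["state"] == "loss").sum()) if len(segments["B"]) else 0,
    }

    # ---- regions ---------------------------------------------------------
    try:
        concordance = regions_mod.intersect_platforms(
            segments["A"], segments["B"], min_overlap_bp=config.min_overlap_bp
        )
        size_corr = regions_mod.size_correlation(
            concordance, min_length_bp=config.size_corr_min_length_bp
        )
        all_cnv = pd.concat([segments["A"], segments["B"]], ignore_index=True)
        regions, genome_fraction = regions_mod.merge_to_regions(
            all_cnv, inputs.genome, merge_bookended=config.merge_bookended
        )
    except Exception as exc:
        raise RuntimeError(f"stage regions failed: {exc}") from exc
    counts["regions"] = {
        "n_cnv_regions": len(regions),
        "genome_fraction": genome_fraction,
        "n_overlapping_A": concordance.n_overlapping_A,
        "n_overlapping_B": concordance.n_overlapping_B,
    }

    manifest = {
        "package": "chmarray",
        "parameters": asdict(config),
        "stage_counts": counts,
    }
    return PipelineResult(
        manifest=manifest,
        geno_A_hqc=ga, geno_B_hqc=gb,
        hqc_reports={"A": rep_a, "B": rep_b, "curve_A": curve_a, "curve_B": curve_b},
        merged=merged, merged_annotation=merged_ann, merge_report=merge_report,
        bins=bins, segments=segments, loss_thresholds=loss_thresholds,
        concordance=concordance, size_correlation=size_corr,
        regions=regions, genome_fraction=genome_fraction,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs | None = None) -> dict:
    """Run every stage, write all outputs under ``config.outdir``, return the manifest."""
    if inputs is None:
        inputs = load_inputs(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = run_stages(config, inputs)

    write_matrix(res.geno_A_hqc, outdir / "genotypes_A_hqc.tsv")
    write_matrix(res.geno_B_hqc, outdir / "genotypes_B_hqc.tsv")
    pd.concat(
        [res.hqc_reports["A"].to_frame(), res.hqc_reports["B"].to_frame()],
        ignore_index=True,
    ).to_csv(outdir / "hqc_report.tsv", sep="\t", index=False)
    res.hqc_reports["curve_A"].to_frame().to_csv(outdir / "het_curve_A.tsv", sep="\t", index=False)
    res.hqc_reports["curve_B"].to_frame().to_csv(outdir / "het_curve_B.tsv", sep="\t", index=False)

    write_matrix(res.merged, outdir / "merged_genotypes.tsv")
    write_marker_annotation(res.merged_annotation, outdir / "merged_annotation.tsv")
    res.merge_report.to_frame().to_csv(outdir / "merge_report.tsv", sep="\t", index=False)

    ld_mod.bin_summary(res.bins).to_csv(outdir / "ld_bins.tsv", sep="\t", index=False)

    for platform in ("A", "B"):
        seg = res.segments[platform]
        intervals = [
            (r.chrom, int(r.start), int(r.end), r.state, int(round(r.mean_intensity * 100)), r.sample_id)
            for r in seg.itertuples(index=False)
        ]
        write_bed(intervals, outdir / f"cnv_segments_{platform}.bed")
        seg.to_csv(outdir / f"cnv_segments_{platform}.tsv", sep="\t", index=False)

    res.concordance.to_frame().to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    write_bed(regions_mod.regions_to_bed_intervals(res.regions), outdir / "cnv_regions.bed")

    checksums = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*")) if p.name != "manifest.json"
    }
    manifest = dict(res.manifest)
    manifest["checksums"] = checksums
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
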