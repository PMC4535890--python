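"""Haploid quality control (HQC).

A duplicated haploid genome is homozygous everywhere, so heterozygous calls
are artifacts — overwhelmingly genotyping noise at markers inside
homozygously deleted (or divergent paralogous) regions, where signal
intensity is low and no call should be made. HQC therefore:

1. profiles the het fraction as a function of relative signal intensity,
2. derives (or accepts) a per-platform intensity reliability threshold at
   the level where heterozygosity reaches ~1%,
3. forces every heterozygous call and every call below the threshold to
   no-call,
4. drops duplicate-position markers, low-call-rate markers and
   low-call-rate samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import HET, NOCALL, GenotypeMatrix, IntensityMatrix, MarkerAnnotation

NEG_INF = float("-inf")


@dataclass
class HetIntensityCurve:
    """Het fraction and cumulative call fraction per intensity bin.

    ``bin_edges`` has ``len(het_fraction) + 1`` entries; bin *i* covers
    ``(bin_edges[i], bin_edges[i+1]]``. Bins with no calls carry NaN
    het fraction. ``cumulative_call_fraction[i]`` is the fraction of all
    calls at or above bin *i*'s lower edge.
    """

    bin_edges: np.ndarray
    het_fraction: np.ndarray
    cumulative_call_fraction: np.ndarray
    n_calls: np.ndarray
    n_het: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "n_calls": self.n_calls,
                "n_het": self.n_het,
                "het_fraction": self.het_fraction,
                "cumulative_call_fraction": self.cumulative_call_fraction,
            }
        )


@dataclass
class HQCReport:
    """Tally of what HQC forced and removed on one platform."""

    platform: str
    threshold: float
    n_het_forced: int = 0
    n_low_intensity_forced: int = 0
    fraction_forced: float = 0.0
    n_duplicate_markers_removed: int = 0
    n_markers_removed_call_rate: int = 0
    samples_retained: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "platform": [self.platform],
                "threshold": [self.threshold],
                "n_het_forced": [self.n_het_forced],
                "n_low_intensity_forced": [self.n_low_intensity_forced],
                "fraction_forced": [self.fraction_forced],
                "n_duplicate_markers_removed": [self.n_duplicate_markers_removed],
                "n_markers_removed_call_rate": [self.n_markers_removed_call_rate],
                "n_samples_retained": [len(self.samples_retained)],
            }
        )


def _aligned_intensity(
    genotypes: GenotypeMatrix, intensities: IntensityMatrix
) -> np.ndarray:
    """Intensity values aligned to the genotype matrix (NaN where absent)."""
    if list(intensities.samples) != list(genotypes.samples):
        raise ValueError("genotype and intensity matrices have different samples")
    idx = intensities.marker_index()
    cols = np.array([idx.get(m, -1) for m in genotypes.markers])
    out = np.full((len(genotypes.samples), len(genotypes.markers)), np.nan)
    have = cols >= 0
    out[:, have] = intensities.values[:, cols[have]]
    return out


def het_intensity_curve(
    genotypes: GenotypeMatrix,
    intensities: IntensityMatrix,
    bin_width: float = 0.1,
) -> HetIntensityCurve:
    """Bin called genotypes by signal intensity and measure the het fraction.

    Only made calls with a non-missing intensity contribute. Raises if there
    is nothing to bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    vals = _aligned_intensity(genotypes, intensities)
    called = genotypes.call_mask() & ~np.isnan(vals)
    if not called.any():
        raise ValueError("no called genotypes with intensity to profile")
    x = vals[called]
    is_het = genotypes.calls[called] == HET
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    # bin i is (edges[i], edges[i+1]]; values exactly at lo land in bin 0
    which = np.clip(np.ceil((x - lo) / bin_width).astype(int) - 1, 0, n_bins - 1)
    n_calls = np.bincount(which, minlength=n_bins)
    n_het = np.bincount(which[is_het], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_fraction = np.where(n_calls > 0, n_het / np.maximum(n_calls, 1), np.nan)
    total = n_calls.sum()
    # calls at or above each bin's lower edge
    above = total - np.concatenate(([0], np.cumsum(n_calls)[:-1]))
    cumulative = above / total
    return HetIntensityCurve(edges, het_fraction, cumulative, n_calls, n_het)


def find_intensity_threshold(
    curve: HetIntensityCurve,
    het_level: float = 0.01,
    significance: float | None = None,
) -> float:
    """Intensity below which calls are deemed unreliable.

    Scanning the binned het-vs-intensity profile, the threshold is the upper
    edge of the highest-intensity bin whose het fraction is at or above
    ``het_level`` (~1%): everything below that edge sits in the
    het-enriched, unreliable regime. With ``significance`` set, a bin only
    counts as het-enriched when its het count is significantly above
    ``het_level`` by a one-sided binomial test at that level — this keeps a
    single stray het call in a sparsely populated tail bin from dragging
    the threshold into the call bulk. Returns ``-inf`` when no bin reaches
    the level (nothing to force); raises when every occupied bin does (the
    data are unusable).
    """
    defined = ~np.isnan(curve.het_fraction)
    if not defined.any():
        raise ValueError("empty het-intensity curve")
    if significance is None:
        hot = defined & (curve.het_fraction >= het_level)
    else:
        from scipy.stats import binom

        with np.errstate(invalid="ignore"):
            pval = binom.sf(curve.n_het - 1, np.maximum(curve.n_calls, 1), het_level)
        hot = defined & (curve.n_calls > 0) & (pval < significance)
    if not (defined & ~hot).any():
        raise ValueError(
            f"het fraction >= {het_level} in every occupied bin; data unusable"
        )
    if not hot.any():
        return NEG_INF
    last_hot = int(np.flatnonzero(hot)[-1])
    return float(curve.bin_edges[last_hot + 1])


def apply_hqc(
    genotypes: GenotypeMatrix,
    intensities: IntensityMatrix,
    threshold: float,
    platform: str = "",
) -> tuple[GenotypeMatrix, HQCReport]:
    """Force het calls and weak-signal calls to no-call.

    Every heterozygous call becomes a no-call regardless of intensity; every
    made call with intensity strictly below ``threshold`` becomes a no-call.
    A het below the threshold is counted once, in the low-intensity tally.
    Missing intensities never trigger the low-intensity rule.
    """
    vals = _aligned_intensity(genotypes, intensities)
    called = genotypes.call_mask()
    n_calls_before = int(called.sum())
    low = called & ~np.isnan(vals) & (vals < threshold)
    het = called & (genotypes.calls == HET) & ~low
    out = genotypes.calls.copy()
    out[low | het] = NOCALL
    report = HQCReport(
        platform=platform,
        threshold=threshold,
        n_het_forced=int(het.sum()),
        n_low_intensity_forced=int(low.sum()),
        fraction_forced=float((low | het).sum() / n_calls_before) if n_calls_before else 0.0,
    )
    return GenotypeMatrix(list(genotypes.samples), list(genotypes.markers), out), report


def remove_duplicate_position_markers(
    annotation: MarkerAnnotation, genotypes: GenotypeMatrix
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop every SNP marker sharing its (chrom, pos) with another SNP marker.

    All members of a duplicated-position group are removed — the platform
    gives no reason to prefer one assay over the other.
    """
    snp = annotation.df[annotation.df["probe_class"] == "snp"]
    dup_mask = snp.duplicated(subset=["chrom", "pos"], keep=False)
    dup_ids = set(snp.loc[dup_mask, "marker_id"])
    removed = [m for m in genotypes.markers if m in dup_ids]
    if not removed:
        return genotypes, []
    keep = [m for m in genotypes.markers if m not in dup_ids]
    return genotypes.subset_markers(keep), removed


def marker_call_rates(genotypes: GenotypeMatrix) -> pd.Series:
    mask = genotypes.call_mask()
    rates = mask.mean(axis=0) if mask.size else np.zeros(len(genotypes.markers))
    return pd.Series(rates, index=genotypes.markers, name="call_rate")


def sample_call_rates(genotypes: GenotypeMatrix) -> pd.Series:
    mask = genotypes.call_mask()
    rates = mask.mean(axis=1) if mask.size else np.zeros(len(genotypes.samples))
    return pd.Series(rates, index=genotypes.samples, name="call_rate")


def filter_by_call_rate(
    genotypes: GenotypeMatrix,
    marker_min: float = 0.90,
    sample_min: float = 0.96,
    per_platform_sample_rates: Mapping[str, pd.Series] | None = None,
) -> tuple[GenotypeMatrix, dict]:
    """Remove low-call-rate markers, then keep only high-call-rate samples.

    Markers with call rate strictly below ``marker_min`` are removed (a
    marker at exactly the minimum is kept). A sample is retained only if its
    call rate is strictly above ``sample_min`` on every platform in
    ``per_platform_sample_rates`` (defaulting to this matrix's own rates);
    rates must be computed after HQC forcing. Raises if no sample survives.
    """
    m_rates = marker_call_rates(genotypes)
    keep_markers = [m for m in genotypes.markers if m_rates[m] >= marker_min]
    out = genotypes.subset_markers(keep_markers)

    if per_platform_sample_rates is None:
        per_platform_sample_rates = {"self": sample_call_rates(out)}
    keep_samples = []
    for s in out.samples:
        if all(float(r.get(s, 0.0)) > sample_min for r in per_platform_sample_rates.values()):
            keep_samples.append(s)
    if not keep_samples:
        raise ValueError("all samples removed by the call-rate filter")
    out = out.subset_samples(keep_samples)
    report = {
        "n_markers_removed": len(genotypes.markers) - len(keep_markers),
        "n_samples_removed": len(genotypes.samples) - len(keep_samples),
        "samples_retained": keep_samples,
        "marker_rates": m_rates,
    }
    return out, report


def run_hqc(
    genotypes: GenotypeMatrix,
    intensities: IntensityMatrix,
    annotation: MarkerAnnotation,
    platform: str = "",
    fixed_threshold: float | None = None,
    het_level: float = 0.01,
    het_significance: float | None = 0.01,
    bin_width: float = 0.1,
    marker_min: float = 0.90,
) -> tuple[GenotypeMatrix, HQCReport, HetIntensityCurve]:
    """Single-platform HQC chain: threshold -> forcing -> duplicates -> markers.

    The derived threshold uses the binomial-significance variant of
    :func:`find_intensity_threshold` by default. The sample-level filter
    needs both platforms' rates and is applied separately (see
    :func:`filter_samples_joint`).
    """
    curve = het_intensity_curve(genotypes, intensities, bin_width=bin_width)
    threshold = (
        float(fixed_threshold)
        if fixed_threshold is not None
        else find_intensity_threshold(
            curve, het_level=het_level, significance=het_significance
        )
    )
    out, report = apply_hqc(genotypes, intensities, threshold, platform=platform)
    out, removed = remove_duplicate_position_markers(annotation, out)
    report.n_duplicate_markers_removed = len(removed)
    m_rates = marker_call_rates(out)
    keep = [m for m in out.markers if m_rates[m] >= marker_min]
    report.n_markers_removed_call_rate = len(out.markers) - len(keep)
    out = out.subset_markers(keep)
    report.samples_retained = list(out.samples)
    return out, report, curve


def filter_samples_joint(
    geno_A: GenotypeMatrix,
    geno_B: GenotypeMatrix,
    sample_min: float = 0.96,
) -> tuple[GenotypeMatrix, GenotypeMatrix, list[str]]:
    """Keep samples called strictly above ``sample_min`` on both platforms."""
    rates = {"A": sample_call_rates(geno_A), "B": sample_call_rates(geno_B)}
    common = [s for s in geno_A.samples if s in set(geno_B.samples)]
    keep = [
        s
        for s in common
        if float(rates["A"][s]) > sample_min and float(rates["B"][s]) > sample_min
    ]
    if not keep:
        raise ValueError("all samples removed by the call-rate filter")
    return geno_A.subset_samples(keep), geno_B.subset_samples(keep), keep
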