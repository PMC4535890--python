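"""Two-platform duplicated-haploid dataset simulator with known ground truth.

A complete hydatidiform mole (CHM) carries a duplicated single-sperm haploid
genome, so every true genotype is homozygous and a haplotype can be read off
directly. The simulator emulates the statistical structure such a cohort
shows on two SNP-array platforms:

* block-structured LD among common SNPs (haplotype-pool copying model:
  each sample's block haplotype is drawn from a small ancestral pool, giving
  high within-block r-squared and near-zero between-block r-squared);
* planted deletion/gain intervals whose carriers get a platform-specific
  mean intensity shift plus Gaussian noise on a log2-ratio scale;
* spurious heterozygous calls concentrated inside carried deletions (the
  genotyping artifact that motivates haploid QC);
* partial marker-panel overlap between the platforms, strand flips on a
  subset of shared SNPs, intensity-only probes, duplicate-position probes,
  and per-call missingness.

The pool-copying model is deliberately simple: the pipeline only needs
tunable block LD, not realistic genealogies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import ceil
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (
    HET,
    HOM_A,
    HOM_B,
    NOCALL,
    GenomeMetadata,
    GenotypeMatrix,
    IntensityMatrix,
    MarkerAnnotation,
    ANNOTATION_COLUMNS,
    write_marker_annotation,
    write_matrix,
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
# allele pairs whose strands are distinguishable (not self-complementary)
_UNAMBIGUOUS_PAIRS = [("A", "G"), ("A", "C"), ("T", "C"), ("T", "G")]
_AMBIGUOUS_PAIRS = [("A", "T"), ("C", "G")]


@dataclass
class CNVSpec:
    """One planted copy-number interval (1-based closed, bp)."""

    chrom: str
    start: int
    end: int
    kind: str  # "loss" | "gain"
    carrier_fraction: float

    def __post_init__(self) -> None:
        if self.kind not in ("loss", "gain"):
            raise ValueError(f"CNV kind must be loss|gain, got {self.kind!r}")
        if self.end < self.start:
            raise ValueError("CNV end < start")
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction outside [0, 1]")


def _default_cnvs() -> list[CNVSpec]:
    # lengths span 50-250 kb so overlapped-segment sizes carry real variance
    return [
        CNVSpec("chr1", 300_000, 350_000, "loss", 0.30),
        CNVSpec("chr1", 900_000, 1_150_000, "gain", 0.20),
        CNVSpec("chr2", 200_000, 350_000, "loss", 0.25),
        CNVSpec("chr2", 1_000_000, 1_100_000, "gain", 0.10),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the simulator; ``seed`` is mandatory.

    Intensity shifts are on the log2-ratio scale. Loss shifts differ by
    platform (defaults -3 and -4) to mirror the platforms' distinct loss
    signatures; gains sit at log2(3/2) ~ 0.58, just above the conventional
    0.5 gain boundary.
    """

    seed: int
    n_samples: int = 84
    n_chromosomes: int = 2
    n_blocks: int = 24
    snps_per_block: int = 25
    block_span_bp: int = 50_000
    n_haplotypes_per_block: int = 6
    maf_floor: float = 0.05
    mutation_rate: float = 0.0
    cnv_spec: list[CNVSpec] = field(default_factory=_default_cnvs)
    noise_sd_A: float = 0.25
    noise_sd_B: float = 0.30
    loss_shift_A: float = -3.0
    loss_shift_B: float = -4.0
    gain_shift_A: float = 0.58
    gain_shift_B: float = 0.58
    false_het_rate_in_loss: float = 0.40
    baseline_het_rate: float = 0.002
    miscall_rate: float = 0.001
    baseline_nocall_rate: float = 0.005
    strand_flip_fraction: float = 0.20
    inject_ambiguous_fraction: float = 0.0
    duplicate_probe_count: int = 5
    shared_fraction: float = 0.60
    intensity_only_fraction: float = 0.15
    intensity_missing_rate: float = 0.002

    def __post_init__(self) -> None:
        self.cnv_spec = [
            c if isinstance(c, CNVSpec) else CNVSpec(**c) for c in self.cnv_spec
        ]
        probs = {
            "maf_floor": self.maf_floor,
            "mutation_rate": self.mutation_rate,
            "false_het_rate_in_loss": self.false_het_rate_in_loss,
            "baseline_het_rate": self.baseline_het_rate,
            "miscall_rate": self.miscall_rate,
            "baseline_nocall_rate": self.baseline_nocall_rate,
            "strand_flip_fraction": self.strand_flip_fraction,
            "inject_ambiguous_fraction": self.inject_ambiguous_fraction,
            "shared_fraction": self.shared_fraction,
            "intensity_only_fraction": self.intensity_only_fraction,
            "intensity_missing_rate": self.intensity_missing_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.loss_shift_A >= 0 or self.loss_shift_B >= 0:
            raise ValueError("loss shifts must be negative")
        if self.gain_shift_A <= 0 or self.gain_shift_B <= 0:
            raise ValueError("gain shifts must be positive")
        if self.n_haplotypes_per_block < 1:
            raise ValueError("n_haplotypes_per_block must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass
class SimulationTruth:
    """Ground truth for recovery tests.

    ``sites`` has one row per simulated SNP site: site_id, chrom, pos,
    ref/alt alleles on the simulated + strand, which platforms carry it,
    the platform marker ids, and whether the platform-B entry is
    strand-flipped. ``haplotypes`` is samples x sites over {0 (ref), 1 (alt)}.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    haplotypes: np.ndarray  # uint8 (n_samples, n_sites)
    true_cnvs: list[tuple[str, str, int, int, str]] = field(default_factory=list)
    # (sample_id, chrom, start, end, kind)
    flipped_marker_ids: set[str] = field(default_factory=set)
    duplicate_marker_ids: set[str] = field(default_factory=set)

    def cnvs_of(self, sample_id: str) -> list[tuple[str, int, int, str]]:
        return [
            (c, s, e, k) for sid, c, s, e, k in self.true_cnvs if sid == sample_id
        ]


@dataclass
class SimulatedDataset:
    """Bundle of everything one simulation run produces."""

    config: SimulationConfig
    genome: GenomeMetadata
    ann_A: MarkerAnnotation
    ann_B: MarkerAnnotation
    geno_A: GenotypeMatrix
    geno_B: GenotypeMatrix
    int_A: IntensityMatrix
    int_B: IntensityMatrix
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

_CHROM_MARGIN = 100_000
_CENTROMERE_HALF = 10_000


def genome_layout(config: SimulationConfig) -> tuple[GenomeMetadata, pd.DataFrame]:
    """Deterministic chromosome/block/marker layout for a config.

    Blocks alternate with equally long inter-block gaps, so between-block
    marker pairs are well separated; the centromere sits in the gap nearest
    the middle of each chromosome. Marker positions are evenly spaced inside
    each block. Returns the genome metadata and a site table (without
    alleles) of columns site_id, chrom, pos, block.
    """
    if config.n_blocks % config.n_chromosomes:
        raise ValueError("n_blocks must be divisible by n_chromosomes")
    per_chrom = config.n_blocks // config.n_chromosomes
    span = config.block_span_bp
    spacing = max(span // config.snps_per_block, 1)
    lengths: dict[str, int] = {}
    cents: dict[str, tuple[int, int]] = {}
    rows = []
    site_k = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        lengths[chrom] = _CHROM_MARGIN + per_chrom * 2 * span + _CHROM_MARGIN
        gap_mid = _CHROM_MARGIN + (per_chrom // 2) * 2 * span - span // 2
        cents[chrom] = (gap_mid - _CENTROMERE_HALF, gap_mid + _CENTROMERE_HALF)
        for b in range(per_chrom):
            block_start = _CHROM_MARGIN + b * 2 * span
            for i in range(config.snps_per_block):
                rows.append(
                    (f"site_{site_k}", chrom, block_start + i * spacing, c * per_chrom + b)
                )
                site_k += 1
    sites = pd.DataFrame(rows, columns=["site_id", "chrom", "pos", "block"])
    return GenomeMetadata(lengths, cents), sites


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, order-insensitive stream per stage
    return np.random.default_rng([int(config.seed), stream])


# ---------------------------------------------------------------------------
# stage 1: haplotypes and marker panels
# ---------------------------------------------------------------------------

def simulate_haplotypes(
    config: SimulationConfig,
) -> tuple[MarkerAnnotation, MarkerAnnotation, SimulationTruth]:
    """Draw sample haplotypes from per-block ancestral pools and build panels.

    Every SNP site gets an allele pair; a ``shared_fraction`` of sites lands
    on both platforms, the rest split evenly between platform-private
    panels. A ``strand_flip_fraction`` of shared unambiguous sites has its
    platform-B annotation complemented (the strand inconsistency the merge
    stage must undo); platform B also lists alleles in swapped order for a
    random half of its sites, exercising allele-label alignment.
    """
    rng = _rng(config, 0)
    genome, sites = genome_layout(config)
    n_sites = len(sites)
    n = config.n_samples
    K = config.n_haplotypes_per_block

    c_min = ceil(config.maf_floor * K)
    if config.maf_floor > 0 and (K < 2 or 2 * c_min > K):
        raise ValueError(
            f"maf_floor {config.maf_floor} unattainable with pool size {K}"
        )

    hap = np.empty((n, n_sites), dtype=np.uint8)
    for block, idx in sites.groupby("block").groups.items():
        idx = np.asarray(idx)
        m = len(idx)
        pool = np.zeros((K, m), dtype=np.uint8)
        if K >= 2 and config.maf_floor > 0:
            counts = rng.integers(c_min, K - c_min + 1, size=m)
        elif K >= 2:
            counts = rng.integers(1, K, size=m)
        else:
            counts = np.zeros(m, dtype=int)
        for j in range(m):
            carriers = rng.choice(K, size=int(counts[j]), replace=False)
            pool[carriers, j] = 1
        choice = rng.integers(0, K, size=n)
        hap[:, idx] = pool[choice, :]
    if config.mutation_rate > 0:
        flips = rng.random(hap.shape) < config.mutation_rate
        hap = np.where(flips, 1 - hap, hap).astype(np.uint8)

    # allele pairs
    n_amb = int(round(config.inject_ambiguous_fraction * n_sites))
    amb_mask = np.zeros(n_sites, dtype=bool)
    if n_amb:
        amb_mask[rng.choice(n_sites, size=n_amb, replace=False)] = True
    refs = np.empty(n_sites, dtype="<U1")
    alts = np.empty(n_sites, dtype="<U1")
    for j in range(n_sites):
        pair = _AMBIGUOUS_PAIRS[rng.integers(2)] if amb_mask[j] else _UNAMBIGUOUS_PAIRS[rng.integers(4)]
        if rng.random() < 0.5:
            pair = pair[::-1]
        refs[j], alts[j] = pair

    # platform membership
    u = rng.random(n_sites)
    half_private = (1.0 - config.shared_fraction) / 2.0
    on_a = u < config.shared_fraction + half_private
    on_b = (u < config.shared_fraction) | (u >= config.shared_fraction + half_private)
    shared = on_a & on_b

    # strand flips: only unambiguous shared sites by default
    flip_candidates = np.flatnonzero(shared & ~amb_mask)
    n_flip = int(round(config.strand_flip_fraction * len(flip_candidates)))
    flip_sites = np.zeros(n_sites, dtype=bool)
    if n_flip:
        flip_sites[rng.choice(flip_candidates, size=n_flip, replace=False)] = True
    # platform B lists alleles in swapped order for a random half of its sites
    b_swap = rng.random(n_sites) < 0.5

    sites = sites.copy()
    sites["ref"] = refs
    sites["alt"] = alts
    sites["on_a"] = on_a
    sites["on_b"] = on_b
    sites["flipped"] = flip_sites
    sites["b_swapped"] = b_swap & on_b
    sites["a_marker_id"] = np.where(on_a, "affy_" + sites.index.astype(str), "")
    sites["b_marker_id"] = np.where(on_b, "ilmn_" + sites.index.astype(str), "")

    ann_A = _build_annotation(config, genome, sites, rng, platform="A")
    ann_B = _build_annotation(config, genome, sites, rng, platform="B")

    flipped_ids = set(sites.loc[sites["flipped"], "b_marker_id"])
    truth = SimulationTruth(
        sample_ids=[f"CHM{i + 1:03d}" for i in range(n)],
        sites=sites,
        haplotypes=hap,
        flipped_marker_ids=flipped_ids,
    )
    _inject_duplicates(config, ann_B, truth, rng)
    return ann_A, ann_B, truth


def _build_annotation(
    config: SimulationConfig,
    genome: GenomeMetadata,
    sites: pd.DataFrame,
    rng: np.random.Generator,
    platform: str,
) -> MarkerAnnotation:
    if platform == "A":
        sub = sites[sites["on_a"]]
        ids = sub["a_marker_id"]
        a1, a2 = sub["ref"].to_numpy(), sub["alt"].to_numpy()
        prefix = "affy_cn"
    else:
        sub = sites[sites["on_b"]]
        ids = sub["b_marker_id"]
        a1 = sub["ref"].to_numpy().copy()
        a2 = sub["alt"].to_numpy().copy()
        flip = sub["flipped"].to_numpy()
        a1[flip] = [_COMPLEMENT[x] for x in a1[flip]]
        a2[flip] = [_COMPLEMENT[x] for x in a2[flip]]
        swap = sub["b_swapped"].to_numpy()
        a1[swap], a2[swap] = a2[swap].copy(), a1[swap].copy()
        prefix = "ilmn_cn"
    df = pd.DataFrame(
        {
            "marker_id": ids.to_numpy(),
            "chrom": sub["chrom"].to_numpy(),
            "pos": sub["pos"].to_numpy(),
            "allele_a": a1,
            "allele_b": a2,
            "probe_class": "snp",
        }
    )
    # intensity-only probes at uniform positions
    n_cn = int(round(config.intensity_only_fraction * len(df)))
    if n_cn:
        chroms = list(genome.chrom_lengths)
        pick = rng.integers(0, len(chroms), size=n_cn)
        rows = []
        for i, ci in enumerate(pick):
            chrom = chroms[ci]
            pos = int(rng.integers(1, genome.chrom_lengths[chrom] + 1))
            rows.append((f"{prefix}_{i}", chrom, pos, "", "", "intensity_only"))
        df = pd.concat(
            [df, pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)], ignore_index=True
        )
    from .io import _chrom_sort_key

    df["_ck"] = df["chrom"].map(_chrom_sort_key)
    df = df.sort_values(["_ck", "pos", "marker_id"], kind="mergesort").drop(columns="_ck")
    return MarkerAnnotation(df.reset_index(drop=True), platform)


def _inject_duplicates(
    config: SimulationConfig,
    ann_B: MarkerAnnotation,
    truth: SimulationTruth,
    rng: np.random.Generator,
) -> None:
    """Add duplicate-position SNP probes to platform B (same assay, new id)."""
    k = config.duplicate_probe_count
    if k == 0:
        return
    snp_rows = ann_B.df[ann_B.df["probe_class"] == "snp"]
    pick = snp_rows.iloc[rng.choice(len(snp_rows), size=min(k, len(snp_rows)), replace=False)]
    dup_rows = pick.copy()
    dup_rows["marker_id"] = [f"ilmn_dup_{i}" for i in range(len(dup_rows))]
    truth.duplicate_marker_ids = set(dup_rows["marker_id"]) | set(pick["marker_id"])
    truth.sites.attrs["dup_partner"] = dict(
        zip(dup_rows["marker_id"], pick["marker_id"])
    )
    from .io import _chrom_sort_key

    df = pd.concat([ann_B.df, dup_rows], ignore_index=True)
    df["_ck"] = df["chrom"].map(_chrom_sort_key)
    df = df.sort_values(["_ck", "pos", "marker_id"], kind="mergesort").drop(columns="_ck")
    ann_B.df = df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# stage 2: CNV carriers and intensities
# ---------------------------------------------------------------------------

def plant_cnvs_and_intensities(
    config: SimulationConfig,
    ann_A: MarkerAnnotation,
    ann_B: MarkerAnnotation,
    truth: SimulationTruth,
) -> tuple[IntensityMatrix, IntensityMatrix]:
    """Assign CNV carriers and draw per-marker relative signal intensities.

    Non-carrier markers are N(0, noise_sd); markers inside a carried CNV are
    shifted by the platform's loss/gain displacement. Overlapping planted
    CNVs of opposite kind in one sample are rejected.
    """
    rng = _rng(config, 1)
    genome, _ = genome_layout(config)
    n = config.n_samples
    samples = truth.sample_ids

    carrier_sets: list[np.ndarray] = []
    truth.true_cnvs = []
    for cnv in config.cnv_spec:
        if cnv.chrom not in genome.chrom_lengths or cnv.end > genome.chrom_lengths[cnv.chrom]:
            raise ValueError(f"planted CNV {cnv} outside the simulated genome")
        k = int(round(cnv.carrier_fraction * n))
        carriers = np.sort(rng.choice(n, size=k, replace=False))
        carrier_sets.append(carriers)
        for i in carriers:
            truth.true_cnvs.append((samples[i], cnv.chrom, cnv.start, cnv.end, cnv.kind))

    # reject same-sample overlapping CNVs of opposite kind
    by_sample: dict[str, list[tuple[str, int, int, str]]] = {}
    for sid, chrom, s, e, kind in truth.true_cnvs:
        for c2, s2, e2, k2 in by_sample.get(sid, []):
            if c2 == chrom and s <= e2 and s2 <= e and k2 != kind:
                raise ValueError(
                    f"sample {sid}: overlapping planted CNVs of opposite kind on {chrom}"
                )
        by_sample.setdefault(sid, []).append((chrom, s, e, kind))

    out = []
    for ann, noise_sd, loss_shift, gain_shift in (
        (ann_A, config.noise_sd_A, config.loss_shift_A, config.gain_shift_A),
        (ann_B, config.noise_sd_B, config.loss_shift_B, config.gain_shift_B),
    ):
        m = len(ann.df)
        values = rng.normal(0.0, noise_sd, size=(n, m))
        chrom_arr = ann.df["chrom"].to_numpy()
        pos_arr = ann.df["pos"].to_numpy()
        for cnv, carriers in zip(config.cnv_spec, carrier_sets):
            in_cnv = (chrom_arr == cnv.chrom) & (pos_arr >= cnv.start) & (pos_arr <= cnv.end)
            shift = loss_shift if cnv.kind == "loss" else gain_shift
            values[np.ix_(carriers, np.flatnonzero(in_cnv))] += shift
        if config.intensity_missing_rate > 0:
            miss = rng.random(values.shape) < config.intensity_missing_rate
            values[miss] = np.nan
        out.append(IntensityMatrix(list(samples), list(ann.df["marker_id"]), values))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# stage 3: genotype calls
# ---------------------------------------------------------------------------

def emit_genotype_calls(
    config: SimulationConfig,
    ann_A: MarkerAnnotation,
    ann_B: MarkerAnnotation,
    truth: SimulationTruth,
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Emit per-platform genotype calls from the true haplotypes.

    Outside CNVs the true homozygote is reported, corrupted at baseline
    rates (no-call, spurious het, opposite-homozygote miscall). Inside a
    carried loss a heterozygous call is emitted with probability
    ``false_het_rate_in_loss`` — the low-intensity het enrichment that
    haploid QC exploits. Duplicate platform-B probes copy their partner's
    calls (same underlying assay).
    """
    rng = _rng(config, 2)
    sites = truth.sites
    n = config.n_samples
    out = []
    for ann, id_col in ((ann_A, "a_marker_id"), (ann_B, "b_marker_id")):
        snp_df = ann.df[ann.df["probe_class"] == "snp"]
        dup_partner: dict[str, str] = sites.attrs.get("dup_partner", {})
        primary_ids = [m for m in snp_df["marker_id"] if m not in dup_partner]
        m = len(primary_ids)
        site_rows = sites.set_index(id_col).loc[primary_ids]
        col_of_site = {sid: j for j, sid in enumerate(sites["site_id"])}
        hap_col = np.array([col_of_site[s] for s in site_rows["site_id"]])
        ann_rows = ann.df.set_index("marker_id").loc[primary_ids]
        ref = site_rows["ref"].to_numpy().copy()
        alt = site_rows["alt"].to_numpy().copy()
        if id_col == "b_marker_id":
            flip = site_rows["flipped"].to_numpy()
            ref[flip] = [_COMPLEMENT[x] for x in ref[flip]]
            alt[flip] = [_COMPLEMENT[x] for x in alt[flip]]
        # code of the true allele relative to the marker's allele_a label
        code_ref = np.where(ann_rows["allele_a"].to_numpy() == ref, HOM_A, HOM_B).astype(np.int8)
        code_alt = np.where(ann_rows["allele_a"].to_numpy() == alt, HOM_A, HOM_B).astype(np.int8)
        bits = truth.haplotypes[:, hap_col]
        calls = np.where(bits == 0, code_ref[None, :], code_alt[None, :]).astype(np.int8)

        # in-loss mask per sample/marker
        chrom_arr = site_rows["chrom"].to_numpy()
        pos_arr = site_rows["pos"].to_numpy()
        in_loss = np.zeros((n, m), dtype=bool)
        sample_pos = {s: i for i, s in enumerate(truth.sample_ids)}
        for sid, chrom, s, e, kind in truth.true_cnvs:
            if kind != "loss":
                continue
            cols = (chrom_arr == chrom) & (pos_arr >= s) & (pos_arr <= e)
            in_loss[sample_pos[sid], cols] = True

        u = rng.random((n, m))
        p_nc = config.baseline_nocall_rate
        p_het = config.baseline_het_rate
        p_mis = config.miscall_rate
        base = calls.copy()
        calls = np.where(u < p_nc, NOCALL, calls)
        calls = np.where((u >= p_nc) & (u < p_nc + p_het), HET, calls)
        mis = (u >= p_nc + p_het) & (u < p_nc + p_het + p_mis)
        calls = np.where(mis, np.where(base == HOM_A, HOM_B, HOM_A), calls)
        # deletion artifact overrides baseline emission
        v = rng.random((n, m))
        calls = np.where(in_loss & (v < config.false_het_rate_in_loss), HET, calls)

        all_ids = list(snp_df["marker_id"])
        full = np.empty((n, len(all_ids)), dtype=np.int8)
        jmap = {mid: j for j, mid in enumerate(primary_ids)}
        for j, mid in enumerate(all_ids):
            src = dup_partner.get(mid, mid)
            full[:, j] = calls[:, jmap[src]]
        out.append(GenotypeMatrix(list(truth.sample_ids), all_ids, full))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# one-call convenience + writers
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run all three stages and bundle the results."""
    genome, _ = genome_layout(config)
    ann_A, ann_B, truth = simulate_haplotypes(config)
    int_A, int_B = plant_cnvs_and_intensities(config, ann_A, ann_B, truth)
    geno_A, geno_B = emit_genotype_calls(config, ann_A, ann_B, truth)
    return SimulatedDataset(config, genome, ann_A, ann_B, geno_A, geno_B, int_A, int_B, truth)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the pipeline's TSV dialects plus a truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation_A": outdir / "annotation_A.tsv",
        "annotation_B": outdir / "annotation_B.tsv",
        "genotypes_A": outdir / "genotypes_A.tsv",
        "genotypes_B": outdir / "genotypes_B.tsv",
        "intensities_A": outdir / "intensities_A.tsv",
        "intensities_B": outdir / "intensities_B.tsv",
        "genome": outdir / "genome.yaml",
        "truth_cnvs": outdir / "truth_cnvs.tsv",
        "truth_flips": outdir / "truth_flips.tsv",
    }
    write_marker_annotation(ds.ann_A, paths["annotation_A"])
    write_marker_annotation(ds.ann_B, paths["annotation_B"])
    write_matrix(ds.geno_A, paths["genotypes_A"])
    write_matrix(ds.geno_B, paths["genotypes_B"])
    write_matrix(ds.int_A, paths["intensities_A"])
    write_matrix(ds.int_B, paths["intensities_B"])
    ds.genome.to_yaml(paths["genome"])
    pd.DataFrame(
        ds.truth.true_cnvs, columns=["sample_id", "chrom", "start", "end", "kind"]
    ).to_csv(paths["truth_cnvs"], sep="\t", index=False)
    pd.DataFrame({"marker_id": sorted(ds.truth.flipped_marker_ids)}).to_csv(
        paths["truth_flips"], sep="\t", index=False
    )
    return paths
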