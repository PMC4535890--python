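"""Pairwise haploid r-squared, greedy LD-bin construction and tagSNP choice.

Haploid calls are phased haplotypes, so linkage disequilibrium between two
SNPs is computed directly from joint haplotype counts: with p and q the
allele-A frequencies at the two markers and f the joint (A, A) frequency,
D = f - p*q and r2 = D^2 / (p(1-p) q(1-q)). Common SNPs (MAF >= 5% by
default) within a 300 kb window are paired; bins collect SNPs that tag each
other at r2 >= 0.80 via a greedy maximal-neighborhood rule in the style of
ldSelect, and each bin's tagSNP is the member with the highest average r2
to the rest ("avesnp" criterion). SNPs left without proxies form
single-SNP bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import HOM_A, HOM_B, GenotypeMatrix, MarkerAnnotation


@dataclass
class LDBin:
    members: list[str]
    tag: str
    tag_avg_r2: float

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


def allele_indicator(geno: GenotypeMatrix) -> np.ndarray:
    """1.0 where the haploid call is allele A, 0.0 for allele B, NaN otherwise."""
    z = np.full(geno.calls.shape, np.nan)
    z[geno.calls == HOM_A] = 1.0
    z[geno.calls == HOM_B] = 0.0
    return z


def minor_allele_frequencies(geno: GenotypeMatrix) -> pd.Series:
    z = allele_indicator(geno)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(z, axis=0)
    maf = np.minimum(p, 1.0 - p)
    return pd.Series(maf, index=geno.markers, name="maf")


def common_snp_ids(geno: GenotypeMatrix, maf_min: float = 0.05) -> list[str]:
    maf = minor_allele_frequencies(geno)
    return [m for m in geno.markers if maf[m] >= maf_min]


def haploid_r2(zi: np.ndarray, zj: np.ndarray) -> float:
    """r2 from two 0/1 allele-indicator vectors over jointly called samples.

    Returns NaN when either marker is monomorphic among the jointly called
    samples (r2 undefined).
    """
    valid = ~np.isnan(zi) & ~np.isnan(zj)
    n = int(valid.sum())
    if n == 0:
        return np.nan
    a, b = zi[valid], zj[valid]
    p = a.mean()
    q = b.mean()
    denom = p * (1 - p) * q * (1 - q)
    if denom == 0:
        return np.nan
    f = (a * b).mean()
    d = f - p * q
    return float(d * d / denom)


def pairwise_r2(
    geno: GenotypeMatrix,
    annotation: MarkerAnnotation,
    maf_min: float = 0.05,
    window_bp: int = 300_000,
) -> pd.DataFrame:
    """All qualifying LD pairs among common SNPs.

    Pairs must lie on one chromosome at most ``window_bp`` apart. Pairs
    where either marker is monomorphic among the jointly called samples are
    skipped. Returns columns marker_i, marker_j, chrom, distance_bp, r2,
    with marker_i the smaller genomic position.
    """
    common = set(common_snp_ids(geno, maf_min=maf_min))
    pos_tbl = annotation.positions()
    keep = [m for m in geno.markers if m in common and m in pos_tbl.index]
    sub = geno.subset_markers(keep)
    z = allele_indicator(sub)
    info = pos_tbl.loc[keep]
    rows = []
    for chrom, grp in info.groupby("chrom", sort=False):
        order = np.argsort(grp["pos"].to_numpy(), kind="mergesort")
        ids = grp.index.to_numpy()[order]
        pos = grp["pos"].to_numpy()[order]
        cols = [sub.marker_index()[m] for m in ids]
        zc = z[:, cols]
        m = len(ids)
        for i in range(m):
            j = i + 1
            while j < m and pos[j] - pos[i] <= window_bp:
                r2 = haploid_r2(zc[:, i], zc[:, j])
                if not np.isnan(r2):
                    rows.append((ids[i], ids[j], chrom, int(pos[j] - pos[i]), r2))
                j += 1
    return pd.DataFrame(
        rows, columns=["marker_i", "marker_j", "chrom", "distance_bp", "r2"]
    )


def _pair_lookup(pairs: pd.DataFrame) -> dict[tuple[str, str], float]:
    lut: dict[tuple[str, str], float] = {}
    for mi, mj, r2 in zip(pairs["marker_i"], pairs["marker_j"], pairs["r2"]):
        lut[(mi, mj)] = r2
        lut[(mj, mi)] = r2
    return lut


def greedy_bins(
    pairs: pd.DataFrame,
    markers: pd.DataFrame,
    r2_threshold: float = 0.80,
) -> list[LDBin]:
    """Greedy maximal LD binning.

    ``markers`` needs columns marker_id, chrom, pos covering every common
    SNP (binned or not). Repeatedly the unbinned marker with the most
    unbinned neighbors at ``r2 >= r2_threshold`` seeds a bin consisting of
    itself plus those neighbors (ties broken by smaller genomic position,
    then marker id); all bin members leave the pool. Markers left without
    neighbors become single-SNP bins. Each bin's tag is chosen by
    :func:`select_tag`.
    """
    pos_of = dict(zip(markers["marker_id"], markers["pos"]))
    neighbors: dict[str, set[str]] = {m: set() for m in markers["marker_id"]}
    strong = pairs[pairs["r2"] >= r2_threshold]
    for mi, mj in zip(strong["marker_i"], strong["marker_j"]):
        if mi in neighbors and mj in neighbors:
            neighbors[mi].add(mj)
            neighbors[mj].add(mi)
    lut = _pair_lookup(pairs)

    unbinned = set(neighbors)
    bins: list[LDBin] = []
    while True:
        best = None
        for m in unbinned:
            k = len(neighbors[m] & unbinned)
            if k == 0:
                continue
            key = (-k, pos_of[m], m)
            if best is None or key < best[0]:
                best = (key, m)
        if best is None:
            break
        seed = best[1]
        members = sorted({seed} | (neighbors[seed] & unbinned), key=lambda m: (pos_of[m], m))
        unbinned -= set(members)
        tag, avg = select_tag(members, lut, pos_of)
        bins.append(LDBin(members, tag, avg))
    for m in sorted(unbinned, key=lambda m: (pos_of[m], m)):
        bins.append(LDBin([m], m, 1.0))
    return bins


def select_tag(
    members: list[str],
    pair_lookup: dict[tuple[str, str], float],
    pos_of: dict[str, int],
) -> tuple[str, float]:
    """Pick the member with maximal average r2 to the other members.

    Missing pairs (beyond the pairing window) count as r2 = 0 in the
    average; ties go to the smaller genomic position, then marker id. A
    singleton tags itself with average 1.
    """
    if len(members) == 1:
        return members[0], 1.0
    best: tuple[float, int, str] | None = None
    best_m = members[0]
    for m in members:
        avg = float(
            np.mean([pair_lookup.get((m, o), 0.0) for o in members if o != m])
        )
        key = (-avg, pos_of[m], m)
        if best is None or key < best:
            best = key
            best_m = m
    assert best is not None
    return best_m, -best[0]


def bin_summary(bins: list[LDBin]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_id": range(len(bins)),
            "n_members": [len(b.members) for b in bins],
            "tag": [b.tag for b in bins],
            "tag_avg_r2": [b.tag_avg_r2 for b in bins],
            "members": [",".join(b.members) for b in bins],
        }
    )


def singleton_fraction(bins: list[LDBin]) -> float:
    """Fraction of common SNPs without proxies = singleton bins / common SNPs."""
    n_snps = sum(len(b.members) for b in bins)
    if n_snps == 0:
        return float("nan")
    return sum(1 for b in bins if b.is_singleton) / n_snps


def proxyless_percent(n_singleton_bins: int, n_common_snps: int) -> float:
    """Percent of common SNPs without proxies (each singleton bin is one SNP)."""
    if n_common_snps <= 0:
        raise ValueError("n_common_snps must be positive")
    return 100.0 * n_singleton_bins / n_common_snps
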