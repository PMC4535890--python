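"""Cross-platform strand harmonization and genotype merging.

The two array platforms annotate SNP alleles on whichever strand their
probe designs use, so the same SNP can appear as A/G on one platform and
T/C on the other. Shared SNPs are matched by (chrom, pos); platform B's
annotation is complemented ("flipped") where that reconciles the allele
sets. Self-complementary A/T and C/G SNPs cannot be oriented from alleles
alone and are resolved by allele-frequency matching, or excluded when the
frequencies cannot discriminate. After harmonization the per-sample calls
are merged; the rare discordant pairs are forced to no-call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import HOM_A, HOM_B, HET, NOCALL, GenotypeMatrix, MarkerAnnotation, _chrom_sort_key

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _comp(x: str) -> str:
    return _COMPLEMENT[x]


@dataclass
class StrandReconciliation:
    """Outcome of matching and orienting shared SNPs."""

    pairs: pd.DataFrame  # chrom, pos, marker_a, marker_b, status
    flip_set: set[str] = field(default_factory=set)  # platform-B marker ids
    ambiguous_set: set[str] = field(default_factory=set)
    irreconcilable_set: set[str] = field(default_factory=set)
    harmonized_ann_B: MarkerAnnotation | None = None


@dataclass
class MergeReport:
    n_shared_snps: int = 0
    n_flipped: int = 0
    n_ambiguous_excluded: int = 0
    n_irreconcilable_excluded: int = 0
    n_discordant_forced: int = 0
    n_compared: int = 0
    discordance_fraction: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: [v] for k, v in self.__dict__.items()})


def _allele_freq(geno: GenotypeMatrix, marker_id: str, allele_a_nuc: str,
                 allele_b_nuc: str, query: str) -> tuple[float, int]:
    """Frequency of ``query`` nucleotide among called haploid genotypes."""
    j = geno.marker_index()[marker_id]
    col = geno.calls[:, j]
    called = (col == HOM_A) | (col == HOM_B)
    n = int(called.sum())
    if n == 0:
        return np.nan, 0
    n_a = int((col[called] == HOM_A).sum())
    if query == allele_a_nuc:
        return n_a / n, n
    if query == allele_b_nuc:
        return (n - n_a) / n, n
    return 0.0, n


def reconcile_strands(
    ann_A: MarkerAnnotation,
    ann_B: MarkerAnnotation,
    geno_A: GenotypeMatrix | None = None,
    geno_B: GenotypeMatrix | None = None,
    freq_tolerance: float = 0.1,
    rare_maf: float = 0.05,
) -> StrandReconciliation:
    """Orient platform B's annotation onto platform A's strand frame.

    Shared SNPs are matched by (chrom, pos). Allele-set comparison decides
    plain cases (match -> keep; complement matches -> flip). A/T and C/G
    SNPs are oriented by minimizing the allele-frequency difference between
    platforms, but excluded when both orientations agree within
    ``freq_tolerance`` or when the SNP's MAF is below ``rare_maf`` on either
    platform (frequency matching is then uninformative). Irreconcilable
    allele sets are excluded, never fatal.
    """
    a_snp = ann_A.df[ann_A.df["probe_class"] == "snp"]
    b_snp = ann_B.df[ann_B.df["probe_class"] == "snp"]
    # positions duplicated within a platform cannot be matched unambiguously
    a_snp = a_snp[~a_snp.duplicated(subset=["chrom", "pos"], keep=False)]
    b_snp = b_snp[~b_snp.duplicated(subset=["chrom", "pos"], keep=False)]
    merged = a_snp.merge(
        b_snp, on=["chrom", "pos"], suffixes=("_a", "_b"), how="inner"
    )

    flip_set: set[str] = set()
    ambiguous: set[str] = set()
    irreconcilable: set[str] = set()
    statuses = []
    for row in merged.itertuples(index=False):
        set_a = frozenset((row.allele_a_a, row.allele_b_a))
        set_b = frozenset((row.allele_a_b, row.allele_b_b))
        comp_b = frozenset(_comp(x) for x in set_b)
        is_ambiguous = set_a == frozenset(_comp(x) for x in set_a)
        if is_ambiguous:
            status = _resolve_ambiguous(
                row, geno_A, geno_B, freq_tolerance, rare_maf
            )
            if status == "flip":
                flip_set.add(row.marker_id_b)
            elif status == "excluded":
                ambiguous.add(row.marker_id_b)
        elif set_b == set_a:
            status = "keep"
        elif comp_b == set_a:
            status = "flip"
            flip_set.add(row.marker_id_b)
        else:
            status = "irreconcilable"
            irreconcilable.add(row.marker_id_b)
        statuses.append(status)

    pairs = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "marker_a": merged["marker_id_a"],
            "marker_b": merged["marker_id_b"],
            "status": statuses,
        }
    )
    harmonized = ann_B.df.copy()
    in_flip = harmonized["marker_id"].isin(flip_set)
    harmonized.loc[in_flip, "allele_a"] = harmonized.loc[in_flip, "allele_a"].map(_COMPLEMENT)
    harmonized.loc[in_flip, "allele_b"] = harmonized.loc[in_flip, "allele_b"].map(_COMPLEMENT)
    return StrandReconciliation(
        pairs=pairs,
        flip_set=flip_set,
        ambiguous_set=ambiguous,
        irreconcilable_set=irreconcilable,
        harmonized_ann_B=MarkerAnnotation(harmonized, ann_B.platform),
    )


def _resolve_ambiguous(row, geno_A, geno_B, tol: float, rare_maf: float) -> str:
    """Frequency-matching orientation for a self-complementary SNP."""
    if geno_A is None or geno_B is None:
        return "excluded"
    if row.marker_id_a not in geno_A.marker_index() or row.marker_id_b not in geno_B.marker_index():
        return "excluded"
    # frequency of platform A's allele_a nucleotide on each platform
    f_a, n_a = _allele_freq(geno_A, row.marker_id_a, row.allele_a_a, row.allele_b_a, row.allele_a_a)
    f_b, n_b = _allele_freq(geno_B, row.marker_id_b, row.allele_a_b, row.allele_b_b, row.allele_a_a)
    if n_a == 0 or n_b == 0 or np.isnan(f_a) or np.isnan(f_b):
        return "excluded"
    maf_a = min(f_a, 1.0 - f_a)
    maf_b = min(f_b, 1.0 - f_b)
    if maf_a < rare_maf or maf_b < rare_maf:
        return "excluded"
    d_asis = abs(f_a - f_b)
    d_flip = abs(f_a - (1.0 - f_b))  # complementing swaps the allele pair
    if d_asis <= tol and d_flip <= tol:
        return "excluded"
    return "flip" if d_flip < d_asis else "keep"


def merge_calls(
    geno_A: GenotypeMatrix,
    geno_B: GenotypeMatrix,
    ann_A: MarkerAnnotation,
    reconciliation: StrandReconciliation,
) -> tuple[GenotypeMatrix, MarkerAnnotation, MergeReport]:
    """Merge the two platforms' calls into one haploid call matrix.

    For shared, harmonized SNPs each sample's pair of calls combines as:
    both missing -> missing; one call -> that call; equal calls -> that
    call; unequal calls -> no-call, counted discordant. Excluded shared
    SNPs (ambiguous or irreconcilable) are dropped from the merged set;
    platform-private markers pass through unchanged. The discordance
    fraction is over pairs where both platforms made a call.
    """
    if set(geno_A.samples) != set(geno_B.samples):
        raise ValueError("sample sets differ between platforms; filter upstream")
    geno_B = geno_B.subset_samples(list(geno_A.samples))
    ann_B = reconciliation.harmonized_ann_B
    assert ann_B is not None

    pairs = reconciliation.pairs
    usable = pairs[pairs["status"].isin(["keep", "flip"])]
    excluded_b = reconciliation.ambiguous_set | reconciliation.irreconcilable_set
    excluded_a = set(pairs.loc[pairs["status"].isin(["excluded", "irreconcilable"]), "marker_a"])

    a_ann = ann_A.df.set_index("marker_id")
    b_ann = ann_B.df.set_index("marker_id")
    a_idx = geno_A.marker_index()
    b_idx = geno_B.marker_index()

    report = MergeReport(
        n_shared_snps=len(pairs),
        n_flipped=len(reconciliation.flip_set),
        n_ambiguous_excluded=len(reconciliation.ambiguous_set),
        n_irreconcilable_excluded=len(reconciliation.irreconcilable_set),
    )

    merged_cols: list[np.ndarray] = []
    merged_ids: list[str] = []
    ann_rows: list[tuple] = []
    n_disc = 0
    n_comp = 0

    shared_b_ids = set(usable["marker_b"])
    shared_a_ids = set(usable["marker_a"])
    for row in usable.itertuples(index=False):
        if row.marker_a not in a_idx or row.marker_b not in b_idx:
            # dropped by upstream QC on one platform: pass the survivor through
            continue
        a_col = geno_A.calls[:, a_idx[row.marker_a]]
        b_col = geno_B.calls[:, b_idx[row.marker_b]].copy()
        # align B's allele labels to A's after harmonization
        aa = a_ann.loc[row.marker_a]
        bb = b_ann.loc[row.marker_b]
        if (bb["allele_a"], bb["allele_b"]) == (aa["allele_b"], aa["allele_a"]):
            swap = b_col == HOM_A
            b_col[b_col == HOM_B] = HOM_A
            b_col[swap] = HOM_B
        elif (bb["allele_a"], bb["allele_b"]) != (aa["allele_a"], aa["allele_b"]):
            continue  # should not happen post-harmonization; drop defensively
        both = (a_col != NOCALL) & (b_col != NOCALL)
        disagree = both & (a_col != b_col)
        n_comp += int(both.sum())
        n_disc += int(disagree.sum())
        out = np.where(a_col != NOCALL, a_col, b_col).astype(np.int8)
        out[disagree] = NOCALL
        merged_cols.append(out)
        merged_ids.append(row.marker_a)
        ann_rows.append(
            (row.marker_a, aa["chrom"], aa["pos"], aa["allele_a"], aa["allele_b"], "snp")
        )

    # platform-private SNPs pass through
    for mid in geno_A.markers:
        if mid in shared_a_ids or mid in excluded_a or mid not in a_ann.index:
            continue
        r = a_ann.loc[mid]
        if r["probe_class"] != "snp":
            continue
        merged_cols.append(geno_A.calls[:, a_idx[mid]])
        merged_ids.append(mid)
        ann_rows.append((mid, r["chrom"], r["pos"], r["allele_a"], r["allele_b"], "snp"))
    for mid in geno_B.markers:
        if mid in shared_b_ids or mid in excluded_b or mid not in b_ann.index:
            continue
        r = b_ann.loc[mid]
        if r["probe_class"] != "snp":
            continue
        merged_cols.append(geno_B.calls[:, b_idx[mid]])
        merged_ids.append(mid)
        ann_rows.append((mid, r["chrom"], r["pos"], r["allele_a"], r["allele_b"], "snp"))

    ann_df = pd.DataFrame(
        ann_rows,
        columns=["marker_id", "chrom", "pos", "allele_a", "allele_b", "probe_class"],
    )
    ann_df["_ck"] = ann_df["chrom"].map(_chrom_sort_key)
    ann_df = ann_df.sort_values(["_ck", "pos", "marker_id"], kind="mergesort").drop(columns="_ck")
    order = {mid: k for k, mid in enumerate(merged_ids)}
    sorted_ids = list(ann_df["marker_id"])
    calls = np.column_stack([merged_cols[order[mid]] for mid in sorted_ids]) if sorted_ids else np.empty((len(geno_A.samples), 0), dtype=np.int8)
    merged = GenotypeMatrix(list(geno_A.samples), sorted_ids, calls.astype(np.int8))

    report.n_discordant_forced = n_disc
    report.n_compared = n_comp
    report.discordance_fraction = (n_disc / n_comp) if n_comp else 0.0
    return merged, MarkerAnnotation(ann_df.reset_index(drop=True), "merged"), report
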