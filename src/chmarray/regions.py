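"""Cross-platform CNV-segment concordance and merging into CNV regions.

Two platforms segment the same genomes independently; a segment is deemed
concordant when at least one bp of it (by default) overlaps a CNV segment
of the same sample on the other platform. Overlapped pairs whose states
disagree (gain on one platform, loss on the other) are tallied separately
— a known artifact of platform-specific reference intensities. CNV regions
(CNVRs) are the union of all CNV segments across samples and platforms,
ignoring state; the fraction of the genome they occupy is reported against
the genome metadata.

All interval arithmetic is on 1-based closed coordinates:
overlap = min(end_a, end_b) - max(start_a, start_b) + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomeMetadata


@dataclass
class ConcordanceReport:
    n_segments_A: int
    n_segments_B: int
    n_overlapping_A: int
    n_overlapping_B: int
    n_opposite_state_overlaps: int
    pairs: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_segments_A": [self.n_segments_A],
                "n_segments_B": [self.n_segments_B],
                "n_overlapping_A": [self.n_overlapping_A],
                "n_overlapping_B": [self.n_overlapping_B],
                "n_opposite_state_overlaps": [self.n_opposite_state_overlaps],
            }
        )


def _overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return min(a_end, b_end) - max(a_start, b_start) + 1


def intersect_platforms(
    segments_A: pd.DataFrame,
    segments_B: pd.DataFrame,
    min_overlap_bp: int = 1,
) -> ConcordanceReport:
    """Per-sample overlap of CNV segments between the two platforms.

    A segment counts as overlapping when >= ``min_overlap_bp`` of it
    intersects any CNV segment of the same sample on the other platform.
    Every qualifying pair is recorded with both lengths (for the size
    correlation); pairs of opposite state are counted separately.
    """
    pair_rows = []
    overlapping_a: set[int] = set()
    overlapping_b: set[int] = set()
    b_groups = {
        key: grp for key, grp in segments_B.groupby(["sample_id", "chrom"], sort=False)
    }
    for key, grp_a in segments_A.groupby(["sample_id", "chrom"], sort=False):
        grp_b = b_groups.get(key)
        if grp_b is None:
            continue
        for ia, a in grp_a.iterrows():
            for ib, b in grp_b.iterrows():
                ov = _overlap_bp(a["start"], a["end"], b["start"], b["end"])
                if ov >= min_overlap_bp:
                    overlapping_a.add(ia)
                    overlapping_b.add(ib)
                    pair_rows.append(
                        (
                            key[0],
                            key[1],
                            a["start"],
                            a["end"],
                            a["state"],
                            a["end"] - a["start"] + 1,
                            b["start"],
                            b["end"],
                            b["state"],
                            b["end"] - b["start"] + 1,
                            ov,
                        )
                    )
    pairs = pd.DataFrame(
        pair_rows,
        columns=[
            "sample_id",
            "chrom",
            "a_start",
            "a_end",
            "a_state",
            "a_length",
            "b_start",
            "b_end",
            "b_state",
            "b_length",
            "overlap_bp",
        ],
    )
    n_opposite = int((pairs["a_state"] != pairs["b_state"]).sum()) if len(pairs) else 0
    return ConcordanceReport(
        n_segments_A=len(segments_A),
        n_segments_B=len(segments_B),
        n_overlapping_A=len(overlapping_a),
        n_overlapping_B=len(overlapping_b),
        n_opposite_state_overlaps=n_opposite,
        pairs=pairs,
    )


def size_correlation(
    report: ConcordanceReport, min_length_bp: int = 10_000
) -> tuple[float, int]:
    """Pearson correlation of log10 lengths over long overlapped pairs.

    Only pairs where both segments exceed ``min_length_bp`` qualify.
    Returns ``(correlation, n_pairs)``; the correlation is NaN when fewer
    than 3 pairs qualify (undefined).
    """
    pairs = report.pairs
    if pairs is None or len(pairs) == 0:
        return float("nan"), 0
    q = pairs[(pairs["a_length"] > min_length_bp) & (pairs["b_length"] > min_length_bp)]
    if len(q) < 3:
        return float("nan"), len(q)
    la = np.log10(q["a_length"].to_numpy(dtype=float))
    lb = np.log10(q["b_length"].to_numpy(dtype=float))
    if la.std() == 0 or lb.std() == 0:
        # degenerate but defined case: identical lengths correlate perfectly
        return (1.0, len(q)) if np.allclose(la, la[0]) and np.allclose(lb, lb[0]) else (float("nan"), len(q))
    return float(np.corrcoef(la, lb)[0, 1]), len(q)


def merge_to_regions(
    all_cnv_segments: pd.DataFrame,
    genome: GenomeMetadata,
    merge_bookended: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Union CNV segments across samples and platforms into CNV regions.

    Gains and losses are not discriminated. Overlapping intervals always
    merge; bookended intervals (one ends at bp x, the next starts at
    x + 1) merge too by default — marker-span boundaries make 1-bp gaps
    artifacts of probe spacing — and ``merge_bookended=False`` restores
    strict-overlap merging. Returns the region table and the fraction of
    the genome the regions occupy.
    """
    cols = ["chrom", "start", "end", "n_contributing", "contributing"]
    if len(all_cnv_segments) == 0:
        return pd.DataFrame(columns=cols), 0.0
    for row in all_cnv_segments.itertuples(index=False):
        length = genome.chrom_lengths.get(row.chrom)
        if length is None or row.end > length or row.start < 1:
            raise ValueError(
                f"segment [{row.start}, {row.end}] outside chromosome {row.chrom}"
            )
    gap = 1 if merge_bookended else 0
    out_rows = []
    seg = all_cnv_segments.sort_values(["chrom", "start", "end"], kind="mergesort")
    for chrom, grp in seg.groupby("chrom", sort=False):
        cur_start = cur_end = None
        contrib: list[tuple] = []
        for row in grp.itertuples(index=False):
            tag = (
                getattr(row, "sample_id", ""),
                getattr(row, "platform", ""),
                getattr(row, "state", ""),
            )
            if cur_start is None:
                cur_start, cur_end, contrib = row.start, row.end, [tag]
            elif row.start <= cur_end + gap:
                cur_end = max(cur_end, row.end)
                contrib.append(tag)
            else:
                out_rows.append((chrom, cur_start, cur_end, len(contrib), contrib))
                cur_start, cur_end, contrib = row.start, row.end, [tag]
        if cur_start is not None:
            out_rows.append((chrom, cur_start, cur_end, len(contrib), contrib))
    regions = pd.DataFrame(out_rows, columns=cols)
    total = int((regions["end"] - regions["start"] + 1).sum())
    return regions, total / genome.total_bp


def per_genome_rate(n_segments: int, n_samples: int) -> float:
    """Cohort-wide segment count expressed as segments per genome."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return n_segments / n_samples


def segment_count_summary(segments: pd.DataFrame, n_samples: int) -> pd.DataFrame:
    """Loss/gain counts and per-genome rates per platform (cohort table)."""
    rows = []
    for platform, grp in segments.groupby("platform", sort=False):
        for state in ("loss", "gain"):
            n = int((grp["state"] == state).sum())
            rows.append((platform, state, n, per_genome_rate(n, n_samples)))
    return pd.DataFrame(rows, columns=["platform", "state", "n_segments", "per_genome"])


def regions_to_bed_intervals(regions: pd.DataFrame) -> list[tuple]:
    """(chrom, start, end, name, score) tuples for :func:`chmarray.io.write_bed`."""
    return [
        (r.chrom, int(r.start), int(r.end), f"CNVR_{i}", int(r.n_contributing))
        for i, r in enumerate(regions.itertuples(index=False))
    ]
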