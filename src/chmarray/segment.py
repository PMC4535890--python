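"""Circular binary segmentation (CBS) of relative signal intensity, loss
threshold derivation, and segment classification.

With genome-wide homozygosity ruling out B-allele-frequency evidence, the
relative signal intensity (log2R / logRR) is the only copy-number signal.
Each sample x platform x chromosome profile is segmented by CBS: over every
arc of the circularly-joined profile the arc-vs-complement mean difference
is scored with a t-like statistic, the best-scoring arc is tested against a
permutation null, and accepted change-points recurse. Segment means are
then histogrammed genome-wide; the valley between the deletion mode (well
below zero) and the neutral mode (near zero) in the bp-weighted histogram
yields the platform's loss threshold, while the gain threshold is the
conventional 0.5 (not resolvable from the histogram). Fixed overrides
(-1 / -2 / 0.5) are supported throughout.

Permutation testing is sequential: permutations run in chunks and stop as
soon as the decision at level alpha is settled — rejection is exact once
the exceedance count passes ``alpha * n_perm``; acceptance stops early when
the Clopper-Pearson 99.9% upper bound on the p-value falls below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as _beta

from .io import GenomeMetadata, IntensityMatrix, MarkerAnnotation

SEGMENT_COLUMNS = [
    "sample_id",
    "platform",
    "chrom",
    "start",
    "end",
    "n_markers",
    "mean_intensity",
    "state",
]


# ---------------------------------------------------------------------------
# split statistic
# ---------------------------------------------------------------------------

def max_arc_split(x: np.ndarray, min_width: int = 2) -> tuple[float, int, int]:
    """Best circular split of ``x``: maximal arc-vs-complement statistic.

    Considers every arc ``x[i:j]`` with both the arc and its complement at
    least ``min_width`` long and returns ``(stat, i, j)`` where the
    statistic is |mean(arc) - mean(complement)| / sqrt(1/k + 1/(n-k)) —
    the two-sample z numerator with the common-variance factor dropped
    (it is permutation-invariant, so it cancels in the permutation test).
    Returns ``(0.0, 0, n)`` when no admissible split exists.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n < 2 * min_width:
        return 0.0, 0, n
    s = np.concatenate(([0.0], np.cumsum(x)))
    tot = s[-1]
    best = (-1.0, 0, n)
    for k in range(min_width, n - min_width + 1):
        w = s[k:] - s[: n - k + 1]  # arc sums for arcs [i, i+k), i = 0..n-k
        stat = np.abs(w / k - (tot - w) / (n - k)) / np.sqrt(1.0 / k + 1.0 / (n - k))
        i = int(np.argmax(stat))
        if stat[i] > best[0]:
            best = (float(stat[i]), i, i + k)
    return best


def _perm_max_stats(
    x: np.ndarray, min_width: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Max split statistic for ``n_perm`` random permutations of ``x``."""
    n = len(x)
    mat = np.tile(x, (n_perm, 1))
    mat = rng.permuted(mat, axis=1)
    s = np.concatenate(
        (np.zeros((n_perm, 1)), np.cumsum(mat, axis=1)), axis=1
    )
    tot = s[:, -1][:, None]
    best = np.zeros(n_perm)
    for k in range(min_width, n - min_width + 1):
        w = s[:, k:] - s[:, : n - k + 1]
        stat = np.abs(w / k - (tot - w) / (n - k)) / np.sqrt(1.0 / k + 1.0 / (n - k))
        np.maximum(best, stat.max(axis=1), out=best)
    return best


def _split_significant(
    x: np.ndarray,
    observed: float,
    alpha: float,
    n_perm: int,
    min_width: int,
    rng: np.random.Generator,
    chunk: int = 500,
) -> bool:
    """Sequential permutation decision: is the observed split significant?"""
    if observed <= 0:
        return False
    reject_at = int(np.floor(alpha * n_perm))  # exceedances beyond this -> p > alpha
    done = 0
    exceed = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        stats = _perm_max_stats(x, min_width, m, rng)
        exceed += int((stats >= observed).sum())
        done += m
        if exceed > reject_at:
            return False
        # Clopper-Pearson 99.9% upper bound on the true exceedance rate
        upper = _beta.ppf(0.999, exceed + 1, done - exceed) if done > exceed else 1.0
        if done >= 1000 and upper <= alpha:
            return True
    return exceed / n_perm <= alpha


# ---------------------------------------------------------------------------
# recursive CBS
# ---------------------------------------------------------------------------

def cbs_segment(
    values: np.ndarray,
    positions: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    min_width: int = 2,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Segment one ordered intensity profile.

    ``values`` and ``positions`` describe one sample on one chromosome in
    genomic order; missing values are dropped (their positions contribute
    to no segment). Returns a frame with columns start, end (bp span of
    the first to last contributing marker), n_markers, mean_intensity.
    """
    values = np.asarray(values, dtype=np.float64)
    positions = np.asarray(positions)
    if values.shape != positions.shape:
        raise ValueError("values and positions differ in length")
    keep = ~np.isnan(values)
    values, positions = values[keep], positions[keep]
    if len(values) == 0:
        raise ValueError("no non-missing values to segment")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    boundaries: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        x = values[lo:hi]
        stat, i, j = max_arc_split(x, min_width=min_width)
        if stat <= 0 or not _split_significant(x, stat, alpha, n_perm, min_width, rng):
            boundaries.append((lo, hi))
            return
        cuts = [c for c in (i, j) if 0 < c < len(x)]
        pieces = []
        prev = 0
        for c in cuts:
            pieces.append((lo + prev, lo + c))
            prev = c
        pieces.append((lo + prev, hi))
        if len(pieces) == 1:  # degenerate: no interior cut
            boundaries.append((lo, hi))
            return
        for a, b in pieces:
            recurse(a, b)

    recurse(0, len(values))
    boundaries.sort()
    rows = [
        (
            int(positions[lo]),
            int(positions[hi - 1]),
            hi - lo,
            float(values[lo:hi].mean()),
        )
        for lo, hi in boundaries
    ]
    return pd.DataFrame(rows, columns=["start", "end", "n_markers", "mean_intensity"])


def segment_intensity_matrix(
    intensities: IntensityMatrix,
    annotation: MarkerAnnotation,
    platform: str,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    min_width: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Run CBS per sample and chromosome over a whole intensity matrix.

    The permutation RNG is re-seeded per (sample, chromosome) from ``seed``
    so any single profile can be re-segmented independently with identical
    results.
    """
    ann = annotation.df
    idx = intensities.marker_index()
    frames = []
    for chrom, grp in ann.groupby("chrom", sort=False):
        grp = grp.sort_values(["pos", "marker_id"], kind="mergesort")
        cols = np.array([idx[m] for m in grp["marker_id"] if m in idx])
        pos = np.array([p for m, p in zip(grp["marker_id"], grp["pos"]) if m in idx])
        if len(cols) == 0:
            continue
        for si, sample in enumerate(intensities.samples):
            vals = intensities.values[si, cols]
            if np.all(np.isnan(vals)):
                continue
            sub_seed = np.random.default_rng(
                [int(seed), _stable_hash(sample), _stable_hash(chrom)]
            )
            segs = cbs_segment(
                vals, pos, alpha=alpha, n_perm=n_perm, min_width=min_width, seed=sub_seed
            )
            segs.insert(0, "chrom", chrom)
            segs.insert(0, "platform", platform)
            segs.insert(0, "sample_id", sample)
            frames.append(segs)
    if not frames:
        return pd.DataFrame(columns=SEGMENT_COLUMNS[:-1])
    out = pd.concat(frames, ignore_index=True)
    return out


def _stable_hash(text: str) -> int:
    import zlib

    return zlib.crc32(text.encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# centromere splitting
# ---------------------------------------------------------------------------

def split_at_centromere(
    segments: pd.DataFrame,
    genome: GenomeMetadata,
    intensities: IntensityMatrix,
    annotation: MarkerAnnotation,
) -> pd.DataFrame:
    """Split segments extending across a centromere at its boundaries.

    Each overlapping segment becomes a p-arm part ending at centromere
    start - 1 and a q-arm part beginning at centromere end + 1, clipped to
    their contributing markers with means recomputed; a part left with no
    markers is dropped.
    """
    ann = annotation.df
    idx = intensities.marker_index()
    srows = []
    for row in segments.itertuples(index=False):
        cent = genome.centromeres.get(row.chrom)
        if cent is None or row.end < cent[0] or row.start > cent[1]:
            srows.append(row._asdict())
            continue
        for lo, hi in ((row.start, cent[0] - 1), (cent[1] + 1, row.end)):
            if hi < lo:
                continue
            part = _remeasure(row, lo, hi, ann, idx, intensities)
            if part is not None:
                srows.append(part)
    return pd.DataFrame(srows, columns=list(segments.columns)).reset_index(drop=True)


def _remeasure(row, lo: int, hi: int, ann, idx, intensities) -> dict | None:
    grp = ann[(ann["chrom"] == row.chrom) & (ann["pos"] >= lo) & (ann["pos"] <= hi)]
    cols = [idx[m] for m in grp["marker_id"] if m in idx]
    if not cols:
        return None
    si = intensities.samples.index(row.sample_id)
    vals = intensities.values[si, cols]
    pos = grp["pos"].to_numpy()[[m in idx for m in grp["marker_id"]]]
    ok = ~np.isnan(vals)
    if not ok.any():
        return None
    d = row._asdict()
    d["start"] = int(pos[ok].min())
    d["end"] = int(pos[ok].max())
    d["n_markers"] = int(ok.sum())
    d["mean_intensity"] = float(vals[ok].mean())
    return d


# ---------------------------------------------------------------------------
# coverage profile and thresholds
# ---------------------------------------------------------------------------

@dataclass
class SegmentCoverageProfile:
    """bp of segment length per mean-intensity bin; bin i = (edges[i], edges[i+1]]."""

    bin_edges: np.ndarray
    bp_covered: np.ndarray
    cumulative_coverage: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "bp_covered": self.bp_covered,
                "cumulative_coverage": self.cumulative_coverage,
            }
        )


def coverage_profile(segments: pd.DataFrame, bin_width: float = 0.1) -> SegmentCoverageProfile:
    """Histogram total segment bp by segment mean intensity."""
    if len(segments) == 0:
        raise ValueError("no segments to profile")
    means = segments["mean_intensity"].to_numpy(dtype=float)
    lengths = (segments["end"] - segments["start"] + 1).to_numpy(dtype=float)
    lo = np.floor(means.min() / bin_width) * bin_width
    hi = np.ceil(means.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    which = np.clip(np.ceil((means - lo) / bin_width).astype(int) - 1, 0, n_bins - 1)
    bp = np.zeros(n_bins)
    np.add.at(bp, which, lengths)
    return SegmentCoverageProfile(edges, bp, np.cumsum(bp))


def find_loss_threshold(profile: SegmentCoverageProfile) -> float:
    """Loss/neutral boundary from the segment-coverage histogram.

    The histogram of CNV-bearing array data is bimodal: a deletion mode
    well below zero and a dominant neutral mode near zero, separated by a
    coverage valley (the plateau of the cumulative-coverage curve). The
    threshold is the upper edge of the valley's minimum-coverage bin (the
    middle one when several tie). Returns ``-inf`` when no coverage lies
    below zero (no losses to separate); raises when the histogram has no
    neutral mode near zero to bracket against.
    """
    bp = profile.bp_covered
    edges = profile.bin_edges
    centers = (edges[:-1] + edges[1:]) / 2.0
    near0 = centers > -0.5
    if not near0.any() or bp[near0].max() == 0:
        raise ValueError("cannot bracket a loss threshold: no neutral mode near 0")
    main_idx = int(np.flatnonzero(near0)[np.argmax(bp[near0])])
    nz = bp > 0
    # leftmost bin of the contiguous nonzero run holding the neutral mode
    run_start = main_idx
    while run_start > 0 and nz[run_start - 1]:
        run_start -= 1
    below = nz & (np.arange(len(bp)) < run_start) & (edges[1:] <= 0)
    if not below.any():
        return float("-inf")
    prev_end = int(np.flatnonzero(below)[-1])  # top of the deletion cluster
    valley = np.arange(prev_end + 1, run_start)  # empty bins by construction
    if len(valley) == 0:
        return float(edges[prev_end + 1])
    pick = int(valley[len(valley) // 2])
    return float(edges[pick + 1])


def classify_and_filter(
    segments: pd.DataFrame,
    loss_threshold: float,
    gain_threshold: float = 0.5,
    min_size_bp: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign loss/neutral/gain states and apply the minimum-size filter.

    A segment is a loss when its mean is strictly below ``loss_threshold``
    and a gain when strictly above ``gain_threshold``; otherwise neutral.
    Segments of every state with length <= ``min_size_bp`` are removed.
    Returns ``(cnv_segments, neutral_segments)`` — only loss/gain segments
    are CNV segments, but neutrals are kept for coverage accounting.
    """
    if loss_threshold >= gain_threshold:
        raise ValueError(
            f"loss threshold {loss_threshold} must lie below gain threshold {gain_threshold}"
        )
    seg = segments.copy()
    mean = seg["mean_intensity"]
    seg["state"] = np.where(
        mean < loss_threshold, "loss", np.where(mean > gain_threshold, "gain", "neutral")
    )
    lengths = seg["end"] - seg["start"] + 1
    seg = seg[lengths > min_size_bp]
    cnv = seg[seg["state"] != "neutral"].reset_index(drop=True)
    neutral = seg[seg["state"] == "neutral"].reset_index(drop=True)
    return cnv, neutral
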