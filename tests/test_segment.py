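"""CBS change-point detection, centromere splitting, thresholds, classification."""

import numpy as np
import pandas as pd
import pytest

import chmarray as ca
from chmarray.io import GenomeMetadata, IntensityMatrix, MarkerAnnotation
from chmarray.segment import (
    SegmentCoverageProfile,
    cbs_segment,
    classify_and_filter,
    coverage_profile,
    find_loss_threshold,
    max_arc_split,
    split_at_centromere,
)


def brute_force_split(x: np.ndarray, min_width: int = 2):
    """Independent oracle: exhaustive loop over every arc (i, j)."""
    n = len(x)
    best = (-1.0, 0, n)
    for i in range(n):
        for j in range(i + min_width, n + 1):
            k = j - i
            if n - k < min_width:
                continue
            arc = x[i:j].mean()
            comp = (x[:i].sum() + x[j:].sum()) / (n - k)
            stat = abs(arc - comp) / np.sqrt(1 / k + 1 / (n - k))
            if stat > best[0]:
                best = (stat, i, j)
    return best


class TestMaxArcSplit:
    def test_step_profile_split_at_step(self):
        x = np.array([0.0] * 10 + [-3.0] * 10)
        stat, i, j = max_arc_split(x)
        assert (i, j) == (10, 20) or (i, j) == (0, 10)

    def test_too_short_input_no_split(self):
        assert max_arc_split(np.array([1.0, 2.0, 3.0]), min_width=2) == (0.0, 0, 3)

    def test_matches_brute_force_on_random_instances(self, rng):
        # an arc and its complement describe the same partition, so compare
        # the induced cut sets rather than raw (i, j)
        for _ in range(50):
            n = int(rng.integers(5, 51))
            x = rng.normal(0, 1, n)
            stat, i, j = max_arc_split(x)
            bstat, bi, bj = brute_force_split(x)
            assert stat == pytest.approx(bstat, rel=1e-10)
            cuts = {c for c in (i, j) if 0 < c < n}
            bcuts = {c for c in (bi, bj) if 0 < c < n}
            assert cuts == bcuts


class TestCbsSegment:
    def test_constant_vector_single_segment(self):
        pos = np.arange(1, 31) * 1000
        segs = cbs_segment(np.full(30, 0.7), pos, seed=0)
        assert len(segs) == 1
        assert segs.iloc[0]["mean_intensity"] == pytest.approx(0.7)
        assert segs.iloc[0]["start"] == 1000 and segs.iloc[0]["end"] == 30_000

    def test_clean_step_recovered_exactly(self):
        x = np.array([0.0] * 10 + [-3.0] * 10) + np.random.default_rng(4).normal(0, 1e-6, 20)
        pos = np.arange(1, 21) * 100
        segs = cbs_segment(x, pos, seed=1)
        assert len(segs) == 2
        assert segs.iloc[0]["n_markers"] == 10 and segs.iloc[1]["n_markers"] == 10
        assert segs.iloc[0]["mean_intensity"] == pytest.approx(0.0, abs=1e-5)
        assert segs.iloc[1]["mean_intensity"] == pytest.approx(-3.0, abs=1e-5)

    def test_missing_values_dropped(self):
        x = np.array([0.1, np.nan, 0.1, 0.1, np.nan, 0.1])
        pos = np.array([10, 20, 30, 40, 50, 60])
        segs = cbs_segment(x, pos, seed=0)
        assert segs["n_markers"].sum() == 4
        assert segs.iloc[0]["start"] == 10 and segs.iloc[-1]["end"] == 60

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            cbs_segment(np.array([np.nan]), np.array([1]), seed=0)

    def test_interior_arc_yields_three_segments(self):
        rngl = np.random.default_rng(10)
        x = rngl.normal(0, 0.1, 60)
        x[20:40] += 4.0
        segs = cbs_segment(x, np.arange(1, 61) * 50, seed=3)
        assert len(segs) == 3
        assert segs.iloc[1]["n_markers"] == 20
        assert segs.iloc[1]["mean_intensity"] == pytest.approx(4.0, abs=0.15)

    def test_segments_tile_markers(self, rng):
        x = rng.normal(0, 0.3, 80)
        x[30:50] -= 3
        pos = np.arange(1, 81) * 17
        segs = cbs_segment(x, pos, seed=5)
        assert segs["n_markers"].sum() == 80
        # consecutive segments do not overlap and preserve order
        assert (segs["start"].to_numpy()[1:] > segs["end"].to_numpy()[:-1]).all()


class TestSplitAtCentromere:
    def make(self, positions, values, cent):
        ann = MarkerAnnotation(
            pd.DataFrame(
                [(f"m{i}", "chr1", p, "A", "G", "snp") for i, p in enumerate(positions)],
                columns=["marker_id", "chrom", "pos", "allele_a", "allele_b", "probe_class"],
            ),
            "A",
        )
        intens = IntensityMatrix(
            ["s0"], [f"m{i}" for i in range(len(positions))], np.array([values])
        )
        genome = GenomeMetadata({"chr1": 10_000}, {"chr1": cent})
        return ann, intens, genome

    def seg(self, start, end, n, mean):
        return pd.DataFrame(
            [("s0", "A", "chr1", start, end, n, mean)],
            columns=["sample_id", "platform", "chrom", "start", "end", "n_markers", "mean_intensity"],
        )

    def test_spanning_segment_split_at_boundaries(self):
        positions = [100, 399, 601, 900]
        ann, intens, genome = self.make(positions, [1.0, 1.0, 3.0, 3.0], (400, 600))
        out = split_at_centromere(self.seg(100, 900, 4, 2.0), genome, intens, ann)
        assert len(out) == 2
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (100, 399)
        assert (out.iloc[1]["start"], out.iloc[1]["end"]) == (601, 900)
        assert out.iloc[0]["mean_intensity"] == pytest.approx(1.0)
        assert out.iloc[1]["mean_intensity"] == pytest.approx(3.0)

    def test_segment_inside_arm_unchanged(self):
        ann, intens, genome = self.make([100, 200, 300], [1.0, 1, 1], (400, 600))
        out = split_at_centromere(self.seg(100, 300, 3, 1.0), genome, intens, ann)
        assert len(out) == 1 and out.iloc[0]["end"] == 300

    def test_segment_inside_centromere_dropped(self):
        ann, intens, genome = self.make([450, 550], [1.0, 1.0], (400, 600))
        out = split_at_centromere(self.seg(450, 550, 2, 1.0), genome, intens, ann)
        assert len(out) == 0


class TestCoverageProfile:
    def test_single_segment_lands_in_its_bin(self):
        seg = pd.DataFrame(
            [("s0", "A", "chr1", 1, 1000, 5, -2.95)],
            columns=["sample_id", "platform", "chrom", "start", "end", "n_markers", "mean_intensity"],
        )
        prof = coverage_profile(seg)
        j = int(np.searchsorted(prof.bin_edges, -2.95) - 1)
        assert prof.bp_covered[j] == 1000

    def test_same_bin_lengths_add_and_total_conserved(self):
        seg = pd.DataFrame(
            [
                ("s0", "A", "chr1", 1, 1000, 5, -2.95),
                ("s1", "A", "chr1", 1, 501, 5, -2.93),
                ("s0", "A", "chr2", 1, 2000, 5, 0.01),
            ],
            columns=["sample_id", "platform", "chrom", "start", "end", "n_markers", "mean_intensity"],
        )
        prof = coverage_profile(seg)
        assert prof.bp_covered.sum() == 1000 + 501 + 2000
        assert prof.bp_covered.max() == 2000


def profile_from(edges, bp):
    bp = np.asarray(bp, dtype=float)
    return SegmentCoverageProfile(np.asarray(edges, float), bp, np.cumsum(bp))


class TestFindLossThreshold:
    def test_valley_between_modes(self):
        # modes near -3 and 0 with empty bins in (-2, -1)
        edges = np.round(np.arange(-3.0, 0.2, 0.1), 10)
        bp = np.zeros(len(edges) - 1)
        bp[0] = 5000  # (-3.0, -2.9]
        bp[np.searchsorted(edges, -2.05) - 1] = 100  # around -2.1
        bp[-1] = 100_000  # (-0.1, 0.0]
        bp[-2] = 20_000
        thr = find_loss_threshold(profile_from(edges, bp))
        assert -2.0 <= thr <= -1.0

    def test_no_coverage_below_zero_gives_sentinel(self):
        edges = [-0.1, 0.0, 0.1]
        assert find_loss_threshold(profile_from(edges, [0, 1000])) == float("-inf")

    def test_no_neutral_mode_raises(self):
        edges = [-3.0, -2.9, -2.8]
        with pytest.raises(ValueError, match="bracket"):
            find_loss_threshold(profile_from(edges, [1000, 0]))

    def test_near_zero_neutral_tail_not_mistaken_for_loss(self):
        # neutral segments with slightly negative means belong to the main run
        edges = np.round(np.arange(-3.0, 0.3, 0.1), 10)
        bp = np.zeros(len(edges) - 1)
        bp[0] = 3000
        main = np.searchsorted(edges, 0.05) - 1
        bp[main] = 90_000
        bp[main - 1] = 40_000  # (-0.2, -0.1]: part of the neutral run
        bp[main + 1] = 30_000
        thr = find_loss_threshold(profile_from(edges, bp))
        assert -2.9 < thr < -0.2


class TestClassifyAndFilter:
    def seg(self, rows):
        return pd.DataFrame(
            [("s0", "A", "chr1", s, e, 5, m) for s, e, m in rows],
            columns=["sample_id", "platform", "chrom", "start", "end", "n_markers", "mean_intensity"],
        )

    def test_state_boundaries_strict(self):
        cnv, neutral = classify_and_filter(
            self.seg([(1, 1000, -1.2), (2000, 3000, -1.0), (4000, 5000, 0.5), (6000, 7000, 0.51)]),
            loss_threshold=-1.0,
        )
        assert list(cnv["state"]) == ["loss", "gain"]
        assert list(cnv["start"]) == [1, 6000]
        assert list(neutral["start"]) == [2000, 4000]

    def test_size_filter_strictly_greater_than(self):
        cnv, _ = classify_and_filter(
            self.seg([(100, 149, -3.0), (200, 250, -3.0)]), loss_threshold=-1.0
        )
        # 50 bp removed, 51 bp kept
        assert list(cnv["start"]) == [200]

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_and_filter(self.seg([(1, 100, 0.0)]), loss_threshold=0.6, gain_threshold=0.5)


class TestTypeIControl:
    def test_pure_noise_rarely_split(self, rng):
        # 40 white-noise chromosomes at alpha = 0.01: expect ~0 splits
        n_split = 0
        for k in range(40):
            x = rng.normal(0, 1, 150)
            segs = cbs_segment(x, np.arange(1, 151) * 10, alpha=0.01, seed=int(rng.integers(2**31)))
            n_split += len(segs) > 1
        assert n_split <= 4
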