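"""Haploid QC: het-intensity curve, threshold, forcing, and filters."""

import numpy as np
import pandas as pd
import pytest

import chmarray as ca
from chmarray.hqc import (
    HetIntensityCurve,
    find_intensity_threshold,
    het_intensity_curve,
    marker_call_rates,
    sample_call_rates,
)
from chmarray.io import GenotypeMatrix, IntensityMatrix, MarkerAnnotation


def geno(calls, samples=None, markers=None):
    calls = np.asarray(calls, dtype=np.int8)
    samples = samples or [f"s{i}" for i in range(calls.shape[0])]
    markers = markers or [f"m{j}" for j in range(calls.shape[1])]
    return GenotypeMatrix(samples, markers, calls)


def intens(values, samples=None, markers=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    markers = markers or [f"m{j}" for j in range(values.shape[1])]
    return IntensityMatrix(samples, markers, values)


def curve_from(edges, fractions, n_calls=1000):
    fractions = np.asarray(fractions, dtype=float)
    ncal = np.full(len(fractions), n_calls)
    nhet = np.round(fractions * n_calls).astype(int)
    total = ncal.sum()
    above = total - np.concatenate(([0], np.cumsum(ncal)[:-1]))
    return HetIntensityCurve(np.asarray(edges, float), fractions, above / total, ncal, nhet)


class TestHetIntensityCurve:
    def test_all_hom_curve_is_zero(self):
        g = geno([[ca.HOM_A, ca.HOM_B], [ca.HOM_B, ca.HOM_A]])
        c = het_intensity_curve(g, intens([[0.05, -0.1], [0.2, 0.0]]))
        assert np.nansum(c.het_fraction) == 0

    def test_direct_het_count_in_one_bin(self):
        # ten calls land in one bin, one of them het
        calls = [[ca.HOM_A] * 9 + [ca.HET]]
        vals = [[0.05] * 10]
        c = het_intensity_curve(geno(calls), intens(vals))
        j = np.nanargmax(c.n_calls)
        assert c.het_fraction[j] == pytest.approx(0.1)

    def test_nocall_and_missing_intensity_excluded(self):
        calls = [[ca.HOM_A, ca.NOCALL, ca.HET]]
        vals = [[0.05, 0.05, np.nan]]
        c = het_intensity_curve(geno(calls), intens(vals))
        assert c.n_calls.sum() == 1

    def test_fraction_below_any_cut_nondecreasing_in_cut(self):
        rng = np.random.default_rng(1)
        calls = np.full((5, 40), ca.HOM_A)
        vals = rng.normal(0, 1, (5, 40))
        c = het_intensity_curve(geno(calls), intens(vals))
        below = 1.0 - c.cumulative_call_fraction
        assert (np.diff(below) >= -1e-12).all()

    def test_no_calls_at_all_raises(self):
        g = geno([[ca.NOCALL]])
        with pytest.raises(ValueError):
            het_intensity_curve(g, intens([[0.1]]))


class TestFindThreshold:
    def test_worked_bin_example(self):
        c = curve_from(
            [-3, -2, -1, -0.5, 0], [0.40, 0.10, 0.012, 0.003], n_calls=1000
        )
        assert find_intensity_threshold(c, 0.01) == pytest.approx(-0.5)

    def test_all_clean_returns_sentinel(self):
        c = curve_from([-1, 0, 1], [0.0, 0.0])
        assert find_intensity_threshold(c, 0.01) == float("-inf")

    def test_everything_enriched_raises(self):
        c = curve_from([-1, 0, 1], [0.05, 0.2])
        with pytest.raises(ValueError, match="unusable"):
            find_intensity_threshold(c, 0.01)

    def test_significance_variant_ignores_single_stray_het(self):
        # a sparse tail bin with 1 het out of 5 calls must not set the threshold
        edges = [-3, -2, -1, 0, 1]
        frac = np.array([0.40, 0.012, 0.003, 0.2])
        ncal = np.array([1000, 1000, 1000, 5])
        nhet = np.array([400, 12, 3, 1])
        total = ncal.sum()
        above = total - np.concatenate(([0], np.cumsum(ncal)[:-1]))
        c = HetIntensityCurve(np.array(edges, float), frac, above / total, ncal, nhet)
        assert find_intensity_threshold(c, 0.01) == pytest.approx(1.0)
        assert find_intensity_threshold(c, 0.01, significance=0.01) == pytest.approx(-2.0)

    def test_threshold_between_loss_mode_and_zero_on_synthetic(self, default_dataset):
        ds = default_dataset
        c = het_intensity_curve(ds.geno_A, ds.int_A)
        thr = find_intensity_threshold(c, 0.01, significance=0.01)
        assert ds.config.loss_shift_A < thr < 0


class TestApplyHqc:
    def test_het_forced_regardless_of_intensity(self):
        g = geno([[ca.HET]])
        out, rep = ca.apply_hqc(g, intens([[0.2]]), threshold=-0.6)
        assert out.calls[0, 0] == ca.NOCALL and rep.n_het_forced == 1

    def test_low_intensity_hom_forced(self):
        g = geno([[ca.HOM_A]])
        out, rep = ca.apply_hqc(g, intens([[-2.0]]), threshold=-0.6)
        assert out.calls[0, 0] == ca.NOCALL and rep.n_low_intensity_forced == 1

    def test_boundary_intensity_retained(self):
        # forcing applies strictly below the threshold
        g = geno([[ca.HOM_B]])
        out, rep = ca.apply_hqc(g, intens([[-0.6]]), threshold=-0.6)
        assert out.calls[0, 0] == ca.HOM_B and rep.fraction_forced == 0

    def test_het_below_threshold_counted_once_as_low(self):
        g = geno([[ca.HET]])
        out, rep = ca.apply_hqc(g, intens([[-5.0]]), threshold=-0.6)
        assert rep.n_low_intensity_forced == 1 and rep.n_het_forced == 0

    def test_never_resurrects_nocalls_and_never_grows_calls(self, small_dataset):
        ds = small_dataset
        out, _ = ca.apply_hqc(ds.geno_A, ds.int_A, threshold=-0.6)
        before = ds.geno_A.calls != ca.NOCALL
        after = out.calls != ca.NOCALL
        assert not (after & ~before).any()
        assert after.sum() <= before.sum()


class TestDuplicateRemoval:
    def ann(self, rows):
        df = pd.DataFrame(
            rows, columns=["marker_id", "chrom", "pos", "allele_a", "allele_b", "probe_class"]
        )
        return MarkerAnnotation(df, "B")

    def test_pair_at_same_position_both_removed(self):
        ann = self.ann(
            [("m1", "chr1", 500, "A", "G", "snp"), ("m2", "chr1", 500, "A", "C", "snp")]
        )
        g = geno([[ca.HOM_A, ca.HOM_B]], markers=["m1", "m2"])
        out, removed = ca.remove_duplicate_position_markers(ann, g)
        assert sorted(removed) == ["m1", "m2"] and out.markers == []

    def test_no_duplicates_unchanged(self):
        ann = self.ann(
            [("m1", "chr1", 500, "A", "G", "snp"), ("m2", "chr1", 600, "A", "C", "snp")]
        )
        g = geno([[ca.HOM_A, ca.HOM_B]], markers=["m1", "m2"])
        out, removed = ca.remove_duplicate_position_markers(ann, g)
        assert removed == [] and out.markers == ["m1", "m2"]

    def test_triple_all_removed(self):
        ann = self.ann(
            [
                ("m1", "chr1", 500, "A", "G", "snp"),
                ("m2", "chr1", 500, "A", "C", "snp"),
                ("m3", "chr1", 500, "T", "C", "snp"),
                ("m4", "chr1", 600, "T", "C", "snp"),
            ]
        )
        g = geno([[ca.HOM_A] * 4], markers=["m1", "m2", "m3", "m4"])
        out, removed = ca.remove_duplicate_position_markers(ann, g)
        assert sorted(removed) == ["m1", "m2", "m3"] and out.markers == ["m4"]

    def test_planted_duplicates_recovered(self, small_dataset):
        ds = small_dataset
        _, removed = ca.remove_duplicate_position_markers(ds.ann_B, ds.geno_B)
        assert set(removed) == ds.truth.duplicate_marker_ids


class TestCallRateFilters:
    def test_marker_below_ninety_percent_removed(self):
        calls = np.full((100, 1), ca.HOM_A, dtype=np.int8)
        calls[:11, 0] = ca.NOCALL  # 89/100
        out, rep = ca.filter_by_call_rate(geno(calls), sample_min=-1.0)
        assert out.markers == [] and rep["n_markers_removed"] == 1

    def test_marker_at_exactly_ninety_percent_kept(self):
        calls = np.full((100, 1), ca.HOM_A, dtype=np.int8)
        calls[:10, 0] = ca.NOCALL  # 90/100
        out, _ = ca.filter_by_call_rate(geno(calls), sample_min=0.0)
        assert out.markers == ["m0"]

    def test_sample_at_exactly_sample_min_removed(self):
        # retention requires strictly greater than the minimum on both platforms
        calls = np.full((1, 100), ca.HOM_A, dtype=np.int8)
        calls[0, :4] = ca.NOCALL  # rate 0.96 exactly
        g = geno(calls)
        rates = {"A": sample_call_rates(g), "B": pd.Series({"s0": 1.0})}
        with pytest.raises(ValueError, match="all samples removed"):
            ca.filter_by_call_rate(g, marker_min=0.0, sample_min=0.96,
                                   per_platform_sample_rates=rates)

    def test_sample_must_pass_on_both_platforms(self):
        calls = np.full((2, 100), ca.HOM_A, dtype=np.int8)
        g = geno(calls)
        rates = {
            "A": pd.Series({"s0": 1.0, "s1": 1.0}),
            "B": pd.Series({"s0": 1.0, "s1": 0.90}),
        }
        out, rep = ca.filter_by_call_rate(
            g, marker_min=0.0, sample_min=0.96, per_platform_sample_rates=rates
        )
        assert out.samples == ["s0"] and rep["n_samples_removed"] == 1

    def test_filters_order_insensitive_for_fixed_rates(self, small_dataset):
        # rates computed once: marker and sample cuts commute
        ds = small_dataset
        g, _, _ = ca.run_hqc(ds.geno_A, ds.int_A, ds.ann_A, platform="A")
        m_rates = marker_call_rates(g)
        s_rates = sample_call_rates(g)
        keep_m = [m for m in g.markers if m_rates[m] >= 0.9]
        keep_s = [s for s in g.samples if s_rates[s] > 0.5]
        a = g.subset_markers(keep_m).subset_samples(keep_s)
        b = g.subset_samples(keep_s).subset_markers(keep_m)
        assert np.array_equal(a.calls, b.calls)


class TestEndToEndHqc:
    def test_hqc_leaves_zero_het_calls(self, default_dataset):
        ds = default_dataset
        out, rep, _ = ca.run_hqc(ds.geno_A, ds.int_A, ds.ann_A, platform="A")
        assert (out.calls == ca.HET).sum() == 0
        assert rep.n_het_forced > 0

    def test_fixed_threshold_override(self, small_dataset):
        ds = small_dataset
        _, rep, _ = ca.run_hqc(
            ds.geno_A, ds.int_A, ds.ann_A, platform="A", fixed_threshold=-0.6
        )
        assert rep.threshold == -0.6
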