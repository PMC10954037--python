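"""Tests of peak calling, condition classification, smoothing, and the
enrichment/permutation machinery."""
import itertools

import numpy as np
import pytest

from hetsilence.peaks import (
    Peak,
    at_content_track,
    call_peaks,
    class_log2fc,
    classify_peaks,
    motif_log2_enrichment,
    permutation_test,
    rolling_mean,
    scan_motif,
)
from hetsilence.tracks import Region, RegionSet, SignalTrack


def track(values, bin_size=1):
    values = np.asarray(values, dtype=float)
    return SignalTrack(len(values) * bin_size, bin_size, values)


class TestCallPeaks:
    def test_zero_track_empty(self):
        assert len(call_peaks(track(np.zeros(1000)))) == 0

    def test_single_run_kept_with_full_width(self):
        v = np.zeros(1000)
        v[100:400] = 5.0
        peaks = call_peaks(track(v), z_threshold=2, min_width=200)
        assert [(p.start, p.end) for p in peaks] == [(100, 400)]

    def test_gap_merging_rule(self):
        v = np.zeros(2000)
        v[100:400] = 5.0
        v[440:700] = 5.0  # gap of 40
        merged = call_peaks(track(v), merge_gap=50)
        assert [(p.start, p.end) for p in merged] == [(100, 700)]
        split = call_peaks(track(v), merge_gap=30)
        assert [(p.start, p.end) for p in split] == [(100, 400), (440, 700)]

    def test_min_width_filter_applied_after_merge(self):
        v = np.zeros(1000)
        v[100:220] = 5.0
        v[260:380] = 5.0  # two 120-bp runs, 40-bp gap: merged width 280
        assert len(call_peaks(track(v), min_width=200, merge_gap=50)) == 1
        assert len(call_peaks(track(v), min_width=200, merge_gap=10)) == 0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            call_peaks(track(np.zeros(100)), min_width=0)


class TestClassifyPeaks:
    def _set(self, *ivals):
        return RegionSet([Region(s, e) for s, e in ivals], 10_000)

    def test_identical_sets_all_independent(self):
        s = self._set((100, 400), (600, 900))
        peaks = classify_peaks(s, s)
        assert [p.peak_class for p in peaks] == ["ppk_independent"] * 2

    def test_disjoint_sets_split_dependent_secondary(self):
        wt = self._set((100, 400))
        dppk = self._set((600, 900))
        classes = {(p.start, p.peak_class) for p in classify_peaks(wt, dppk)}
        assert classes == {(100, "ppk_dependent"), (600, "secondary")}

    def test_reciprocal_overlap_threshold(self):
        wt = self._set((0, 100))
        dppk = self._set((40, 140))  # 60 bp overlap, 60% reciprocal
        peaks = classify_peaks(wt, dppk, min_overlap_frac=0.5)
        assert len(peaks) == 1 and peaks[0].peak_class == "ppk_independent"
        # at a stricter threshold the merged interval is present in neither
        assert classify_peaks(wt, dppk, min_overlap_frac=0.9) == []

    def test_classification_is_a_partition(self, study):
        peaks = study["classified"]
        assert len(peaks) > 0
        counts = {cls: 0 for cls in ("ppk_dependent", "ppk_independent", "secondary")}
        for p in peaks:
            counts[p.peak_class] += 1
        assert sum(counts.values()) == len(peaks)
        assert all(v > 0 for v in counts.values())

    def test_peak_class_invariant(self):
        assert Peak(0, 10, True, False).peak_class == "ppk_dependent"
        assert Peak(0, 10, True, True).peak_class == "ppk_independent"
        assert Peak(0, 10, False, True).peak_class == "secondary"
        with pytest.raises(ValueError):
            Peak(0, 10, False, False).peak_class


class TestRollingMeanAndAtContent:
    def test_constant_unchanged(self):
        t = rolling_mean(track(np.full(100, 3.5)), window=11)
        assert np.allclose(t.values, 3.5)

    def test_unit_impulse_spreads(self):
        v = np.zeros(21)
        v[10] = 1.0
        sm = rolling_mean(track(v), window=5)
        assert np.allclose(sm.values[8:13], 0.2)
        assert np.allclose(sm.values[:8], 0.0)

    def test_linear_ramp_interior_fixed_point(self):
        v = np.arange(100, dtype=float)
        sm = rolling_mean(track(v), window=9)
        assert np.allclose(sm.values[4:-4], v[4:-4])

    def test_window_larger_than_genome_rejected(self):
        with pytest.raises(ValueError, match="genome"):
            rolling_mean(track(np.zeros(10)), window=100)

    def test_all_a_sequence(self):
        t = at_content_track("A" * 50, window=10)
        assert np.allclose(t.values, 1.0)

    def test_acgt_repeat_interior(self):
        t = at_content_track("ACGT" * 25, window=4)
        assert np.allclose(t.values[2:-2], 0.5)

    def test_eight_bp_worked_example(self):
        t = at_content_track("AATTGGCC", window=8)
        assert t.values[4] == pytest.approx(0.5)

    def test_non_acgt_handling(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            at_content_track("ACGN", window=2)
        t = at_content_track("ACGN", window=4, strict=False)
        assert t.values[2] == pytest.approx(0.25)


class TestClassLog2fc:
    def test_class_equal_to_genome_mean(self):
        sm = track(np.full(100, 2.0))
        assert class_log2fc(sm, [Region(10, 20)]) == 0.0

    def test_doubled_class_mean(self):
        v = np.full(100, 1.0)
        v[10:20] = 2.0
        fc = class_log2fc(track(v), [Region(10, 20)])
        assert fc == pytest.approx(np.log2(2.0 / 1.1))

    def test_zero_class_gives_neg_inf(self):
        v = np.full(100, 1.0)
        v[10:20] = 0.0
        assert class_log2fc(track(v), [Region(10, 20)]) == float("-inf")

    def test_empty_class_flagged_nan(self):
        assert np.isnan(class_log2fc(track(np.ones(10)), []))

    def test_zero_genome_mean_rejected(self):
        with pytest.raises(ValueError, match="genome-wide mean"):
            class_log2fc(track(np.zeros(10)), [Region(0, 5)])


class TestPermutationTest:
    def test_constant_track_p_one(self):
        p = permutation_test([Region(2, 5)], track(np.ones(100)), n_perm=999, seed=0)
        assert p == 1.0

    def test_extreme_enrichment_hits_floor(self):
        v = np.zeros(5000)
        v[0:100] = 100.0
        p = permutation_test([Region(0, 100)], track(v), n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_add_one_bound(self, rng):
        v = rng.normal(size=500)
        p = permutation_test([Region(50, 80)], track(v), n_perm=999, seed=2)
        assert p >= 1 / 1000

    def test_matches_exhaustive_enumeration_on_toy_genome(self):
        values = np.array([5.0, 1, 0, 2, 0, 1, 0, 3, 0, 0])
        sm = track(values)
        gm = values.mean()
        # exhaustive null: one width-1 interval at each of the 10 placements
        obs = abs(values[0] - gm)
        null = [abs(v - gm) for v in values]
        p_exact = sum(d >= obs - 1e-12 for d in null) / 10
        p_perm = permutation_test([Region(0, 1)], sm, n_perm=9999, seed=3)
        assert p_perm == pytest.approx(p_exact, abs=0.02)

    def test_interval_wider_than_genome_rejected(self):
        with pytest.raises(ValueError, match="wider"):
            permutation_test([Region(0, 50)], track(np.ones(10)), n_perm=999, seed=0)


class TestMotifs:
    def test_exact_and_iupac_matching(self):
        hits = scan_motif("GGATATGG", "ATAT", both_strands=False)
        assert [(h.start, h.end) for h in hits] == [(2, 6)]
        hits = scan_motif("GGAATTGG", "WWWW", both_strands=False)
        assert [(h.start, h.end) for h in hits] == [(2, 6)]

    def test_reverse_complement_found(self):
        # CCGGA reverse complement is TCCGG; only the latter is present
        assert len(scan_motif("AATCCGGTT", "CCGGA")) == 1
        assert len(scan_motif("AATCCGGTT", "CCGGA", both_strands=False)) == 0

    def test_equal_rates_give_zero(self):
        peaks = {
            "a": [Peak(0, 10, True, False), Peak(20, 30, True, False)],
            "b": [Peak(40, 50, False, True), Peak(60, 70, False, True)],
        }
        hits = RegionSet([Region(0, 2), Region(40, 42)], 100)
        res = {r.class_label: r.log2fc for r in motif_log2_enrichment(peaks, hits)}
        assert res["a"] == 0.0 and res["b"] == 0.0

    def test_zero_rate_class_neg_inf(self):
        peaks = {
            "a": [Peak(0, 10, True, False)],
            "b": [Peak(40, 50, False, True)],
        }
        hits = RegionSet([Region(40, 42)], 100)
        res = {r.class_label: r.log2fc for r in motif_log2_enrichment(peaks, hits)}
        assert res["a"] == float("-inf")
        assert res["b"] == float("inf")

    def test_hand_ratio(self):
        mk = lambda n, s0, hit_first: [
            Peak(s0 + 20 * i, s0 + 20 * i + 10, True, True) for i in range(n)
        ]
        class_a = mk(8, 0, True)
        others = mk(8, 200, False)
        # 4/8 of class a bear hits, 1/8 of the others
        hits = RegionSet(
            [Region(p.start, p.start + 2) for p in class_a[:4]]
            + [Region(others[0].start, others[0].start + 2)],
            1000,
        )
        res = {
            r.class_label: r.log2fc
            for r in motif_log2_enrichment({"a": class_a, "b": others}, hits)
        }
        assert res["a"] == pytest.approx(2.0)

    def test_all_classes_empty_rejected(self):
        with pytest.raises(ValueError, match="no peaks"):
            motif_log2_enrichment({"a": [], "b": []}, RegionSet([], 100))
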