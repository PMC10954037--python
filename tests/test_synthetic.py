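"""Tests of the synthetic-data generators: planted structure, seeded
determinism, and the count/concentration arithmetic."""
import dataclasses

import numpy as np
import pytest

from hetsilence import synthetic as syn
from hetsilence.synthetic import SyntheticGenomeSpec, generate_genome


def at_fraction(seq: str) -> float:
    return sum(c in "AT" for c in seq) / len(seq)


class TestGenerateGenome:
    def test_mge_at_fraction_near_target(self):
        spec = SyntheticGenomeSpec(
            genome_length=100_000, at_mge=0.65, at_background=0.50, seed=5
        )
        g = generate_genome(spec)
        mge_seq = "".join(g.sequence[r.start : r.end] for r in g.epods if r.mge)
        assert len(mge_seq) > 1000
        assert abs(at_fraction(mge_seq) - 0.65) < 0.03

    def test_mge_at_exceeds_background(self):
        g = generate_genome(SyntheticGenomeSpec(seed=2))
        outside = np.ones(g.spec.genome_length, dtype=bool)
        for r in g.epods:
            outside[r.start : r.end] = False
        for r in g.secondary_sites:
            outside[r.start : r.end] = False
        bg_seq = "".join(c for c, keep in zip(g.sequence, outside) if keep)
        mge_seq = "".join(g.sequence[r.start : r.end] for r in g.epods if r.mge)
        assert at_fraction(mge_seq) > at_fraction(bg_seq)

    def test_zero_mge_fraction_flags_nothing(self):
        g = generate_genome(SyntheticGenomeSpec(mge_fraction=0.0, seed=1))
        assert not any(r.mge for r in g.epods)

    def test_seeded_determinism(self):
        spec = SyntheticGenomeSpec(seed=42)
        a, b = generate_genome(spec), generate_genome(spec)
        assert a.sequence == b.sequence
        assert a.epods == b.epods
        assert np.array_equal(a.hns_track.values, b.hns_track.values)
        assert np.array_equal(a.affinity["wt"].values, b.affinity["wt"].values)

    def test_epods_sorted_nonoverlapping_separated(self):
        g = generate_genome(SyntheticGenomeSpec(seed=3))
        regs = g.epods.regions
        for a, b in zip(regs, regs[1:]):
            assert a.end + g.spec.min_separation <= b.start
        assert regs[-1].end <= g.spec.genome_length

    def test_infeasible_packing_raises(self):
        spec = SyntheticGenomeSpec(
            genome_length=20_000, n_epods=15, epod_width_range=(2_000, 2_000)
        )
        with pytest.raises(ValueError, match="infeasible"):
            generate_genome(spec)

    def test_hns_boost_inside_mge_epods(self):
        g = generate_genome(SyntheticGenomeSpec(seed=4))
        for r in g.epods:
            expected = g.spec.hns_baseline + (g.spec.hns_mge_boost if r.mge else 0)
            assert np.allclose(g.hns_track.values[r.start : r.end], expected)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(at_background=0.7, at_mge=0.6),
            dict(n_epods=0),
            dict(mge_fraction=1.5),
            dict(epod_width_range=(5000, 1000)),
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_genome(SyntheticGenomeSpec(**bad))


class TestOccupancyTracks:
    def test_zero_noise_reproduces_affinity(self):
        g = generate_genome(SyntheticGenomeSpec(seed=1))
        tagged, untagged = syn.generate_occupancy_tracks(g, "wt", noise_sd=0.0, seed=0)
        assert np.array_equal(tagged.values, g.affinity["wt"].values)
        assert np.all(untagged.values == 0)

    def test_wt_exceeds_dppk_at_mge_epods_by_planted_effect(self):
        g = generate_genome(SyntheticGenomeSpec(seed=1))
        mge_mask = g.epods.subset(lambda r: r.mge).mask(g.spec.genome_length)
        diff = g.affinity["wt"].values[mge_mask] - g.affinity["dppk"].values[mge_mask]
        assert np.allclose(diff, g.spec.affinity_mge)

    def test_seeded_reproducibility(self):
        g = generate_genome(SyntheticGenomeSpec(seed=1))
        t1, u1 = syn.generate_occupancy_tracks(g, "dppk", noise_sd=1.0, seed=9)
        t2, u2 = syn.generate_occupancy_tracks(g, "dppk", noise_sd=1.0, seed=9)
        assert np.array_equal(t1.values, t2.values)
        assert np.array_equal(u1.values, u2.values)

    def test_unknown_condition(self):
        g = generate_genome(SyntheticGenomeSpec(seed=1))
        with pytest.raises(ValueError, match="unknown condition"):
            syn.generate_occupancy_tracks(g, "dhns", 1.0, 0)


class TestPlatingCounts:
    def test_poisson_mean_matches_exponent(self):
        obs = syn.generate_plating_counts([8.0] * 1000, None, [-6.0], seed=0)
        counts = [o.count for o in obs]
        assert abs(np.mean(counts) - 100.0) < 5.0

    def test_tiny_expected_count_yields_zero(self):
        obs = syn.generate_plating_counts([8.0], -10.0, [0.0], seed=0)
        treated = [o for o in obs if o.arm == "treated"]
        assert all(o.count == 0 for o in treated)

    def test_null_effect_matches_untreated_distribution(self):
        obs = syn.generate_plating_counts([6.0] * 2000, 0.0, [-4.0], seed=1)
        treated = np.array([o.count for o in obs if o.arm == "treated"])
        untreated = np.array([o.count for o in obs if o.arm == "untreated"])
        # same Poisson(100) law: means and variances agree within CLT noise
        assert abs(treated.mean() - untreated.mean()) < 1.5
        assert abs(treated.var() / untreated.var() - 1.0) < 0.15

    def test_overflow_advises_dilution(self):
        with pytest.raises(ValueError, match="dilute"):
            syn.generate_plating_counts([10.0], None, [0.0], seed=0)


class TestExpressionTable:
    def test_zero_shift_identical_in_law(self):
        t = syn.generate_expression_table(4000, 0.5, {"c": 0.0}, 1.0, seed=3)
        mge = t.loc[t.category == "MGE", "c"]
        other = t.loc[t.category == "other", "c"]
        assert abs(mge.mean() - other.mean()) < 0.1
        assert abs(mge.std() / other.std() - 1.0) < 0.1

    def test_shift_applied_to_mge_only(self):
        t = syn.generate_expression_table(2000, 0.2, {"c": 1.0}, 0.0, seed=0, gene_sd=0.0)
        assert np.allclose(t.loc[t.category == "MGE", "c"], 1.0)
        assert np.allclose(t.loc[t.category == "other", "c"], 0.0)

    def test_identical_shifts_correlate_as_noise_vanishes(self):
        from hetsilence.expression import genotype_spearman

        t = syn.generate_expression_table(
            500, 0.3, {"a": 1.0, "b": 1.0}, 1e-9, seed=5
        )
        rho, _ = genotype_spearman(t, "MGE", ["a", "b"])
        assert rho.loc["a", "b"] > 0.99


class TestCellsAndFrap:
    def test_constant_occupancy(self):
        cells = syn.generate_cell_measurements(50, 0.5, 0.0, seed=0)
        ratios = [c.dapi_area / c.cell_area for c in cells]
        assert np.allclose(ratios, 0.5)

    def test_noiseless_frap_round_trip(self):
        from hetsilence.imaging import fit_frap_trace

        trace = syn.generate_frap_trace(0.2, 0.9, 29.0, 5.0, 300.0, 0.0, seed=0)
        fit = fit_frap_trace(trace)
        assert fit.t_half == pytest.approx(29.0, abs=1e-4)
        assert fit.y0 == pytest.approx(0.2, abs=1e-6)
        assert fit.plateau == pytest.approx(0.9, abs=1e-6)

    def test_seeded_reproducibility(self):
        a = syn.generate_frap_trace(0.2, 0.9, 29.0, 5.0, 300.0, 0.02, seed=4)
        b = syn.generate_frap_trace(0.2, 0.9, 29.0, 5.0, 300.0, 0.02, seed=4)
        assert np.array_equal(a.roi_intensity, b.roi_intensity)

    @pytest.mark.parametrize("bad", [dict(t_half=0.0), dict(dt=-1.0)])
    def test_nonpositive_time_parameters_rejected(self, bad):
        kwargs = dict(y0=0.2, plateau=0.9, t_half=29.0, dt=5.0,
                      duration=300.0, noise_cv=0.0, seed=0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            syn.generate_frap_trace(**kwargs)


class TestCopyNumberConversion:
    @pytest.mark.parametrize(
        "n,vol,expected,tol",
        [
            (55_000, 1.0, 91.3, 0.05),
            (0, 1.0, 0.0, 0.0),
            (602_214, 1.0, 1000.0, 0.1),
        ],
    )
    def test_conversion(self, n, vol, expected, tol):
        assert syn.copy_number_to_concentration(n, vol) == pytest.approx(
            expected, abs=tol + 1e-12
        )

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            syn.copy_number_to_concentration(100, 0.0)
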