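import numpy as np
import pytest

from rtverify.dose_model import DoseGrid, VoxelMask
from rtverify.dvh_verification import (
    classify_correlation,
    correlation_analysis,
    cumulative_dvh,
    dose_at_volume,
    dosimetric_error,
    dvh_index_set,
    error_record,
    paired_t_test,
    tolerance_level,
    volume_at_dose,
    volume_error,
)


def grid_and_mask(doses, spacing=(1.0, 1.0, 1.0)):
    """1-D list of voxel doses packed into a (1, 1, n) grid, all in-mask."""
    v = np.asarray(doses, float).reshape(1, 1, -1)
    grid = DoseGrid(v, (0, 0, 0), spacing)
    mask = VoxelMask(np.ones(v.shape, bool), (0, 0, 0), spacing)
    return grid, mask


class TestCumulativeDvh:
    def test_uniform_dose_step(self):
        grid, mask = grid_and_mask([10.0] * 50)
        dvh = cumulative_dvh(grid, mask, bin_width=0.5)
        assert dvh.cumulative_volume[0] == 1.0
        assert dvh.cumulative_volume[-1] == 0.0
        # 1.0 for bins <= 10 Gy, 0 above
        below = dvh.dose_bins <= 10.0
        assert np.all(dvh.cumulative_volume[below] == 1.0)
        assert np.all(dvh.cumulative_volume[~below] == 0.0)

    def test_two_voxel_curve(self):
        grid, mask = grid_and_mask([10.0, 20.0])
        dvh = cumulative_dvh(grid, mask, bin_width=1.0)
        assert np.interp(5.0, dvh.dose_bins, dvh.cumulative_volume) == 1.0
        assert np.interp(15.0, dvh.dose_bins, dvh.cumulative_volume) == 0.5
        assert np.interp(25.0, dvh.dose_bins, dvh.cumulative_volume, right=0.0) == 0.0

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(0)
        grid, mask = grid_and_mask(rng.uniform(0, 60, 500))
        dvh = cumulative_dvh(grid, mask)
        assert np.all(np.diff(dvh.cumulative_volume) <= 1e-12)

    def test_total_volume(self):
        grid, mask = grid_and_mask([1.0] * 8, spacing=(2.0, 2.0, 2.0))
        dvh = cumulative_dvh(grid, mask)
        assert dvh.total_volume_cm3 == pytest.approx(8 * 8 / 1000.0)

    def test_empty_mask_errors(self):
        grid, mask = grid_and_mask([1.0, 2.0])
        mask.flags[:] = False
        with pytest.raises(ValueError):
            cumulative_dvh(grid, mask)

    def test_matches_sorting_oracle_on_random_masks(self):
        rng = np.random.default_rng(42)
        doses = rng.uniform(0, 55, 1000)
        grid, mask = grid_and_mask(doses)
        dvh = cumulative_dvh(grid, mask, bin_width=0.01)
        srt = np.sort(doses)[::-1]
        for p in (2, 10, 50, 90, 95, 99):
            # oracle: dose of the ceil(p% * n)-th hottest voxel
            k = int(np.ceil(p / 100 * len(srt)))
            oracle = srt[k - 1]
            assert dose_at_volume(dvh, p) == pytest.approx(oracle, abs=0.011)


class TestDvhQueries:
    def test_uniform_dose_d95(self):
        grid, mask = grid_and_mask([25.0] * 20)
        dvh = cumulative_dvh(grid, mask)
        for p in (2, 50, 95, 99.9):
            assert dose_at_volume(dvh, p) == pytest.approx(25.0, abs=dvh.bin_width)

    def test_linear_ramp_quantiles(self):
        # uniform-volume ramp 0 -> 60 Gy: D95 = 3 Gy, D50 = 30 Gy
        grid, mask = grid_and_mask(np.linspace(0, 60, 6001))
        dvh = cumulative_dvh(grid, mask, bin_width=0.01)
        assert dose_at_volume(dvh, 95) == pytest.approx(3.0, abs=0.05)
        assert dose_at_volume(dvh, 50) == pytest.approx(30.0, abs=0.05)

    def test_p100_is_minimum_dose(self):
        grid, mask = grid_and_mask([5.0, 12.0, 40.0])
        dvh = cumulative_dvh(grid, mask, bin_width=0.01)
        assert dose_at_volume(dvh, 100) == pytest.approx(5.0, abs=0.011)

    def test_p_out_of_range(self):
        grid, mask = grid_and_mask([5.0])
        dvh = cumulative_dvh(grid, mask)
        with pytest.raises(ValueError):
            dose_at_volume(dvh, 0)
        with pytest.raises(ValueError):
            dose_at_volume(dvh, 101)

    def test_volume_at_dose_basics(self):
        grid, mask = grid_and_mask([25.0] * 10)
        dvh = cumulative_dvh(grid, mask)
        assert volume_at_dose(dvh, 0.0) == 100.0
        assert volume_at_dose(dvh, 20.0) == 100.0
        assert volume_at_dose(dvh, 30.0) == 0.0

    def test_round_trip_within_one_bin(self):
        rng = np.random.default_rng(1)
        grid, mask = grid_and_mask(rng.uniform(1, 50, 400))
        dvh = cumulative_dvh(grid, mask, bin_width=0.02)
        for p in (5, 20, 50, 80, 95):
            d = dose_at_volume(dvh, p)
            assert volume_at_dose(dvh, d) == pytest.approx(p, abs=1.0)


class TestIndexSet:
    def _spherical_case(self):
        n = 31
        axes = [np.arange(n) * 2.0 for _ in range(3)]
        gz, gy, gx = np.meshgrid(*axes, indexing="ij")
        c = (n - 1) * 1.0
        r = np.sqrt((gz - c) ** 2 + (gy - c) ** 2 + (gx - c) ** 2)
        dose = 50.0 * np.exp(-(r**2) / (2 * 15.0**2))
        grid = DoseGrid(dose, (0, 0, 0), (2.0, 2.0, 2.0))
        masks = {
            "iGTV": VoxelMask(r <= 8.0, (0, 0, 0), (2.0, 2.0, 2.0)),
            "PTV": VoxelMask(r <= 16.0, (0, 0, 0), (2.0, 2.0, 2.0)),
            "lung": VoxelMask(r <= 28.0, (0, 0, 0), (2.0, 2.0, 2.0)),
            "spinal_cord": VoxelMask(
                (np.abs(gy - c) < 3) & (np.abs(gx - 4) < 3), (0, 0, 0), (2.0, 2.0, 2.0)
            ),
        }
        return grid, masks, (c, c, c)

    def test_indices_match_voxel_sort_oracle(self):
        grid, masks, iso = self._spherical_case()
        idx = dvh_index_set(grid, masks, iso)
        ptv_doses = np.sort(grid.values[masks["PTV"].flags])[::-1]
        n = len(ptv_doses)
        assert idx.targets["PTV"].D95 == pytest.approx(ptv_doses[int(np.ceil(0.95 * n)) - 1], abs=0.02)
        assert idx.targets["PTV"].D2 == pytest.approx(ptv_doses[int(np.ceil(0.02 * n)) - 1], abs=0.02)
        assert idx.targets["PTV"].Dmax == ptv_doses[0]
        assert idx.targets["PTV"].Dmean == pytest.approx(ptv_doses.mean())
        assert idx.isocenter_dose == pytest.approx(50.0, rel=1e-3)

    def test_d_index_ordering_and_v_ordering(self):
        grid, masks, iso = self._spherical_case()
        idx = dvh_index_set(grid, masks, iso)
        for t in idx.targets.values():
            assert t.D99 <= t.D95 <= t.D2 <= t.Dmax
        assert idx.lung_V5Gy >= idx.lung_V10Gy >= idx.lung_V20Gy

    def test_lung_is_lung_minus_igtv(self):
        grid, masks, iso = self._spherical_case()
        idx = dvh_index_set(grid, masks, iso)
        lung_minus = masks["lung"].minus(masks["iGTV"])
        assert idx.lung_Dmean == pytest.approx(grid.values[lung_minus.flags].mean())
        assert idx.lung_volume_cm3 == pytest.approx(lung_minus.volume_cm3)

    def test_missing_structure_absent_not_zero(self):
        grid, masks, iso = self._spherical_case()
        del masks["spinal_cord"]
        idx = dvh_index_set(grid, masks, iso)
        assert idx.cord_Dmax is None

    def test_uniform_field_all_indices_equal(self):
        grid, _ = grid_and_mask([20.0] * 64)
        grid = DoseGrid(np.full((4, 4, 4), 20.0), (0, 0, 0), (1, 1, 1))
        masks = {"PTV": VoxelMask(np.ones((4, 4, 4), bool), (0, 0, 0), (1, 1, 1))}
        idx = dvh_index_set(grid, masks)
        t = idx.targets["PTV"]
        assert t.D99 == pytest.approx(20.0, abs=0.02)
        assert t.Dmax == 20.0 and t.Dmean == 20.0


class TestErrorMetrics:
    def test_de_zero(self):
        assert dosimetric_error(50.0, 50.0) == 0.0

    def test_de_negative(self):
        assert dosimetric_error(48.0, 50.0) == pytest.approx(-4.0)

    def test_de_positive(self):
        assert dosimetric_error(51.0, 50.0) == pytest.approx(2.0)

    def test_de_zero_denominator(self):
        with pytest.raises(ValueError):
            dosimetric_error(10.0, 0.0)

    def test_ve(self):
        assert volume_error(10.0, 10.0) == 0.0
        assert volume_error(10.5, 10.0) == pytest.approx(5.0)
        assert volume_error(0.0, 10.0) == pytest.approx(-100.0)
        with pytest.raises(ValueError):
            volume_error(1.0, 0.0)


class TestToleranceLevel:
    def test_constant_values(self):
        assert tolerance_level([-2.0, -2.0, -2.0]) == (-2.0, -2.0)

    def test_hand_arithmetic(self):
        lo, hi = tolerance_level([0.0, 2.0])
        assert lo == pytest.approx(1 - np.sqrt(2))
        assert hi == pytest.approx(1 + np.sqrt(2))

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            tolerance_level([1.0])

    def test_recovers_injected_distribution(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(-3.0, 1.0, 50)
        lo, hi = tolerance_level(vals)
        mean, sd = (lo + hi) / 2, (hi - lo) / 2
        assert mean == pytest.approx(-3.0, abs=0.5)
        assert sd == pytest.approx(1.0, abs=0.35)


class TestCorrelation:
    def test_perfect_linear(self):
        de = [1.0, 2.0, 3.0, 4.0]
        res = correlation_analysis(de, {"cov": [2.0, 4.0, 6.0, 8.0]})[0]
        assert res.cc == pytest.approx(1.0)
        assert res.strength == "strong"

    def test_strength_classes_from_reported_values(self):
        # 0.36 is weak, 0.50 is moderate under the stated ranges
        assert classify_correlation(0.36) == "weak"
        assert classify_correlation(0.50) == "moderate"

    def test_boundaries_go_to_upper_class(self):
        assert classify_correlation(0.4) == "moderate"
        assert classify_correlation(0.8) == "strong"
        assert classify_correlation(0.3999) == "weak"

    def test_zero_variance_undefined(self):
        res = correlation_analysis([1.0, 2.0, 3.0], {"cov": [5.0, 5.0, 5.0]})[0]
        assert res.undefined and res.cc is None

    def test_null_distribution_mostly_weak(self):
        rng = np.random.default_rng(21)
        weak = 0
        trials = 200
        for _ in range(trials):
            de = rng.normal(size=50)
            cov = rng.normal(size=50)
            res = correlation_analysis(de, {"c": cov})[0]
            weak += abs(res.cc) < 0.4
        assert weak / trials >= 0.90

    def test_needs_three(self):
        with pytest.raises(ValueError):
            correlation_analysis([1.0, 2.0], {"c": [1.0, 2.0]})


class TestPairedTTest:
    def test_identical_samples_degenerate(self):
        p, sig = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p is None and sig is None

    def test_constant_shift_degenerate(self):
        p, sig = paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert p is None

    def test_power_at_minus_3pct_shift(self):
        rng = np.random.default_rng(33)
        significant = 0
        trials = 200
        for _ in range(trials):
            base = rng.uniform(45, 55, 50)
            shifted = base * (1 - 0.03) + rng.normal(0, base * 0.01)
            p, sig = paired_t_test(base, shifted)
            significant += sig
        assert significant / trials >= 0.99

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [1.0, 2.0])


class TestErrorRecord:
    def test_uniform_scale_gives_uniform_de(self):
        grid = DoseGrid(np.full((4, 4, 4), 50.0), (0, 0, 0), (1, 1, 1))
        masks = {"PTV": VoxelMask(np.ones((4, 4, 4), bool), (0, 0, 0), (1, 1, 1))}
        idx_p = dvh_index_set(grid, masks)
        grid_s = DoseGrid(grid.values * 0.97, (0, 0, 0), (1, 1, 1))
        idx_s = dvh_index_set(grid_s, masks)
        rec = error_record(idx_p, idx_s, "c1")
        for name, de in rec.DE.items():
            assert de == pytest.approx(-3.0, abs=0.1), name
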