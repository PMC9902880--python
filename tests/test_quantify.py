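"""Region counting, calibration fitting, LOD and selectivity arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirspot.quantify import (
    QuantificationError,
    RegionCounts,
    count_regions,
    estimate_lod,
    fit_calibration,
    selectivity_ratios,
)


from oracles import ols_normal_equations


class TestCountRegions:
    def test_equal_counts(self):
        rc = count_regions([3, 3, 3], label="s")
        assert rc.mean == 3.0 and rc.sd == 0.0

    def test_hand_computed_sample_sd(self):
        rc = count_regions([1, 2, 3, 4])
        assert rc.mean == 2.5
        assert rc.sd == pytest.approx(1.2910, abs=1e-4)

    def test_accepts_spot_lists(self):
        from mirspot.detect import Spot

        regions = [[Spot(0, 0, 0)] * 2, [Spot(0, 0, 0)] * 4]
        rc = count_regions(regions)
        assert rc.counts == [2, 4]

    def test_zero_regions_rejected(self):
        with pytest.raises(QuantificationError):
            count_regions([])

    def test_negative_counts_rejected(self):
        with pytest.raises(QuantificationError):
            RegionCounts(label="x", counts=[1, -2])


class TestFitCalibration:
    def test_exact_line(self):
        concs = [0.1, 1.0, 10.0, 100.0]
        counts = [2 * math.log10(c) + 3 for c in concs]
        fit = fit_calibration(concs, counts)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(3.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        concs = np.array([0.1, 0.5, 1, 5, 10, 50, 100])
        counts = 85.0 * np.log10(concs) + 40.0 + rng.normal(0, 12, size=concs.size)
        fit = fit_calibration(concs, counts)
        slope, intercept = ols_normal_equations(np.log10(concs), counts)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)
        assert 0.0 <= fit.r_squared <= 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(QuantificationError):
            fit_calibration([1.0, 10.0], [1.0, 2.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(QuantificationError):
            fit_calibration([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_nonpositive_x_rejected(self):
        with pytest.raises(QuantificationError):
            fit_calibration([0.0, 1.0, 10.0], [1.0, 2.0, 3.0])


class TestEstimateLod:
    def _fit(self, slope, intercept):
        concs = [0.1, 1.0, 10.0, 100.0]
        counts = [slope * math.log10(c) + intercept for c in concs]
        return fit_calibration(concs, counts)

    def test_algebraic_example(self):
        # blank 5 ± 2 counts against N = 100·log10(C) + 8:
        # threshold 11 → lod = 10^0.03 ≈ 1.072 pM
        fit = self._fit(100.0, 8.0)
        blank = count_regions([3, 5, 7], label="blank")
        lod = estimate_lod(fit, blank)
        assert lod.blank_mean == 5.0 and lod.blank_sd == 2.0
        assert lod.lod_value == pytest.approx(10**0.03, rel=1e-9)

    def test_closed_form_agrees_with_numeric_inversion(self):
        """LOD must be the root of predict(C) − (blank mean + 3 SD)."""
        from scipy.optimize import brentq

        fit = self._fit(111.21, 120.84)
        blank = count_regions([4, 5, 6, 7, 8], label="blank")
        lod = estimate_lod(fit, blank)
        threshold = blank.mean + 3 * blank.sd
        root = brentq(lambda c: fit.predict(c) - threshold, 1e-6, 1e3, xtol=1e-15)
        assert lod.lod_value == pytest.approx(root, rel=1e-9)

    def test_degenerate_blank(self):
        fit = self._fit(100.0, 5.0)
        blank = count_regions([5, 5], label="blank")  # sd 0, mean = intercept
        lod = estimate_lod(fit, blank)
        assert lod.lod_value == pytest.approx(1.0, rel=1e-12)

    def test_negative_slope_rejected(self):
        fit = self._fit(-10.0, 5.0)
        with pytest.raises(QuantificationError):
            estimate_lod(fit, count_regions([1, 2, 3]))


class TestSelectivity:
    def test_headline_fold(self):
        ref = count_regions([210] * 3, label="miR-126")
        var = count_regions([100] * 3, label="mm1")
        res = selectivity_ratios(ref, [var])
        assert res.folds["mm1"] == pytest.approx(2.1)

    def test_identical_means_fold_one(self):
        ref = count_regions([50, 60], label="ref")
        var = count_regions([55, 55], label="v")
        assert selectivity_ratios(ref, [var]).folds["v"] == pytest.approx(1.0)

    def test_zero_variant_warns_infinite(self):
        ref = count_regions([10], label="ref")
        var = count_regions([0], label="v")
        with pytest.warns(UserWarning):
            res = selectivity_ratios(ref, [var])
        assert math.isinf(res.folds["v"])


class TestScaleCovariance:
    @given(st.integers(2, 50))
    def test_scaling_counts_scales_fit_not_r2_or_folds(self, c):
        concs = [0.1, 1.0, 10.0, 100.0]
        counts = np.array([12.0, 118.0, 228.0, 341.0])
        base = fit_calibration(concs, counts)
        scaled = fit_calibration(concs, counts * c)
        assert scaled.slope == pytest.approx(base.slope * c, rel=1e-9)
        assert scaled.intercept == pytest.approx(base.intercept * c, rel=1e-9)
        assert scaled.r_squared == pytest.approx(base.r_squared, abs=1e-9)

        ref = count_regions([30, 40], label="ref")
        var = count_regions([10, 12], label="v")
        ref_s = count_regions([30 * c, 40 * c], label="ref")
        var_s = count_regions([10 * c, 12 * c], label="v")
        assert selectivity_ratios(ref_s, [var_s]).folds["v"] == pytest.approx(
            selectivity_ratios(ref, [var]).folds["v"], rel=1e-12
        )
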