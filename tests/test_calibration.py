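import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfasquant.calibration import (
    back_calculate,
    fit_calibration,
    ion_ratio,
    ion_ratio_summary,
    relative_retention_time,
)
from pfasquant.model import InsufficientDataError
from pfasquant.simulate import CampaignDesign, generate_campaign

from conftest import make_analyte, make_truth


def frame(levels, ratios, analyte="PFX", istd_area=1000.0):
    return pd.DataFrame(
        {
            "analyte": analyte,
            "level": levels,
            "quant_area": [r * istd_area for r in ratios],
            "istd_area": istd_area,
        }
    )


class TestFitCalibration:
    def test_exact_line_recovers_slope_intercept_r2(self, simple_analyte):
        records = frame([1.0, 10.0, 100.0], [2.0, 20.0, 200.0])
        fit = fit_calibration(records, simple_analyte)
        assert fit.slope == pytest.approx(2.0, rel=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == 1.0

    def test_replicates_of_collinear_data_match_single_injections(self, simple_analyte):
        single = frame([1.0, 10.0, 100.0], [2.0, 20.0, 200.0])
        triple = pd.concat([single] * 3, ignore_index=True)
        f1 = fit_calibration(single, simple_analyte)
        f3 = fit_calibration(triple, simple_analyte)
        assert f3.slope == pytest.approx(f1.slope, rel=1e-12)
        assert f3.intercept == pytest.approx(f1.intercept, abs=1e-9)
        assert f3.r_squared == 1.0

    @pytest.mark.parametrize("noise_cv,floor", [(0.05, 0.99), (0.01, 0.999)])
    def test_nineteen_level_noisy_campaign_stays_linear(self, simple_analyte, noise_cv, floor):
        # triplicate 19-point curve: r² floor set by the multiplicative
        # noise level (Monte-Carlo: r² ≈ 1 − O(cv²) for an unweighted fit)
        truth = make_truth(noise_cv=noise_cv, istd_cv=noise_cv)
        design = CampaignDesign(seed=42)
        injections, _, _ = generate_campaign(truth, design)
        fit = fit_calibration(injections[injections.sample_type == "cal"], simple_analyte)
        assert fit.r_squared >= floor

    def test_fewer_than_three_levels_rejected(self, simple_analyte):
        with pytest.raises(InsufficientDataError):
            fit_calibration(frame([1.0, 10.0], [2.0, 20.0]), simple_analyte)

    def test_zero_istd_injections_are_excluded(self, simple_analyte, caplog):
        records = frame([1.0, 5.0, 10.0, 100.0], [2.0, 10.0, 20.0, 200.0])
        records.loc[1, "istd_area"] = 0.0
        fit = fit_calibration(records, simple_analyte)
        assert fit.n_points == 3
        assert fit.slope == pytest.approx(2.0, rel=1e-12)

    def test_slope_invariant_under_common_area_rescaling(self, simple_analyte):
        records = frame([1.0, 10.0, 100.0], [2.1, 19.5, 201.0])
        scaled = records.assign(
            quant_area=records.quant_area * 7.3, istd_area=records.istd_area * 7.3
        )
        f1 = fit_calibration(records, simple_analyte)
        f2 = fit_calibration(scaled, simple_analyte)
        assert f2.slope == pytest.approx(f1.slope, rel=1e-12)
        assert f2.intercept == pytest.approx(f1.intercept, rel=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        slope=st.floats(0.01, 50.0),
        intercept=st.floats(-5.0, 5.0),
        levels=st.lists(st.integers(1, 500), min_size=3, max_size=8, unique=True),
    )
    def test_r_squared_is_one_for_collinear_input(self, slope, intercept, levels):
        analyte = make_analyte(calib_low=0.5, calib_high=1000.0)
        ratios = [slope * lv + intercept for lv in levels]
        fit = fit_calibration(frame([float(x) for x in levels], ratios), analyte)
        assert fit.r_squared == 1.0

    def test_one_over_x_weighting_still_exact_on_exact_line(self, simple_analyte):
        records = frame([1.0, 10.0, 100.0], [2.0, 20.0, 200.0])
        fit = fit_calibration(records, simple_analyte, weighting="one_over_x")
        assert fit.weighting == "one_over_x"
        assert fit.slope == pytest.approx(2.0, rel=1e-12)


class TestBackCalculate:
    def test_inverts_exact_line(self, simple_analyte):
        fit = fit_calibration(frame([1.0, 10.0, 100.0], [2.0, 20.0, 200.0]), simple_analyte)
        res = back_calculate(fit, quant_area=20.0 * 1000.0, istd_area=1000.0)
        assert res.conc == pytest.approx(10.0, rel=1e-12)
        assert not (res.extrapolated_low or res.extrapolated_high or res.negative)

    def test_ratio_at_intercept_gives_zero_flagged_low(self, simple_analyte):
        fit = fit_calibration(frame([1.0, 10.0, 100.0], [2.0, 20.0, 200.0]), simple_analyte)
        res = back_calculate(fit, quant_area=0.0, istd_area=1000.0)
        assert res.conc == pytest.approx(0.0, abs=1e-9)
        assert res.extrapolated_low

    def test_negative_concentration_reported_and_flagged(self, simple_analyte):
        records = frame([1.0, 10.0, 100.0], [3.0, 21.0, 201.0])  # positive intercept
        fit = fit_calibration(records, simple_analyte)
        res = back_calculate(fit, quant_area=0.0, istd_area=1000.0)
        assert res.conc < 0
        assert res.negative and res.extrapolated_low

    def test_zero_slope_errors(self):
        from pfasquant.calibration import CalibrationFit

        fit = CalibrationFit("PFX", 0.0, 5.0, 1.0, "none", (1.0, 100.0), 3)
        with pytest.raises(ZeroDivisionError):
            back_calculate(fit, 10.0, 1000.0)

    def test_istd_area_must_be_positive(self, simple_analyte):
        fit = fit_calibration(frame([1.0, 10.0, 100.0], [2.0, 20.0, 200.0]), simple_analyte)
        with pytest.raises(ValueError):
            back_calculate(fit, 10.0, 0.0)


class TestIonRatio:
    @pytest.mark.parametrize(
        "quant,qual,expected", [(100.0, 50.0, 2.0), (77.0, 77.0, 1.0), (52.0, 100.0, 0.52)]
    )
    def test_quantifier_over_qualifier(self, quant, qual, expected):
        assert ion_ratio(quant, qual) == pytest.approx(expected)

    def test_missing_qualifier_is_not_applicable(self):
        assert ion_ratio(100.0, None) is None
        assert ion_ratio(100.0, float("nan")) is None

    def test_zero_qualifier_errors(self):
        with pytest.raises(ValueError):
            ion_ratio(100.0, 0.0)

    def test_mean_ratio_converges_to_truth(self):
        # configured truth ratio 0.52 at 5 % noise: mean of 100 injections
        # recovers it within ±0.01
        truth = make_truth(ion_ratio=0.52, noise_cv=0.05, istd_cv=0.0)
        design = CampaignDesign(
            calib_levels=(10.0,), n_injection_replicates=100, seed=7, influent_days=()
        )
        injections, _, _ = generate_campaign(truth, design)
        ratios = injections.quant_area / injections.qual_area
        assert ratios.mean() == pytest.approx(0.52, abs=0.01)


class TestIonRatioSummary:
    def make_records(self, ratios, level=10.0):
        return pd.DataFrame(
            {
                "level": level,
                "quant_area": [r * 100.0 for r in ratios],
                "qual_area": 100.0,
            }
        )

    @pytest.mark.parametrize(
        "ratios,expected_within",
        [
            ((1.0, 1.1, 0.9), True),
            ((1.0, 2.0), True),  # deviations ±33 % of mean 1.5
            ((1.0, 3.0), False),  # deviations ±50 % of mean 2.0
        ],
    )
    def test_window_rule_on_band_mean(self, ratios, expected_within):
        s = ion_ratio_summary(self.make_records(ratios), "low", iql=0.1)
        assert s.within_window is expected_within

    def test_mean_and_sd(self):
        s = ion_ratio_summary(self.make_records((1.0, 1.1, 0.9)), "low", iql=0.1)
        assert s.mean == pytest.approx(1.0)
        assert s.sd == pytest.approx(0.1, rel=1e-9)

    def test_constant_ratios_have_zero_sd(self):
        s = ion_ratio_summary(self.make_records((1.3, 1.3, 1.3)), "low", iql=0.1)
        assert s.sd == 0.0 and s.within_window

    def test_band_split_at_100(self):
        records = pd.concat(
            [self.make_records((1.0, 1.0), level=50.0), self.make_records((2.0, 2.0), level=500.0)],
            ignore_index=True,
        )
        low = ion_ratio_summary(records, "low", iql=0.1)
        high = ion_ratio_summary(records, "high", iql=0.1)
        assert low.mean == pytest.approx(1.0) and low.n == 2
        assert high.mean == pytest.approx(2.0) and high.n == 2

    def test_empty_band_is_absent(self):
        s = ion_ratio_summary(self.make_records((1.0, 1.1), level=500.0), "low", iql=0.1)
        assert s is None


class TestRelativeRetentionTime:
    @pytest.mark.parametrize(
        "rt,rt_istd,expected", [(7.80, 7.80, 1.00), (10.55, 5.36, 1.97), (0.75 * 8.0, 8.0, 0.75)]
    )
    def test_ratio(self, rt, rt_istd, expected):
        assert relative_retention_time(rt, rt_istd) == pytest.approx(expected, abs=0.005)

    def test_requires_positive_times(self):
        with pytest.raises(ValueError):
            relative_retention_time(0.0, 5.0)
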