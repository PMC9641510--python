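"""Lifestyle component: RR-to-years conversion, banding, offset tables."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lifeage import (
    ActivityReport,
    ConfigError,
    InputError,
    LifestyleCategories,
    LifestyleOffsetsConfig,
    categorize_profile,
    lifestyle_offset,
    rr_to_years,
)
from lifeage.config import CATEGORIES, FACTORS

from conftest import make_profile

OPTIMAL = LifestyleCategories("<23", "never", "none_low", "optimal", "high")
WORST = LifestyleCategories(">=40", "current", "binge", "poor", "sedentary")
REFERENCE = LifestyleCategories("23-24.9", "ex", "moderate", "average", "moderate")


class TestRRToYears:
    def test_unit_risk_is_zero_years(self):
        assert rr_to_years(1.0, 0.05) == 0.0

    def test_doubling_risk_at_default_slope(self):
        assert rr_to_years(2.0, 0.0866) == pytest.approx(8.004, abs=1e-3)

    def test_protective_risk_is_antisymmetric(self):
        assert rr_to_years(0.5, 0.0866) == pytest.approx(-rr_to_years(2.0, 0.0866))

    @pytest.mark.parametrize("rr, b", [(0.0, 0.1), (-1.0, 0.1), (2.0, 0.0), (2.0, -0.1)])
    def test_domain_errors(self, rr, b):
        with pytest.raises(InputError):
            rr_to_years(rr, b)

    @given(
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=0.01, max_value=0.2),
    )
    def test_log_additivity(self, rr1, rr2, b):
        assert rr_to_years(rr1 * rr2, b) == pytest.approx(
            rr_to_years(rr1, b) + rr_to_years(rr2, b), rel=1e-9, abs=1e-12
        )


class TestCategorize:
    @pytest.mark.parametrize(
        "bmi, band",
        [(22.0, "<23"), (23.0, "23-24.9"), (24.9, "23-24.9"), (25.0, "25-29.9"),
         (32.0, "30-39.9"), (40.0, ">=40"), (42.0, ">=40")],
    )
    def test_bmi_bands(self, bmi, band):
        assert categorize_profile(make_profile(bmi=bmi)).bmi_band == band

    def test_bmi_computed_from_height_weight(self):
        profile = make_profile(bmi=None, height_m=1.70, weight_kg=63.0)  # BMI 21.8
        assert categorize_profile(profile).bmi_band == "<23"

    def test_missing_bmi_and_height_weight_errors(self):
        with pytest.raises(Exception, match="BMI"):
            categorize_profile(make_profile(bmi=None))

    @pytest.mark.parametrize(
        "units, binge, band",
        [(10.0, False, "none_low"), (13.9, False, "none_low"), (14.0, False, "moderate"),
         (0.0, True, "binge"), (30.0, False, "moderate")],
    )
    def test_alcohol_bands(self, units, binge, band):
        profile = make_profile(alcohol_units_per_week=units, binge=binge)
        assert categorize_profile(profile).alcohol_band == band

    @pytest.mark.parametrize(
        "score, band",
        [(14, "optimal"), (10, "optimal"), (9, "average"), (7, "average"), (6, "poor"), (0, "poor")],
    )
    def test_diet_bands_follow_mediterranean_score(self, score, band):
        assert categorize_profile(make_profile(diet_score=score)).diet_band == band

    @pytest.mark.parametrize(
        "met_h, band",
        [(0.0, "sedentary"), (5.0, "low"), (10.0, "moderate"), (19.9, "moderate"), (20.0, "high")],
    )
    def test_activity_bands(self, met_h, band):
        profile = make_profile(activity=ActivityReport(met_hours_per_week=met_h))
        assert categorize_profile(profile).activity_band == band

    def test_unknown_smoking_category_rejected(self):
        with pytest.raises(InputError, match="smoking"):
            categorize_profile(make_profile(smoking="pipe"))


class TestOffsets:
    def test_optimal_profile_sums_to_minus_six(self, config):
        total, breakdown = lifestyle_offset(OPTIMAL, config)
        assert total == -6.0
        assert total == sum(breakdown.values())

    def test_worst_profile_sums_to_plus_28(self, config):
        total, breakdown = lifestyle_offset(WORST, config)
        assert total == 28.0
        assert total == sum(breakdown.values())

    def test_reference_categories_sum_to_zero(self, config):
        total, breakdown = lifestyle_offset(REFERENCE, config)
        assert total == 0.0
        assert all(v == 0.0 for v in breakdown.values())

    def test_monotone_within_each_factor(self, config):
        # categories are declared healthiest -> least healthy
        for factor in FACTORS:
            offsets = [config.offset(factor, cat) for cat in CATEGORIES[factor]]
            assert offsets == sorted(offsets), factor

    def test_missing_category_names_factor_and_category(self, config):
        bad = {f: dict(config.offsets[f]) for f in FACTORS}
        del bad["diet"]["poor"]
        with pytest.raises(ConfigError, match="diet.*poor"):
            LifestyleOffsetsConfig(version="user-bad", offsets=bad)

    def test_rr_table_round_trips_to_years_table(self, config):
        b = config.gompertz_slope
        rr = {
            factor: {cat: math.exp(b * years) for cat, years in table.items()}
            for factor, table in config.offsets.items()
        }
        derived = LifestyleOffsetsConfig(
            version="user-rr", offsets={}, relative_risks=rr, gompertz_slope=b
        )
        for factor in FACTORS:
            for cat in CATEGORIES[factor]:
                assert derived.offset(factor, cat) == pytest.approx(
                    config.offset(factor, cat), abs=1e-9
                )
        for cats in (OPTIMAL, WORST, REFERENCE):
            assert lifestyle_offset(cats, derived)[0] == pytest.approx(
                lifestyle_offset(cats, config)[0], abs=1e-9
            )

    def test_default_table_without_reference_category_rejected(self):
        bad = {
            "bmi": {"<23": -1.0, "23-24.9": 0.5, "25-29.9": 2.0, "30-39.9": 4.0, ">=40": 8.0},
            "smoking": {"never": -2.0, "ex": 0.0, "current": 8.0},
            "alcohol": {"none_low": -1.0, "moderate": 0.0, "binge": 4.0},
            "diet": {"optimal": -1.0, "average": 0.0, "poor": 4.0},
            "activity": {"high": -1.0, "moderate": 0.0, "low": 2.0, "sedentary": 4.0},
        }
        with pytest.raises(ConfigError, match="reference"):
            LifestyleOffsetsConfig(version="user-noref", offsets=bad)
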