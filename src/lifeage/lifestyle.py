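"""Lifestyle effective-age component.

Five modifiable all-cause-mortality factors — body weight (BMI band), smoking,
alcohol, Mediterranean-diet adherence and physical activity — each contribute
a signed offset in years.  Offsets come from a configuration table, or are
derived from relative risks via the effective-age identity: under a Gompertz
adult hazard a·exp(b·t), a hazard ratio RR is equivalent to an age shift of
ln(RR)/b years, so risk multipliers become additive year offsets.  The five
offsets are summed with no interaction terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

from .config import CATEGORIES, FACTORS, CategoryThresholds, LifestyleOffsetsConfig
from .errors import InputError, MissingDataError

if TYPE_CHECKING:  # pragma: no cover
    from .engine import ParticipantProfile

__all__ = ["LifestyleCategories", "rr_to_years", "categorize_profile", "lifestyle_offset"]


@dataclass(frozen=True)
class LifestyleCategories:
    """One category per lifestyle factor."""

    bmi_band: str
    smoking: str
    alcohol_band: str
    diet_band: str
    activity_band: str

    def __post_init__(self) -> None:
        for factor, value in self.as_dict().items():
            if value not in CATEGORIES[factor]:
                raise InputError(
                    f"unknown category {value!r} for factor {factor!r}; "
                    f"expected one of {CATEGORIES[factor]}"
                )

    def as_dict(self) -> dict[str, str]:
        return {
            "bmi": self.bmi_band,
            "smoking": self.smoking,
            "alcohol": self.alcohol_band,
            "diet": self.diet_band,
            "activity": self.activity_band,
        }


def rr_to_years(rr: float, b: float) -> float:
    """Convert a relative risk into an effective-age shift in years.

    Under a Gompertz hazard a·exp(b·t), multiplying the hazard by ``rr``
    equals advancing age by ln(rr)/b years; protective risks (rr < 1) give
    negative years.  Log-additive: rr_to_years(r1*r2, b) equals the sum of
    the individual conversions.
    """
    if rr <= 0:
        raise InputError(f"relative risk must be > 0, got {rr}")
    if b <= 0:
        raise InputError(f"Gompertz slope must be > 0, got {b}")
    return math.log(rr) / b


def _bmi_band(bmi: float, edges: tuple[float, ...]) -> str:
    if bmi <= 0 or not math.isfinite(bmi):
        raise InputError(f"BMI must be a positive finite number, got {bmi}")
    e23, e25, e30, e40 = edges
    if bmi < e23:
        return "<23"
    if bmi < e25:
        return "23-24.9"
    if bmi < e30:
        return "25-29.9"
    if bmi < e40:
        return "30-39.9"
    return ">=40"


def _alcohol_band(units_per_week: float | None, binge: bool, low_max: float) -> str:
    if binge:
        return "binge"
    if units_per_week is None:
        raise MissingDataError("alcohol units per week required (or a binge flag)")
    if units_per_week < 0:
        raise InputError(f"alcohol units must be non-negative, got {units_per_week}")
    return "none_low" if units_per_week < low_max else "moderate"


def _diet_band(score: int, optimal_min: int, poor_max: int) -> str:
    if not 0 <= score <= 14:
        raise InputError(f"diet score must be in [0, 14], got {score}")
    if score >= optimal_min:
        return "optimal"
    if score <= poor_max:
        return "poor"
    return "average"


def _activity_band(met_hours_per_week: float, moderate_min: float, high_min: float) -> str:
    if met_hours_per_week < 0:
        raise InputError(f"MET·hours must be non-negative, got {met_hours_per_week}")
    if met_hours_per_week == 0:
        return "sedentary"
    if met_hours_per_week >= high_min:
        return "high"
    if met_hours_per_week >= moderate_min:
        return "moderate"
    return "low"


def categorize_profile(
    profile: "ParticipantProfile", thresholds: CategoryThresholds | None = None
) -> LifestyleCategories:
    """Band a participant's raw lifestyle measurements into factor categories.

    BMI is taken directly or computed as weight/height² when only height and
    weight are given; smoking maps through unchanged; alcohol is "binge" when
    any binge episode is flagged, otherwise banded at the 14-unit weekly
    boundary; the diet band follows the Mediterranean score; activity is
    banded on weekly MET·hours (0 = sedentary).
    """
    thresholds = thresholds or CategoryThresholds()
    if profile.smoking is None:
        raise MissingDataError("smoking status required")
    if profile.smoking not in CATEGORIES["smoking"]:
        raise InputError(
            f"unknown smoking category {profile.smoking!r}; expected one of {CATEGORIES['smoking']}"
        )
    return LifestyleCategories(
        bmi_band=_bmi_band(profile.resolved_bmi(), thresholds.bmi_edges),
        smoking=profile.smoking,
        alcohol_band=_alcohol_band(
            profile.alcohol_units_per_week, profile.binge, thresholds.alcohol_low_max_units
        ),
        diet_band=_diet_band(
            profile.resolved_diet_score(), thresholds.diet_optimal_min, thresholds.diet_poor_max
        ),
        activity_band=_activity_band(
            profile.resolved_met_hours(),
            thresholds.activity_moderate_min_met_hours,
            thresholds.activity_high_min_met_hours,
        ),
    )


def lifestyle_offset(
    categories: LifestyleCategories, config: LifestyleOffsetsConfig
) -> tuple[float, dict[str, float]]:
    """Total lifestyle years plus the per-factor breakdown.

    The total is the exact sum of the five factor offsets; a category absent
    from the configuration raises :class:`~lifeage.errors.ConfigError` naming
    the factor and category.
    """
    cats = categories.as_dict()
    breakdown = {factor: config.offset(factor, cats[factor]) for factor in FACTORS}
    return sum(breakdown.values()), breakdown
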