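"""Questionnaire scoring: Mediterranean diet, mood, life satisfaction, stress, activity.

Each instrument is represented by a small immutable response container that
validates itself on construction, and a scorer that reduces the responses to
the scalar used downstream (by the effective-age components and by the
pre/post evaluation).  Scorers reject out-of-range responses instead of
clipping: a rating of 6 on a 1-5 scale is a data error, not an extreme value.

Instruments
-----------
* **Mediterranean diet** — 14 yes/no criteria (PREDIMED adherence screener);
  the score is the count of criteria met, banded into low (<=7) / high (>=8)
  adherence.
* **Mood** — 10 positive-affect and 10 negative-affect items, each rated 1-5;
  subscale sums range 10-50.  The analysis variable is the *combined* mood,
  positive sum minus negative sum.
* **Life satisfaction** — 5 items rated 1-7 (total 5-35).
* **Perceived stress** — 10 items rated 0-4 with items 4, 5, 7 and 8
  (1-based) reverse-coded (total 0-40).
* **Physical activity** — weekly minutes of moderate/vigorous activity,
  or MET·hours per week directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import InputError, MissingDataError

__all__ = [
    "DietResponses",
    "MoodResponses",
    "SatisfactionResponses",
    "StressResponses",
    "ActivityReport",
    "score_mediterranean_diet",
    "score_mood",
    "combined_mood",
    "score_life_satisfaction",
    "score_perceived_stress",
    "met_hours",
    "meets_activity_guideline",
]

#: PREDIMED band boundary: a score of <=7 is "low" adherence, >=8 "high".
DIET_HIGH_ADHERENCE_MIN = 8

#: Default MET intensities assigned to moderate and vigorous minutes.
MODERATE_MET = 4.0
VIGOROUS_MET = 8.0

#: Weekly activity guideline: minutes of moderate OR vigorous activity.
GUIDELINE_MODERATE_MIN = 150.0
GUIDELINE_VIGOROUS_MIN = 75.0

#: 1-based indices of the reverse-coded perceived-stress items.
STRESS_REVERSE_ITEMS = frozenset({4, 5, 7, 8})


def _check_ratings(items: Sequence[int], n: int, lo: int, hi: int, label: str) -> tuple[int, ...]:
    items = tuple(items)
    if len(items) != n:
        raise InputError(f"{label}: expected exactly {n} items, got {len(items)}")
    for i, v in enumerate(items, start=1):
        if not float(v).is_integer() or not (lo <= int(v) <= hi):
            raise InputError(f"{label}: item {i} is {v!r}, must be an integer in [{lo}, {hi}]")
    return tuple(int(v) for v in items)


@dataclass(frozen=True)
class DietResponses:
    """14 Mediterranean-diet adherence criteria (met / not met)."""

    items: tuple[bool, ...]

    def __init__(self, items: Sequence[bool]):
        items = tuple(items)
        if len(items) != 14:
            raise InputError(f"diet responses: expected exactly 14 items, got {len(items)}")
        for i, v in enumerate(items, start=1):
            if not isinstance(v, (bool,)) and v not in (0, 1):
                raise InputError(f"diet responses: item {i} is {v!r}, must be a definite yes/no")
        object.__setattr__(self, "items", tuple(bool(v) for v in items))


@dataclass(frozen=True)
class MoodResponses:
    """Positive and negative affect items, 10 each, rated 1-5."""

    positive_items: tuple[int, ...]
    negative_items: tuple[int, ...]

    def __init__(self, positive_items: Sequence[int], negative_items: Sequence[int]):
        object.__setattr__(
            self, "positive_items", _check_ratings(positive_items, 10, 1, 5, "positive mood")
        )
        object.__setattr__(
            self, "negative_items", _check_ratings(negative_items, 10, 1, 5, "negative mood")
        )


@dataclass(frozen=True)
class SatisfactionResponses:
    """Five life-satisfaction items rated 1-7 (total 5-35)."""

    items: tuple[int, ...]

    def __init__(self, items: Sequence[int]):
        object.__setattr__(self, "items", _check_ratings(items, 5, 1, 7, "life satisfaction"))


@dataclass(frozen=True)
class StressResponses:
    """Ten perceived-stress items rated 0-4; a fixed subset is reverse-coded.

    With the default reverse set {4, 5, 7, 8} (1-based) the total ranges 0-40,
    higher meaning more perceived stress.
    """

    items: tuple[int, ...]
    reverse_coded: frozenset[int] = field(default=STRESS_REVERSE_ITEMS)

    def __init__(self, items: Sequence[int], reverse_coded: frozenset[int] = STRESS_REVERSE_ITEMS):
        object.__setattr__(self, "items", _check_ratings(items, 10, 0, 4, "perceived stress"))
        reverse = frozenset(int(i) for i in reverse_coded)
        if not all(1 <= i <= 10 for i in reverse):
            raise InputError("perceived stress: reverse-coded indices must be 1-based in [1, 10]")
        object.__setattr__(self, "reverse_coded", reverse)


@dataclass(frozen=True)
class ActivityReport:
    """Weekly physical activity as minutes and/or MET·hours.

    ``met_hours_per_week`` may be supplied directly (it is then authoritative);
    otherwise it is derived from the minutes.  All quantities are per week and
    non-negative.
    """

    moderate_minutes_per_week: float | None = None
    vigorous_minutes_per_week: float | None = None
    met_hours_per_week: float | None = None

    def __post_init__(self) -> None:
        for name in ("moderate_minutes_per_week", "vigorous_minutes_per_week", "met_hours_per_week"):
            v = getattr(self, name)
            if v is not None and (not isinstance(v, (int, float)) or v < 0):
                raise InputError(f"activity report: {name} must be non-negative, got {v!r}")
        if (
            self.met_hours_per_week is None
            and self.moderate_minutes_per_week is None
            and self.vigorous_minutes_per_week is None
        ):
            raise InputError("activity report: provide minutes or MET·hours")
        # Both representations given: they must agree under default intensities.
        if self.met_hours_per_week is not None and (
            self.moderate_minutes_per_week is not None or self.vigorous_minutes_per_week is not None
        ):
            derived = _met_hours_from_minutes(
                self.moderate_minutes_per_week or 0.0, self.vigorous_minutes_per_week or 0.0
            )
            if abs(derived - self.met_hours_per_week) > 0.5:
                raise InputError(
                    "activity report: MET·hours "
                    f"{self.met_hours_per_week:g} inconsistent with minutes (derived {derived:g})"
                )


def score_mediterranean_diet(responses: DietResponses) -> tuple[int, str]:
    """Score the 14-item Mediterranean-diet screener.

    Returns ``(score, band)`` where ``score`` is the number of criteria met
    (0-14) and ``band`` is ``"low"`` for scores <=7 and ``"high"`` for >=8.
    """
    score = sum(responses.items)
    band = "high" if score >= DIET_HIGH_ADHERENCE_MIN else "low"
    return score, band


def score_mood(responses: MoodResponses) -> tuple[int, int]:
    """Return ``(positive_sum, negative_sum)``, each in 10-50."""
    return sum(responses.positive_items), sum(responses.negative_items)


def combined_mood(positive: float, negative: float) -> float:
    """Combined mood = positive mood + (negative mood x -1).

    Accepts floats so it can be applied to cohort means as well as individual
    subscale sums.  With subscale sums in 10-50 the result lies in [-40, 40].
    """
    if positive is None or negative is None:  # type: ignore[comparison-overlap]
        raise MissingDataError("combined mood requires both subscale scores")
    return positive - negative


def score_life_satisfaction(responses: SatisfactionResponses) -> int:
    """Sum of the five satisfaction items (5-35, higher = more satisfied)."""
    return sum(responses.items)


def score_perceived_stress(responses: StressResponses) -> int:
    """Sum of the ten stress items with reverse-coded items inverted (0-40)."""
    return sum(
        (4 - v) if (i in responses.reverse_coded) else v
        for i, v in enumerate(responses.items, start=1)
    )


def _met_hours_from_minutes(
    moderate: float, vigorous: float, m_mod: float = MODERATE_MET, m_vig: float = VIGOROUS_MET
) -> float:
    return (moderate * m_mod + vigorous * m_vig) / 60.0


def met_hours(
    report: ActivityReport, m_mod: float = MODERATE_MET, m_vig: float = VIGOROUS_MET
) -> float:
    """Weekly MET·hours for an activity report.

    A directly supplied ``met_hours_per_week`` passes through unchanged;
    otherwise minutes are weighted by the MET intensities (defaults 4.0
    moderate, 8.0 vigorous) and divided by 60.
    """
    if report.met_hours_per_week is not None:
        return float(report.met_hours_per_week)
    return _met_hours_from_minutes(
        report.moderate_minutes_per_week or 0.0,
        report.vigorous_minutes_per_week or 0.0,
        m_mod,
        m_vig,
    )


def meets_activity_guideline(report: ActivityReport, equivalent_minutes: bool = False) -> bool:
    """Whether the weekly activity guideline is met.

    Default rule: at least 150 moderate-intensity minutes OR at least 75
    vigorous-intensity minutes per week.  With ``equivalent_minutes=True`` a
    blended rule is used instead: moderate + 2 x vigorous >= 150.
    """
    if report.moderate_minutes_per_week is None and report.vigorous_minutes_per_week is None:
        raise MissingDataError("guideline check requires weekly minutes, not MET·hours alone")
    mod = report.moderate_minutes_per_week or 0.0
    vig = report.vigorous_minutes_per_week or 0.0
    if equivalent_minutes:
        return mod + 2.0 * vig >= GUIDELINE_MODERATE_MIN
    return mod >= GUIDELINE_MODERATE_MIN or vig >= GUIDELINE_VIGOROUS_MIN
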