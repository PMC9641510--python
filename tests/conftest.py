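import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from lifeage import (  # noqa: E402
    ActivityReport,
    ParticipantProfile,
    default_lifestyle_config,
    default_population_norms,
)


@pytest.fixture(scope="session")
def config():
    return default_lifestyle_config()


@pytest.fixture(scope="session")
def norms():
    return default_population_norms()


def make_profile(**overrides) -> ParticipantProfile:
    """A fully reference-category, at-norm participant; override fields as needed.

    Every lifestyle factor sits in its zero-offset category (BMI 24,
    ex-smoker, 20 units/week, diet score 8, 15 MET·h/week) and every
    psychosocial domain sits at its population norm (satisfaction 24,
    combined mood 15, stress 16, sleep 7 h), so the Life Age delta is 0.
    """
    fields = dict(
        id="ref",
        chronological_age=37.0,
        sex="female",
        bmi=24.0,
        smoking="ex",
        alcohol_units_per_week=20.0,
        binge=False,
        activity=ActivityReport(met_hours_per_week=15.0),
        diet_score=8,
        positive_mood=35.0,
        negative_mood=20.0,
        life_satisfaction=24.0,
        stress_score=16.0,
        sleep_hours=7.0,
    )
    fields.update(overrides)
    return ParticipantProfile(**fields)


@pytest.fixture
def neutral_profile():
    return make_profile()


@pytest.fixture
def optimal_lifestyle_profile():
    """Healthiest category on every lifestyle factor, psychosocial at norm."""
    return make_profile(
        id="optimal",
        bmi=22.0,
        smoking="never",
        alcohol_units_per_week=0.0,
        diet_score=14,
        activity=ActivityReport(met_hours_per_week=40.0),
    )


@pytest.fixture
def worst_profile():
    """Least healthy category on every factor and every psychosocial extreme."""
    return make_profile(
        id="worst",
        bmi=42.0,
        smoking="current",
        binge=True,
        diet_score=2,
        activity=ActivityReport(met_hours_per_week=0.0),
        life_satisfaction=5.0,
        positive_mood=10.0,
        negative_mood=50.0,
        stress_score=40.0,
        sleep_hours=4.0,
    )
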