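"""Life Age assembly: one participant in, a decomposed result out.

Life Age = chronological age + lifestyle years + psychosocial years.  The
lifestyle component sums five effective-age factor offsets (BMI band, smoking,
alcohol, diet, activity); the psychosocial component sums four norm-referenced
domains (life satisfaction, combined mood, stress, sleep), each clipped to
±2 years.  The headline quantity for reporting is the *delta* — Life Age
minus chronological age — which by construction equals the sum of the two
components exactly and does not depend on chronological age.

Two surfaces are provided: plain functions (:func:`compute_life_age`,
:func:`compute_cohort`) over :class:`ParticipantProfile` objects, and
:class:`LifeAgeScorer`, a scikit-learn compatible transformer mapping a
profile DataFrame to a result DataFrame, so the scorer composes with sklearn
pipelines and model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import (
    LifestyleOffsetsConfig,
    PopulationNorms,
    config_hash,
    default_lifestyle_config,
    default_population_norms,
)
from .errors import InputError, LifeAgeError, MissingDataError
from .lifestyle import LifestyleCategories, categorize_profile, lifestyle_offset
from .psychosocial import psychosocial_offset
from .questionnaires import (
    ActivityReport,
    DietResponses,
    MoodResponses,
    SatisfactionResponses,
    StressResponses,
    combined_mood,
    met_hours,
    score_life_satisfaction,
    score_mediterranean_diet,
    score_mood,
    score_perceived_stress,
)

__all__ = ["ParticipantProfile", "LifeAgeResult", "compute_life_age", "compute_cohort", "LifeAgeScorer"]

#: Study inclusion window; ages outside it warn but do not error.
AGE_SOFT_RANGE = (30.0, 60.0)

_BMI_TOL = 0.1  # kg/m² agreement required between a stated BMI and height/weight


def _agree(name: str, given: float, derived: float, tol: float, pid: Any) -> None:
    if abs(given - derived) > tol:
        raise InputError(
            f"participant {pid!r}: {name} given as {given:g} conflicts with value "
            f"{derived:g} derived from raw responses/measurements"
        )


@dataclass(frozen=True)
class ParticipantProfile:
    """One participant's measurements at a single timepoint.

    Raw questionnaire responses and precomputed scores may both be supplied;
    when both are present they must agree (no silent precedence).  Waist
    circumference and sex are carried through for reporting only — neither
    enters any score under the default configuration.
    """

    id: Any
    chronological_age: float
    sex: str | None = None
    height_m: float | None = None
    weight_kg: float | None = None
    bmi: float | None = None
    waist_cm: float | None = None
    smoking: str | None = None
    alcohol_units_per_week: float | None = None
    binge: bool = False
    activity: ActivityReport | None = None
    diet: DietResponses | None = None
    diet_score: int | None = None
    mood: MoodResponses | None = None
    positive_mood: float | None = None
    negative_mood: float | None = None
    satisfaction: SatisfactionResponses | None = None
    life_satisfaction: float | None = None
    stress: StressResponses | None = None
    stress_score: float | None = None
    sleep_hours: float | None = None

    def __post_init__(self) -> None:
        if self.chronological_age is None or not self.chronological_age > 0:
            raise InputError(f"participant {self.id!r}: age must be positive")
        if not AGE_SOFT_RANGE[0] <= self.chronological_age <= AGE_SOFT_RANGE[1]:
            warnings.warn(
                f"participant {self.id!r}: age {self.chronological_age:g} outside the "
                f"{AGE_SOFT_RANGE[0]:g}-{AGE_SOFT_RANGE[1]:g} study window",
                stacklevel=2,
            )
        if self.bmi is not None and not self.bmi > 0:
            raise InputError(f"participant {self.id!r}: BMI must be positive")

    # -- score resolution (raw responses vs precomputed, with agreement checks)

    def resolved_bmi(self) -> float:
        derived = None
        if self.height_m is not None and self.weight_kg is not None:
            if self.height_m <= 0 or self.weight_kg <= 0:
                raise InputError(f"participant {self.id!r}: height and weight must be positive")
            derived = self.weight_kg / self.height_m**2
        if self.bmi is not None:
            if derived is not None:
                _agree("BMI", self.bmi, derived, _BMI_TOL, self.id)
            return float(self.bmi)
        if derived is None:
            raise MissingDataError(f"participant {self.id!r}: BMI or height+weight required")
        return derived

    def resolved_diet_score(self) -> int:
        derived = score_mediterranean_diet(self.diet)[0] if self.diet is not None else None
        if self.diet_score is not None:
            if derived is not None and derived != self.diet_score:
                _agree("diet score", self.diet_score, derived, 0, self.id)
            if not 0 <= self.diet_score <= 14:
                raise InputError(f"participant {self.id!r}: diet score must be in [0, 14]")
            return int(self.diet_score)
        if derived is None:
            raise MissingDataError(f"participant {self.id!r}: diet responses or score required")
        return derived

    def resolved_mood(self) -> tuple[float, float]:
        derived = score_mood(self.mood) if self.mood is not None else None
        pos, neg = self.positive_mood, self.negative_mood
        if derived is not None:
            if pos is not None:
                _agree("positive mood", pos, derived[0], 1e-9, self.id)
            if neg is not None:
                _agree("negative mood", neg, derived[1], 1e-9, self.id)
            return float(derived[0]), float(derived[1])
        if pos is None or neg is None:
            raise MissingDataError(f"participant {self.id!r}: mood responses or both subscale scores required")
        return float(pos), float(neg)

    def resolved_life_satisfaction(self) -> float:
        derived = (
            score_life_satisfaction(self.satisfaction) if self.satisfaction is not None else None
        )
        if self.life_satisfaction is not None:
            if derived is not None:
                _agree("life satisfaction", self.life_satisfaction, derived, 1e-9, self.id)
            return float(self.life_satisfaction)
        if derived is None:
            raise MissingDataError(f"participant {self.id!r}: satisfaction responses or score required")
        return float(derived)

    def resolved_stress(self) -> float:
        derived = score_perceived_stress(self.stress) if self.stress is not None else None
        if self.stress_score is not None:
            if derived is not None:
                _agree("stress", self.stress_score, derived, 1e-9, self.id)
            return float(self.stress_score)
        if derived is None:
            raise MissingDataError(f"participant {self.id!r}: stress responses or score required")
        return float(derived)

    def resolved_met_hours(self) -> float:
        if self.activity is None:
            raise MissingDataError(f"participant {self.id!r}: activity report required")
        return met_hours(self.activity)

    def resolved_sleep_hours(self) -> float:
        if self.sleep_hours is None:
            raise MissingDataError(f"participant {self.id!r}: sleep hours required")
        return float(self.sleep_hours)


@dataclass(frozen=True)
class LifeAgeResult:
    """Decomposed Life Age for one participant.

    ``delta = life_age - chronological_age = lifestyle_years +
    psychosocial_years`` holds exactly on every result.
    """

    id: Any
    chronological_age: float
    lifestyle_years: float
    psychosocial_years: float
    life_age: float
    delta: float
    categories: LifestyleCategories
    lifestyle_breakdown: dict[str, float] = field(default_factory=dict)
    psychosocial_breakdown: dict[str, float] = field(default_factory=dict)
    config_version: str = ""
    norms_version: str = ""
    config_hash: str = ""

    def __post_init__(self) -> None:
        assert self.delta == self.lifestyle_years + self.psychosocial_years
        assert self.life_age == self.chronological_age + self.delta

    def to_dict(self) -> dict[str, Any]:
        """Flat record suitable for a CSV row; JSON output mirrors it."""
        row: dict[str, Any] = {
            "id": self.id,
            "chronological_age": self.chronological_age,
            "lifestyle_years": self.lifestyle_years,
            "psychosocial_years": self.psychosocial_years,
            "life_age": self.life_age,
            "delta": self.delta,
        }
        for factor, years in self.lifestyle_breakdown.items():
            row[f"lifestyle_{factor}_years"] = years
        for factor, cat in self.categories.as_dict().items():
            row[f"category_{factor}"] = cat
        for domain, years in self.psychosocial_breakdown.items():
            row[f"psychosocial_{domain}_years"] = years
        row["config_version"] = self.config_version
        row["norms_version"] = self.norms_version
        row["config_hash"] = self.config_hash
        return row


def compute_life_age(
    profile: ParticipantProfile,
    config: LifestyleOffsetsConfig | None = None,
    norms: PopulationNorms | None = None,
) -> LifeAgeResult:
    """Score one participant; deterministic for fixed inputs and config."""
    config = config or default_lifestyle_config()
    norms = norms or default_population_norms()
    try:
        categories = categorize_profile(profile, config.thresholds)
        life_years, life_breakdown = lifestyle_offset(categories, config)
        pos, neg = profile.resolved_mood()
        psy_scores = {
            "life_satisfaction": profile.resolved_life_satisfaction(),
            "mood": combined_mood(pos, neg),
            "stress": profile.resolved_stress(),
            "sleep_hours": profile.resolved_sleep_hours(),
        }
        psy_years, psy_breakdown = psychosocial_offset(psy_scores, norms)
    except LifeAgeError as exc:
        if str(exc).startswith(f"participant {profile.id!r}"):
            raise
        raise type(exc)(f"participant {profile.id!r}: {exc}") from exc
    delta = life_years + psy_years
    return LifeAgeResult(
        id=profile.id,
        chronological_age=float(profile.chronological_age),
        lifestyle_years=life_years,
        psychosocial_years=psy_years,
        life_age=float(profile.chronological_age) + delta,
        delta=delta,
        categories=categories,
        lifestyle_breakdown=life_breakdown,
        psychosocial_breakdown=psy_breakdown,
        config_version=config.version,
        norms_version=norms.version,
        config_hash=config_hash(config, norms),
    )


def compute_cohort(
    profiles: Iterable[ParticipantProfile],
    config: LifestyleOffsetsConfig | None = None,
    norms: PopulationNorms | None = None,
) -> tuple[list[LifeAgeResult], list[tuple[Any, str]]]:
    """Order-preserving map of :func:`compute_life_age` over profiles.

    Per-row failures are collected as ``(participant id, message)`` pairs
    rather than aborting the whole cohort.
    """
    results: list[LifeAgeResult] = []
    errors: list[tuple[Any, str]] = []
    for profile in profiles:
        try:
            results.append(compute_life_age(profile, config, norms))
        except LifeAgeError as exc:
            errors.append((profile.id, str(exc)))
    return results, errors


class LifeAgeScorer(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer computing Life Age for profile rows.

    The transformer is stateless in the statistical sense — ``fit`` only
    validates and freezes the configuration (``config_``, ``norms_``,
    ``config_hash_``) — so it slots into sklearn pipelines as a feature
    constructor.  ``transform`` takes a DataFrame with the documented cohort
    columns (see :mod:`lifeage.io`) and returns one result row per input row.

    Parameters
    ----------
    config : LifestyleOffsetsConfig, optional
        Lifestyle offset tables and banding thresholds; shipped default if None.
    norms : PopulationNorms, optional
        Psychosocial norms; shipped default if None.
    on_error : {"raise", "collect"}
        Whether a row that cannot be scored aborts ``transform`` or is
        recorded in ``errors_`` and dropped from the output.
    """

    def __init__(
        self,
        config: LifestyleOffsetsConfig | None = None,
        norms: PopulationNorms | None = None,
        on_error: str = "raise",
    ):
        self.config = config
        self.norms = norms
        self.on_error = on_error

    def fit(self, X: pd.DataFrame | None = None, y: Any = None) -> "LifeAgeScorer":
        if self.on_error not in ("raise", "collect"):
            raise ValueError("on_error must be 'raise' or 'collect'")
        self.config_ = self.config or default_lifestyle_config()
        self.norms_ = self.norms or default_population_norms()
        self.config_.validate()
        self.config_hash_ = config_hash(self.config_, self.norms_)
        self.n_features_in_ = 0 if X is None else X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "config_"):
            raise RuntimeError("LifeAgeScorer is not fitted; call fit() first")
        from .io import profiles_from_frame  # local import to avoid a cycle

        profiles = profiles_from_frame(X)
        if self.on_error == "collect":
            results, errors = compute_cohort(profiles, self.config_, self.norms_)
            self.errors_ = errors
        else:
            results = [compute_life_age(p, self.config_, self.norms_) for p in profiles]
            self.errors_ = []
        return pd.DataFrame([r.to_dict() for r in results])

    def score_one(self, profile: ParticipantProfile) -> LifeAgeResult:
        """Convenience: score a single :class:`ParticipantProfile`."""
        if not hasattr(self, "config_"):
            raise RuntimeError("LifeAgeScorer is not fitted; call fit() first")
        return compute_life_age(profile, self.config_, self.norms_)
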