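"""Psychosocial well-being years: norm-referenced, clipped to ±2 per domain.

Life satisfaction, combined mood and perceived stress are mapped to years by
their distance from a reference-population mean in SD units, at a configurable
years-per-SD slope, sign-flipped so healthier-than-norm is negative (younger),
and clipped to [-2, +2].  Sleep is mapped by absolute deviation from an
optimum (default 7 h/night) — a U-shaped penalty that is never negative —
capped at +2.  Under defaults the four domains together span [-6, +8].
"""

from __future__ import annotations

from typing import Mapping

from .config import DomainNorm, PopulationNorms, SleepNorm
from .errors import InputError, MissingDataError

__all__ = ["domain_years", "sleep_years", "psychosocial_offset"]

CLIP_YEARS = 2.0

#: Domains required by :func:`psychosocial_offset` (sleep enters as hours).
DOMAINS = ("life_satisfaction", "mood", "stress", "sleep_hours")


def domain_years(score: float, norm: DomainNorm) -> float:
    """Years for one norm-referenced domain, clipped to [-2, +2].

    years = clip(-direction · (score - mean)/sd · years_per_sd, -2, +2),
    so a beneficial score above the norm reduces Life Age.
    """
    z = (float(score) - norm.mean) / norm.sd
    years = -norm.beneficial_direction * z * norm.years_per_sd
    return max(-CLIP_YEARS, min(CLIP_YEARS, years))


def sleep_years(hours: float, norm: SleepNorm | None = None) -> float:
    """Years added for deviation from optimal sleep, in [0, +2].

    Both short and long sleep carry risk, so the mapping is symmetric about
    the optimum and never negative; a deviation of 2 h or more (at the
    default 1 year/h slope) hits the +2 cap.
    """
    norm = norm or SleepNorm()
    if not 0 <= float(hours) <= 24:
        raise InputError(f"sleep hours must be in [0, 24], got {hours}")
    return min(CLIP_YEARS, abs(float(hours) - norm.optimum_hours) * norm.years_per_hour_deviation)


def psychosocial_offset(
    scores: Mapping[str, float], norms: PopulationNorms | None = None
) -> tuple[float, dict[str, float]]:
    """Total psychosocial years plus the per-domain breakdown.

    ``scores`` must contain all of ``life_satisfaction``, ``mood`` (the
    combined positive-minus-negative score), ``stress`` and ``sleep_hours``;
    missing domains raise rather than yielding a partial total.
    """
    norms = norms or PopulationNorms()
    missing = [d for d in DOMAINS if scores.get(d) is None]
    if missing:
        raise MissingDataError(f"psychosocial domains missing: {', '.join(missing)}")
    breakdown = {
        "life_satisfaction": domain_years(scores["life_satisfaction"], norms.life_satisfaction),
        "mood": domain_years(scores["mood"], norms.mood),
        "stress": domain_years(scores["stress"], norms.stress),
        "sleep": sleep_years(scores["sleep_hours"], norms.sleep),
    }
    return sum(breakdown.values()), breakdown
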