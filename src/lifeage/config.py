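"""Configuration: lifestyle offset tables, banding thresholds, population norms.

The lifestyle component is driven by a per-factor table mapping categories to
signed year offsets.  The shipped default table is a *calibration*: no
published per-factor relative risks are bundled, the defaults are chosen so
that the best-possible profile (BMI < 23, never-smoker, no/low alcohol,
optimal diet, high activity) sums to -6 years and the worst profile
(BMI >= 40, current smoker, binge drinker, poor diet, sedentary) to
+28 years, with each factor anchored to a zero-offset reference category.
Users may instead supply published relative risks plus a Gompertz slope and
have the offsets derived as ln(RR)/b.

Population norms drive the psychosocial component: per domain a reference
mean, SD, beneficial direction and a years-per-SD slope; sleep is handled
separately by absolute deviation from an optimum.  The shipped norms are
documented placeholders (the reference populations are not bundled) and are
meant to be replaced from local normative data.

Everything here serialises to/from plain dicts and YAML/JSON, and carries a
version string plus a content hash so results can record their provenance.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

__all__ = [
    "FACTORS",
    "CATEGORIES",
    "CategoryThresholds",
    "LifestyleOffsetsConfig",
    "DomainNorm",
    "SleepNorm",
    "PopulationNorms",
    "default_lifestyle_config",
    "default_population_norms",
    "load_config",
    "dump_config",
    "config_hash",
]

#: Default Gompertz log-hazard slope (per year): adult all-cause mortality
#: roughly doubles every 8 years, b = ln(2)/8 ~= 0.0866.
DEFAULT_GOMPERTZ_SLOPE = 0.0866

FACTORS = ("bmi", "smoking", "alcohol", "diet", "activity")

#: Categories per factor, ordered healthiest -> least healthy.
CATEGORIES: dict[str, tuple[str, ...]] = {
    "bmi": ("<23", "23-24.9", "25-29.9", "30-39.9", ">=40"),
    "smoking": ("never", "ex", "current"),
    "alcohol": ("none_low", "moderate", "binge"),
    "diet": ("optimal", "average", "poor"),
    "activity": ("high", "moderate", "low", "sedentary"),
}

# Calibrated default offsets (years). Optimal profile sums to -6, worst to +28.
_DEFAULT_OFFSETS: dict[str, dict[str, float]] = {
    "bmi": {"<23": -1.0, "23-24.9": 0.0, "25-29.9": 2.0, "30-39.9": 4.0, ">=40": 8.0},
    "smoking": {"never": -2.0, "ex": 0.0, "current": 8.0},
    "alcohol": {"none_low": -1.0, "moderate": 0.0, "binge": 4.0},
    "diet": {"optimal": -1.0, "average": 0.0, "poor": 4.0},
    "activity": {"high": -1.0, "moderate": 0.0, "low": 2.0, "sedentary": 4.0},
}

#: (healthiest category, least healthy category) per factor, for the extremes check.
_BEST = {"bmi": "<23", "smoking": "never", "alcohol": "none_low", "diet": "optimal", "activity": "high"}
_WORST = {"bmi": ">=40", "smoking": "current", "alcohol": "binge", "diet": "poor", "activity": "sedentary"}

DEFAULT_EXTREMES = (-6.0, 28.0)


@dataclass(frozen=True)
class CategoryThresholds:
    """Band edges used to map raw measurements onto factor categories.

    BMI edges follow the published profile anchors (<23 best, >=40 worst);
    the 14-unit weekly alcohol boundary separates no/low from moderate
    drinking; diet bands are tied to the 14-item Mediterranean score
    (optimal >= 10, poor <= 6); activity bands are in MET·hours per week,
    with the moderate band starting at the guideline-equivalent 10 MET·h
    (150 moderate-intensity minutes at 4 MET).
    """

    bmi_edges: tuple[float, ...] = (23.0, 25.0, 30.0, 40.0)
    alcohol_low_max_units: float = 14.0
    diet_optimal_min: int = 10
    diet_poor_max: int = 6
    activity_moderate_min_met_hours: float = 10.0
    activity_high_min_met_hours: float = 20.0

    def to_dict(self) -> dict[str, Any]:
        return {
            "bmi_edges": list(self.bmi_edges),
            "alcohol_low_max_units": self.alcohol_low_max_units,
            "diet_optimal_min": self.diet_optimal_min,
            "diet_poor_max": self.diet_poor_max,
            "activity_moderate_min_met_hours": self.activity_moderate_min_met_hours,
            "activity_high_min_met_hours": self.activity_high_min_met_hours,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CategoryThresholds":
        d = dict(d)
        if "bmi_edges" in d:
            d["bmi_edges"] = tuple(float(x) for x in d["bmi_edges"])
        return cls(**d)


@dataclass(frozen=True)
class LifestyleOffsetsConfig:
    """Per-factor category -> years offsets, or relative risks to derive them.

    If ``relative_risks`` is given (category -> all-cause mortality RR per
    factor) the year offsets are derived as ln(RR)/gompertz_slope; an explicit
    ``offsets`` table always takes precedence.
    """

    version: str = "default-calibrated-1"
    offsets: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {f: dict(t) for f, t in _DEFAULT_OFFSETS.items()}
    )
    relative_risks: Mapping[str, Mapping[str, float]] | None = None
    gompertz_slope: float = DEFAULT_GOMPERTZ_SLOPE
    thresholds: CategoryThresholds = field(default_factory=CategoryThresholds)

    def __post_init__(self) -> None:
        if self.gompertz_slope <= 0:
            raise ConfigError(f"gompertz_slope must be > 0, got {self.gompertz_slope}")
        if not self.offsets and self.relative_risks is None:
            raise ConfigError("config must supply offsets or relative_risks")
        if not self.offsets and self.relative_risks is not None:
            derived = {
                factor: {
                    cat: math.log(rr) / self.gompertz_slope for cat, rr in table.items()
                }
                for factor, table in self.relative_risks.items()
            }
            object.__setattr__(self, "offsets", derived)
        self.validate()

    def validate(self) -> None:
        """Structural validation; the -6/+28 extremes check applies to the default table."""
        for factor in FACTORS:
            if factor not in self.offsets:
                raise ConfigError(f"offset table missing factor {factor!r}")
            table = self.offsets[factor]
            for cat in CATEGORIES[factor]:
                if cat not in table:
                    raise ConfigError(f"offset table for factor {factor!r} missing category {cat!r}")
            if not any(abs(v) < 1e-12 for v in table.values()):
                raise ConfigError(f"factor {factor!r} has no reference category with offset 0")
        best = sum(self.offsets[f][_BEST[f]] for f in FACTORS)
        worst = sum(self.offsets[f][_WORST[f]] for f in FACTORS)
        if self.version.startswith("default"):
            if not (math.isclose(best, DEFAULT_EXTREMES[0]) and math.isclose(worst, DEFAULT_EXTREMES[1])):
                raise ConfigError(
                    f"default table extremes must be {DEFAULT_EXTREMES}, got ({best}, {worst})"
                )
        elif not (math.isclose(best, DEFAULT_EXTREMES[0]) and math.isclose(worst, DEFAULT_EXTREMES[1])):
            warnings.warn(
                f"user offset table extremes ({best:+g}, {worst:+g}) differ from the "
                f"calibrated ({DEFAULT_EXTREMES[0]:+g}, {DEFAULT_EXTREMES[1]:+g})",
                stacklevel=2,
            )

    def offset(self, factor: str, category: str) -> float:
        try:
            table = self.offsets[factor]
        except KeyError:
            raise ConfigError(f"no offset table for factor {factor!r}") from None
        try:
            return float(table[category])
        except KeyError:
            raise ConfigError(
                f"factor {factor!r} has no offset for category {category!r}"
            ) from None

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "version": self.version,
            "offsets": {f: dict(t) for f, t in self.offsets.items()},
            "gompertz_slope": self.gompertz_slope,
            "thresholds": self.thresholds.to_dict(),
        }
        if self.relative_risks is not None:
            d["relative_risks"] = {f: dict(t) for f, t in self.relative_risks.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "LifestyleOffsetsConfig":
        kwargs: dict[str, Any] = {
            "version": d.get("version", "user"),
            "offsets": {f: dict(t) for f, t in d.get("offsets", {}).items()},
            "relative_risks": (
                {f: dict(t) for f, t in d["relative_risks"].items()}
                if d.get("relative_risks")
                else None
            ),
            "gompertz_slope": float(d.get("gompertz_slope", DEFAULT_GOMPERTZ_SLOPE)),
        }
        if "thresholds" in d:
            kwargs["thresholds"] = CategoryThresholds.from_dict(d["thresholds"])
        return cls(**kwargs)


@dataclass(frozen=True)
class DomainNorm:
    """Reference distribution for one psychosocial domain.

    ``beneficial_direction`` is +1 when higher scores are healthier
    (satisfaction, mood) and -1 when higher scores are worse (stress);
    ``years_per_sd`` is the slope of the score-to-years mapping.
    """

    mean: float
    sd: float
    beneficial_direction: int
    years_per_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigError(f"norm SD must be > 0, got {self.sd}")
        if self.years_per_sd <= 0:
            raise ConfigError(f"years_per_sd must be > 0, got {self.years_per_sd}")
        if self.beneficial_direction not in (-1, 1):
            raise ConfigError("beneficial_direction must be +1 or -1")


@dataclass(frozen=True)
class SleepNorm:
    """U-shaped sleep mapping: years per hour of deviation from the optimum."""

    optimum_hours: float = 7.0
    years_per_hour_deviation: float = 1.0

    def __post_init__(self) -> None:
        if self.years_per_hour_deviation <= 0:
            raise ConfigError("years_per_hour_deviation must be > 0")


@dataclass(frozen=True)
class PopulationNorms:
    """Norms for the psychosocial domains plus the sleep optimum.

    The shipped defaults are placeholders standing in for unpublished
    reference-population statistics; replace them with local norms when
    available.
    """

    version: str = "default-placeholder-1"
    life_satisfaction: DomainNorm = field(
        default_factory=lambda: DomainNorm(mean=24.0, sd=6.0, beneficial_direction=1)
    )
    mood: DomainNorm = field(
        default_factory=lambda: DomainNorm(mean=15.0, sd=10.0, beneficial_direction=1)
    )
    stress: DomainNorm = field(
        default_factory=lambda: DomainNorm(mean=16.0, sd=7.0, beneficial_direction=-1)
    )
    sleep: SleepNorm = field(default_factory=SleepNorm)

    def domain(self, name: str) -> DomainNorm:
        try:
            norm = getattr(self, name)
        except AttributeError:
            raise ConfigError(f"no norms defined for domain {name!r}") from None
        if not isinstance(norm, DomainNorm):
            raise ConfigError(f"no norms defined for domain {name!r}")
        return norm

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"version": self.version}
        for name in ("life_satisfaction", "mood", "stress"):
            n: DomainNorm = getattr(self, name)
            out[name] = {
                "mean": n.mean,
                "sd": n.sd,
                "beneficial_direction": n.beneficial_direction,
                "years_per_sd": n.years_per_sd,
            }
        out["sleep"] = {
            "optimum_hours": self.sleep.optimum_hours,
            "years_per_hour_deviation": self.sleep.years_per_hour_deviation,
        }
        return out

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PopulationNorms":
        kwargs: dict[str, Any] = {"version": d.get("version", "user")}
        for name in ("life_satisfaction", "mood", "stress"):
            if name in d:
                kwargs[name] = DomainNorm(**d[name])
        if "sleep" in d:
            kwargs["sleep"] = SleepNorm(**d["sleep"])
        return cls(**kwargs)


def default_lifestyle_config() -> LifestyleOffsetsConfig:
    """The shipped, calibrated default offset table (version-tagged)."""
    return LifestyleOffsetsConfig()


def default_population_norms() -> PopulationNorms:
    """The shipped placeholder norms (version-tagged)."""
    return PopulationNorms()


def config_hash(*configs: LifestyleOffsetsConfig | PopulationNorms) -> str:
    """Short content hash over the canonical JSON of one or more config objects."""
    payload = json.dumps([c.to_dict() for c in configs], sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path) -> tuple[LifestyleOffsetsConfig, PopulationNorms]:
    """Load (lifestyle config, population norms) from a YAML or JSON file.

    The file has two top-level sections, ``lifestyle`` and ``norms``; either
    may be omitted, in which case the shipped default is used.  The loaded
    objects are fully validated (a default-versioned table must reproduce the
    -6/+28 extremes; user tables get a warning if they do not).
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: expected a mapping with 'lifestyle'/'norms' sections")
    config = (
        LifestyleOffsetsConfig.from_dict(data["lifestyle"])
        if "lifestyle" in data
        else default_lifestyle_config()
    )
    norms = (
        PopulationNorms.from_dict(data["norms"]) if "norms" in data else default_population_norms()
    )
    return config, norms


def dump_config(
    config: LifestyleOffsetsConfig, norms: PopulationNorms, path: str | Path
) -> None:
    """Write both config sections to a YAML (or, by suffix, JSON) file."""
    path = Path(path)
    data = {"lifestyle": config.to_dict(), "norms": norms.to_dict()}
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
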