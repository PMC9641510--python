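"""Cohort table IO, result writers, and the frame -> profile bridge.

Cohort tables are plain CSV (UTF-8, comma-separated, header row, ``.``
decimal separator, missing = empty cell — never zero) or JSON arrays of
records.  One row is one participant at one timepoint; baseline and
follow-up live in separate files.  Unknown columns are preserved on read and
ignored by scoring.

Column dictionary (units fixed by the schema):

===================  =======================================================
column               meaning
===================  =======================================================
id                   participant identifier (unique per file)
age                  chronological age, years
sex                  ``female`` / ``male`` (reporting only)
height_m             height, metres
weight_kg            body weight, kg
bmi                  body-mass index, kg/m² (optional if height+weight given)
waist_cm             waist circumference, cm (reporting only)
smoking              ``never`` / ``ex`` / ``current``
alcohol_units        weekly alcohol, UK units
binge                any binge episode in a typical week (true/false)
moderate_minutes     weekly moderate-intensity activity, minutes
vigorous_minutes     weekly vigorous-intensity activity, minutes
met_hours            weekly activity, MET·hours (overrides minutes)
diet_score           Mediterranean diet score 0-14
diet_item_1..14      per-criterion yes/no (alternative to diet_score)
positive_mood        positive-affect sum 10-50
negative_mood        negative-affect sum 10-50
*_mood_item_1..10    raw mood ratings 1-5 (alternative to the sums)
life_satisfaction    satisfaction sum 5-35
satisfaction_item_*  raw ratings 1-7
stress               perceived stress sum 0-40
stress_item_1..10    raw ratings 0-4 (reverse-coded items stored as answered)
sleep_hours          typical nightly sleep, hours
===================  =======================================================
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .engine import LifeAgeResult, ParticipantProfile
from .errors import InputError
from .questionnaires import (
    ActivityReport,
    DietResponses,
    MoodResponses,
    SatisfactionResponses,
    StressResponses,
)

__all__ = ["read_cohort", "write_results", "profiles_from_frame", "write_cohort"]

_BMI_TOL = 0.1


def _is_missing(v: Any) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    if isinstance(v, str) and v.strip() == "":
        return True
    return False


def _opt_float(row: pd.Series, col: str) -> float | None:
    if col not in row.index or _is_missing(row[col]):
        return None
    return float(row[col])


def _opt_str(row: pd.Series, col: str) -> str | None:
    if col not in row.index or _is_missing(row[col]):
        return None
    return str(row[col])


def _opt_bool(row: pd.Series, col: str) -> bool:
    if col not in row.index or _is_missing(row[col]):
        return False
    v = row[col]
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes", "y")
    return bool(v)


def _item_block(row: pd.Series, prefix: str, n: int) -> list[int] | None:
    cols = [f"{prefix}_{i}" for i in range(1, n + 1)]
    if not all(c in row.index for c in cols):
        return None
    vals = [row[c] for c in cols]
    if any(_is_missing(v) for v in vals):
        return None  # missing items are missing, never zeros
    return [int(v) for v in vals]


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort table from CSV or (by suffix) JSON.

    Rows are validated structurally: the ``id`` column must exist and be
    unique, and a stated BMI must agree with height/weight when all three are
    present.  Malformed rows are reported with their position; an empty file
    yields an empty table.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text() or "[]")
        df = pd.DataFrame.from_records(records)
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            df = pd.DataFrame()
    if not len(df):
        return df
    if "id" not in df.columns:
        raise InputError(f"{path}: cohort table must have an 'id' column")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise InputError(f"{path}: duplicate participant ids: {dups}")
    for i, row in df.iterrows():
        bmi, h, w = _opt_float(row, "bmi"), _opt_float(row, "height_m"), _opt_float(row, "weight_kg")
        if bmi is not None and h is not None and w is not None:
            derived = w / h**2
            if abs(bmi - derived) > _BMI_TOL:
                raise InputError(
                    f"{path}: row {i + 2} (id {row['id']!r}): BMI {bmi:g} inconsistent "
                    f"with height/weight (derived {derived:.2f})"
                )
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV or (by suffix) JSON records."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2, default=str))
    else:
        df.to_csv(path, index=False)


def profiles_from_frame(df: pd.DataFrame) -> list[ParticipantProfile]:
    """Build :class:`ParticipantProfile` objects from cohort rows.

    Raw item columns, when fully present, are parsed into response objects so
    the engine can cross-check them against any precomputed score columns.
    """
    if len(df) and "id" not in df.columns:
        raise InputError("cohort frame must have an 'id' column")
    profiles: list[ParticipantProfile] = []
    for _, row in df.iterrows():
        diet_items = _item_block(row, "diet_item", 14)
        pos_items = _item_block(row, "positive_mood_item", 10)
        neg_items = _item_block(row, "negative_mood_item", 10)
        sat_items = _item_block(row, "satisfaction_item", 5)
        stress_items = _item_block(row, "stress_item", 10)
        mod_min = _opt_float(row, "moderate_minutes")
        vig_min = _opt_float(row, "vigorous_minutes")
        met_h = _opt_float(row, "met_hours")
        activity = None
        if met_h is not None or mod_min is not None or vig_min is not None:
            activity = ActivityReport(
                moderate_minutes_per_week=mod_min,
                vigorous_minutes_per_week=vig_min,
                met_hours_per_week=met_h,
            )
        diet_score = _opt_float(row, "diet_score")
        profiles.append(
            ParticipantProfile(
                id=row["id"],
                chronological_age=_opt_float(row, "age"),
                sex=_opt_str(row, "sex"),
                height_m=_opt_float(row, "height_m"),
                weight_kg=_opt_float(row, "weight_kg"),
                bmi=_opt_float(row, "bmi"),
                waist_cm=_opt_float(row, "waist_cm"),
                smoking=_opt_str(row, "smoking"),
                alcohol_units_per_week=_opt_float(row, "alcohol_units"),
                binge=_opt_bool(row, "binge"),
                activity=activity,
                diet=DietResponses([bool(v) for v in diet_items]) if diet_items else None,
                diet_score=int(diet_score) if diet_score is not None else None,
                mood=MoodResponses(pos_items, neg_items) if pos_items and neg_items else None,
                positive_mood=_opt_float(row, "positive_mood"),
                negative_mood=_opt_float(row, "negative_mood"),
                satisfaction=SatisfactionResponses(sat_items) if sat_items else None,
                life_satisfaction=_opt_float(row, "life_satisfaction"),
                stress=StressResponses(stress_items) if stress_items else None,
                stress_score=_opt_float(row, "stress"),
                sleep_hours=_opt_float(row, "sleep_hours"),
            )
        )
    return profiles


def results_frame(results: Sequence[LifeAgeResult]) -> pd.DataFrame:
    """Flat one-row-per-participant frame of scored results."""
    return pd.DataFrame([r.to_dict() for r in results])


def write_results(
    results: Sequence[LifeAgeResult] | pd.DataFrame,
    path: str | Path,
    fmt: str | None = None,
) -> None:
    """Write scored results as CSV or JSON (format inferred from the suffix).

    The CSV rows and the JSON records carry identical fields and values.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2, default=float))
    else:
        raise InputError(f"unsupported output format {fmt!r}; use csv or json")
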