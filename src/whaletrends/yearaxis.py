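"""Species-year conventions.

Humpback and blue whale seasons sit comfortably inside the calendar year,
so their species year starts January 1.  The gray whale southbound
migration straddles New Year, so gray whales use an adjusted year whose
day 1 is June 1; the adjusted year is labelled by the calendar year
containing that June 1.
"""

from __future__ import annotations

import pandas as pd

CALENDAR = "calendar"
JUNE1 = "june1"


def species_year(dates: pd.Series, convention: str = CALENDAR) -> pd.Series:
    """Species-year label for each date under the given convention."""
    dates = pd.to_datetime(dates)
    if convention == CALENDAR:
        return dates.dt.year
    if convention == JUNE1:
        return dates.dt.year.where(dates.dt.month >= 6, dates.dt.year - 1)
    raise ValueError(f"unknown year convention: {convention!r}")


def year_day(dates: pd.Series, convention: str = CALENDAR) -> pd.Series:
    """Day within the species year (day 1 = Jan 1 or Jun 1)."""
    dates = pd.to_datetime(dates)
    if convention == CALENDAR:
        return dates.dt.dayofyear
    if convention == JUNE1:
        start_year = species_year(dates, JUNE1)
        starts = pd.to_datetime({"year": start_year, "month": 6, "day": 1})
        return (dates - starts).dt.days + 1
    raise ValueError(f"unknown year convention: {convention!r}")


def year_week(dates: pd.Series, convention: str = CALENDAR) -> pd.Series:
    """1-based 7-day week index within the species year; week 53 folds into 52."""
    day = year_day(dates, convention)
    return ((day - 1) // 7 + 1).clip(upper=52)


def convention_for(species: str) -> str:
    """Gray whale datasets run on the June-1 adjusted year; others on calendar."""
    return JUNE1 if species.startswith("gray") else CALENDAR
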