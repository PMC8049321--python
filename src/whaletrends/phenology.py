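"""Migration phenology: percentile arrival / peak / departure and timing trends.

Arrival, peak and departure are the days of the species year on which
cumulative annual sightings first reach 10%, 50% and 90% of the annual
total (achieved-count rule, no interpolation); residency is departure
minus arrival.  Species-specific exclusions are applied first: blue
whales lose January-February, the gray southbound dataset loses adjusted
weeks 1-18 (the summer resident animals), and anomaly years with a
collapsed annual total are excluded entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import yearaxis
from .modelfit import select_poly_shape

PERCENTILES = {"arrival_day": 10, "peak_day": 50, "departure_day": 90}
GRAY_SOUTH_EXCLUDED_WEEKS = 18
ANOMALY_FRACTION = 0.05


@dataclass
class TimingRecord:
    species: str
    species_year: int
    arrival_day: float
    peak_day: float
    departure_day: float
    residency_days: float
    annual_total: float
    excluded: bool = False
    reason: str = ""


def percentile_day(days: np.ndarray, counts: np.ndarray, percentile: float) -> float:
    """Smallest day with cumulative count >= percentile% of the total."""
    order = np.argsort(days)
    days, counts = np.asarray(days)[order], np.asarray(counts, dtype=float)[order]
    total = counts.sum()
    if total <= 0:
        raise ValueError("no sightings in year")
    cum = np.cumsum(counts)
    idx = int(np.searchsorted(cum, percentile / 100.0 * total))
    return float(days[min(idx, len(days) - 1)])


def compute_timing(
    daily: pd.DataFrame, species: str, species_year: int, year_convention: str | None = None
) -> TimingRecord:
    """Timing record for one species-year of (filtered) daily counts."""
    if year_convention is None:
        year_convention = yearaxis.convention_for(species)
    grp = daily[(daily["species"] == species)].copy()
    grp["date"] = pd.to_datetime(grp["date"])
    grp = grp[yearaxis.species_year(grp["date"], year_convention) == species_year]
    day = yearaxis.year_day(grp["date"], year_convention).to_numpy()
    counts = grp["count"].to_numpy(dtype=float)
    total = float(np.nansum(counts))
    if total <= 0:
        return TimingRecord(species, species_year, np.nan, np.nan, np.nan, np.nan, 0.0,
                            excluded=True, reason="no sightings")
    days = {k: percentile_day(day, counts, p) for k, p in PERCENTILES.items()}
    return TimingRecord(
        species=species,
        species_year=int(species_year),
        arrival_day=days["arrival_day"],
        peak_day=days["peak_day"],
        departure_day=days["departure_day"],
        residency_days=days["departure_day"] - days["arrival_day"],
        annual_total=total,
    )


def apply_exclusions(
    daily: pd.DataFrame, species: str, anomaly_fraction: float = ANOMALY_FRACTION
) -> tuple[pd.DataFrame, list[dict]]:
    """Species-specific day and anomaly-year exclusions.

    Blue: drop January-February days.  Gray-south: drop adjusted-year
    weeks 1-18 (June-September resident animals).  Any species-year whose
    total falls below ``anomaly_fraction`` of the cross-year median total
    is excluded as an ecological anomaly.  Returns the reduced table and
    an exclusion log.
    """
    grp = daily[daily["species"] == species].copy()
    grp["date"] = pd.to_datetime(grp["date"])
    log: list[dict] = []
    if species == "blue":
        winter = grp["date"].dt.month.isin((1, 2))
        if winter.any():
            log.append({"rule": "blue_winter", "n_days": int(winter.sum())})
        grp = grp[~winter]
    if species == "gray_south":
        week = yearaxis.year_week(grp["date"], yearaxis.JUNE1)
        summer = week <= GRAY_SOUTH_EXCLUDED_WEEKS
        if summer.any():
            log.append({"rule": "gray_south_weeks_1_18", "n_days": int(summer.sum())})
        grp = grp[~summer]

    conv = yearaxis.convention_for(species)
    syear = yearaxis.species_year(grp["date"], conv)
    totals = grp.groupby(syear)["count"].sum()
    median = float(totals.median())
    anomalous = totals[totals < anomaly_fraction * median]
    for yr, tot in anomalous.items():
        log.append({"rule": "anomaly_year", "species_year": int(yr), "total": float(tot),
                    "median_total": median})
    grp = grp[~syear.isin(anomalous.index)]
    return grp.reset_index(drop=True), log


def timing_table(
    daily: pd.DataFrame, species: str, anomaly_fraction: float = ANOMALY_FRACTION
) -> pd.DataFrame:
    """Per species-year timing records after exclusions, as a DataFrame."""
    reduced, _ = apply_exclusions(daily, species, anomaly_fraction)
    conv = yearaxis.convention_for(species)
    years = sorted(yearaxis.species_year(reduced["date"], conv).unique())
    recs = [compute_timing(reduced, species, y, conv) for y in years]
    return pd.DataFrame([vars(r) for r in recs])


def fit_timing_trend(
    timing: pd.DataFrame, metric: str = "arrival_day", min_years: int = 6
):
    """OLS trend of a timing metric on year, keeping the highest significant order.

    Returns ``(label, order, fit)`` with labels ``L/Q/C`` plus the sign of
    the top coefficient, or ``NA`` when no polynomial order of year is
    significant at the 5% level.
    """
    ok = timing[~timing["excluded"].astype(bool)] if "excluded" in timing.columns else timing
    ok = ok.dropna(subset=[metric])
    if len(ok) < min_years:
        raise ValueError(f"need >= {min_years} non-excluded years, got {len(ok)}")
    return select_poly_shape(
        ok[metric].to_numpy(), ok["species_year"].to_numpy(), name="year", max_order=3
    )
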