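"""Environmental covariates: SST fronts, Ekman transport, spring transition,
seasonal averages and lagged climate indices.

Covariates are built per species-year under either the calendar or the
June-1 adjusted ("gray") year convention, as annual means, standard
seasonal means (Dec-Feb, Mar-May, Jun-Aug, Sep-Nov), previous-season
values, and 1-3 month lagged variants of the basin-scale indices.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import yearaxis

SEASONS = {
    "winter": (12, 1, 2),
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "fall": (9, 10, 11),
}

KNOTS_TO_MS = 0.514444
OMEGA = 7.2921159e-5  # Earth's angular velocity, rad/s

# bulk-formula defaults
RHO_AIR = 1.22  # kg/m^3
DRAG_COEF = 1.3e-3
RHO_SEAWATER = 1025.0  # kg/m^3


# ---------------------------------------------------------------- front index
def front_intensity_index(
    grid: pd.DataFrame,
    radius_km: float,
    center: tuple[float, float] = (0.0, 0.0),
    value_col: str = "sst",
) -> float:
    """Maximum SST gradient magnitude (degC/km) within ``radius_km`` of ``center``.

    ``grid`` holds one snapshot with columns x_km, y_km and the SST value
    on a regular km grid.  Gradients use central differences in the
    interior and one-sided differences at the field edge; the maximum is
    taken over cells whose centres lie inside the disc.
    """
    pivot = grid.pivot_table(index="x_km", columns="y_km", values=value_col)
    xs = pivot.index.to_numpy(dtype=float)
    ys = pivot.columns.to_numpy(dtype=float)
    fld = pivot.to_numpy(dtype=float)
    if np.isnan(fld).any():
        raise ValueError("gridded SST field has holes inside its bounding box")
    cx, cy = center
    if (
        cx - radius_km < xs.min()
        or cx + radius_km > xs.max()
        or cy - radius_km < ys.min()
        or cy + radius_km > ys.max()
    ):
        raise ValueError(
            f"grid [{xs.min()},{xs.max()}]x[{ys.min()},{ys.max()}] does not cover "
            f"the radius-{radius_km} km disc around {center}"
        )
    gx, gy = np.gradient(fld, xs, ys)
    mag = np.hypot(gx, gy)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_km**2
    return float(mag[inside].max())


# ------------------------------------------------------------- Ekman transport
def wind_to_uv(speed_knots: np.ndarray, direction_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convert speed (knots) and meteorological direction (degrees FROM) to
    eastward/northward components in m/s."""
    spd = np.asarray(speed_knots, dtype=float) * KNOTS_TO_MS
    theta = np.deg2rad(np.asarray(direction_deg, dtype=float))
    # wind FROM direction theta blows TOWARD theta + 180
    u = -spd * np.sin(theta)
    v = -spd * np.cos(theta)
    return u, v


def coriolis(latitude_deg: float) -> float:
    if abs(latitude_deg) < 1.0:
        raise ValueError("Coriolis parameter vanishes near the equator; latitude must exceed 1 deg")
    return 2.0 * OMEGA * np.sin(np.deg2rad(latitude_deg))


def ekman_transport(
    u: np.ndarray,
    v: np.ndarray,
    latitude_deg: float = 38.0,
    coast_angle_deg: float = 0.0,
    rho_air: float = RHO_AIR,
    drag_coef: float = DRAG_COEF,
    rho_sw: float = RHO_SEAWATER,
) -> tuple[np.ndarray, np.ndarray]:
    """Alongshore wind stress and cross-shore Ekman transport from wind vectors.

    ``coast_angle_deg`` is the orientation of the coastline's poleward
    direction, degrees clockwise from north (0 = coast runs north-south).
    Stress follows the bulk formula tau = rho_air * C_d * |W| * W_along,
    signed so that equatorward alongshore wind is positive
    (upwelling-favorable in the northern hemisphere); transport is
    tau / (rho_sw * f) scaled to m^3/s per 100 m of coastline.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    f = coriolis(latitude_deg)
    theta = np.deg2rad(coast_angle_deg)
    # equatorward alongshore unit vector (NH): opposite the poleward axis
    w_along = -(u * np.sin(theta) + v * np.cos(theta))
    speed = np.hypot(u, v)
    tau = rho_air * drag_coef * speed * w_along
    transport = tau / (rho_sw * f) * 100.0
    return tau, transport


def ekman_from_met(
    speed_knots: np.ndarray, direction_deg: np.ndarray, **kwargs
) -> tuple[np.ndarray, np.ndarray]:
    """Ekman transport directly from speed (knots) + meteorological direction."""
    u, v = wind_to_uv(speed_knots, direction_deg)
    return ekman_transport(u, v, **kwargs)


# ------------------------------------------------------------ spring transition
def spring_transition(daily_transport: np.ndarray) -> tuple[int, int]:
    """Spring transition day from one year of daily cross-shore transport.

    The cumulative sum of upwelling-favorable transport from January 1
    reaches its minimum when sustained upwelling begins; that day of year
    is the transition (STB).  Returns ``(stb_day, anomaly_from_day_90)``.
    A cumulative curve with its minimum on day 1 (no winter downwelling)
    yields day 1 with a warning.
    """
    transport = np.asarray(daily_transport, dtype=float)
    if len(transport) < 300:
        raise ValueError(f"need >= 300 days of transport, got {len(transport)}")
    cum = np.cumsum(transport)
    stb = int(np.argmin(cum)) + 1
    if stb == 1 and np.all(np.diff(cum) >= 0):
        warnings.warn("cumulative transport is monotone increasing; STB degenerate at day 1",
                      stacklevel=2)
    return stb, stb - 90


def annual_spring_transitions(
    wind: pd.DataFrame, latitude_deg: float = 38.0, coast_angle_deg: float = 0.0
) -> pd.DataFrame:
    """STB per calendar year from a daily wind table with date, u, v (m/s)."""
    wind = wind.copy()
    wind["date"] = pd.to_datetime(wind["date"])
    _, transport = ekman_transport(
        wind["u"].to_numpy(), wind["v"].to_numpy(), latitude_deg, coast_angle_deg
    )
    wind["transport"] = transport
    rows = []
    for year, grp in wind.groupby(wind["date"].dt.year):
        stb, anom = spring_transition(grp.sort_values("date")["transport"].to_numpy())
        rows.append({"year": int(year), "stb_day": stb, "stb_anomaly": anom})
    return pd.DataFrame(rows)


# ------------------------------------------------------- seasonal aggregation
def _monthly(series: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Collapse a daily (date, value) table to per-month means; pass through
    tables already keyed by year/month."""
    if {"year", "month"}.issubset(series.columns):
        return series[["year", "month", value_col]].copy()
    out = series.copy()
    out["date"] = pd.to_datetime(out["date"])
    out["year"] = out["date"].dt.year
    out["month"] = out["date"].dt.month
    return out.groupby(["year", "month"], as_index=False)[value_col].mean()


def _season_members(year: int, season: str, year_convention: str) -> list[tuple[int, int]]:
    """(calendar year, month) triples making up one season of a species-year.

    Calendar convention: winter of year Y is Dec(Y-1), Jan(Y), Feb(Y);
    other seasons fall inside Y.  June-1 convention: species-year Y spans
    Jun(Y)..May(Y+1), so summer/fall sit in Y and winter/spring in Y+1
    (winter of adjusted year Y is Dec(Y), Jan(Y+1), Feb(Y+1)).
    """
    months = SEASONS[season]
    if year_convention == yearaxis.CALENDAR:
        return [(year - 1 if m == 12 else year, m) for m in months]
    if year_convention == yearaxis.JUNE1:
        return [(year if m >= 6 else year + 1, m) for m in months]
    raise ValueError(f"unknown year convention {year_convention!r}")


def _year_members(year: int, year_convention: str) -> list[tuple[int, int]]:
    if year_convention == yearaxis.CALENDAR:
        return [(year, m) for m in range(1, 13)]
    return [(year, m) for m in range(6, 13)] + [(year + 1, m) for m in range(1, 6)]


def seasonal_average(
    series: pd.DataFrame,
    season: str,
    year: int,
    value_col: str = "value",
    year_convention: str = yearaxis.CALENDAR,
) -> float:
    """Mean of a monthly (or daily, collapsed to monthly) series over one season.

    Raises if any member month is absent, naming the missing months.
    """
    monthly = _monthly(series, value_col).set_index(["year", "month"])[value_col]
    members = _season_members(year, season, year_convention)
    missing = [m for m in members if m not in monthly.index]
    if missing:
        raise ValueError(f"missing months for {season} of {year_convention} year {year}: {missing}")
    return float(np.mean([monthly[m] for m in members]))


def annual_average(
    series: pd.DataFrame,
    year: int,
    value_col: str = "value",
    year_convention: str = yearaxis.CALENDAR,
) -> float:
    monthly = _monthly(series, value_col).set_index(["year", "month"])[value_col]
    members = _year_members(year, year_convention)
    missing = [m for m in members if m not in monthly.index]
    if missing:
        raise ValueError(f"missing months for {year_convention} year {year}: {missing}")
    return float(np.mean([monthly[m] for m in members]))


def lag_series(monthly: pd.DataFrame, k: int, value_col: str = "value") -> pd.DataFrame:
    """Shift a monthly series so month m carries the raw value of month m-k.

    Months whose source falls before the series start become missing and
    are propagated explicitly as NaN.
    """
    if k not in (0, 1, 2, 3):
        raise ValueError("lag must be 0-3 months")
    out = monthly.sort_values(["year", "month"]).reset_index(drop=True).copy()
    out[value_col] = out[value_col].shift(k)
    return out


# -------------------------------------------------------- covariate assembly
# last calendar day-of-year on which each temporal scope's raw data window
# closes, for forecast eligibility (previous-year scopes close before day 1)
_SEASON_CLOSE = {"winter": 59, "spring": 151, "summer": 243, "fall": 334}


def availability_day(scope: str) -> int:
    """Forecast-eligibility metadata: calendar day the covariate window closes."""
    if scope.startswith("prev_"):
        return 0
    if scope == "annual":
        return 365
    if scope.startswith("lag"):
        return 365
    season = scope.split("_")[0]
    # anything without a recognised seasonal window (STB, FII radii, ...)
    # closes with the year
    return _SEASON_CLOSE.get(season, 365)


def build_covariates(
    climate: pd.DataFrame,
    sea_surface: pd.DataFrame,
    sst_grid: pd.DataFrame | None,
    wind: pd.DataFrame | None,
    years: list[int],
    year_convention: str = yearaxis.CALENDAR,
    fii_radii: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0),
    ui_monthly: pd.DataFrame | None = None,
    latitude_deg: float = 38.0,
    coast_angle_deg: float = 0.0,
) -> pd.DataFrame:
    """Assemble the per species-year covariate table.

    One row per year with annual, seasonal, previous-season and (for the
    climate indices) 1-3 month-lagged seasonal/annual means, plus annual
    mean front intensity per radius, upwelling index aggregates and the
    spring transition day.  The upwelling index is consumed directly when
    ``ui_monthly`` (year, month, ui) is given, otherwise synthesised from
    the daily wind via Ekman transport.
    """
    rows = []
    if ui_monthly is None and wind is not None:
        w = wind.copy()
        w["date"] = pd.to_datetime(w["date"])
        _, transport = ekman_transport(
            w["u"].to_numpy(), w["v"].to_numpy(), latitude_deg, coast_angle_deg
        )
        w["ui"] = transport
        ui_monthly = w.assign(year=w["date"].dt.year, month=w["date"].dt.month).groupby(
            ["year", "month"], as_index=False
        )["ui"].mean()
    stb = annual_spring_transitions(wind, latitude_deg, coast_angle_deg) if wind is not None else None

    fii_annual: dict[float, dict[int, float]] = {r: {} for r in fii_radii}
    if sst_grid is not None:
        per_month = {}
        for (yy, mm), snap in sst_grid.groupby(["year", "month"]):
            per_month[(int(yy), int(mm))] = {
                r: front_intensity_index(snap, r) for r in fii_radii
            }
        fii_monthly = pd.DataFrame(
            [
                {"year": y, "month": m, **{f"fii_{int(r)}km": v for r, v in vals.items()}}
                for (y, m), vals in per_month.items()
            ]
        )

    def safe(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except (ValueError, KeyError):
            return np.nan

    for year in years:
        row: dict[str, float] = {"species_year": int(year)}
        for col, src in (("sst", sea_surface), ("sss", sea_surface)):
            row[f"{col}_annual"] = safe(annual_average, src, year, col, year_convention)
            for season in SEASONS:
                row[f"{col}_{season}"] = safe(
                    seasonal_average, src, season, year, col, year_convention
                )
                row[f"{col}_prev_{season}"] = safe(
                    seasonal_average, src, season, year - 1, col, year_convention
                )
        for idx in ("soi", "pdo", "npgo"):
            row[f"{idx}_annual"] = safe(annual_average, climate, year, idx, year_convention)
            for season in SEASONS:
                row[f"{idx}_{season}"] = safe(
                    seasonal_average, climate, season, year, idx, year_convention
                )
                row[f"{idx}_prev_{season}"] = safe(
                    seasonal_average, climate, season, year - 1, idx, year_convention
                )
            for k in (1, 2, 3):
                lagged = lag_series(climate, k, idx)
                row[f"{idx}_lag{k}_annual"] = safe(
                    annual_average, lagged, year, idx, year_convention
                )
        if ui_monthly is not None:
            row["ui_annual"] = safe(annual_average, ui_monthly, year, "ui", year_convention)
            for season in SEASONS:
                row[f"ui_{season}"] = safe(
                    seasonal_average, ui_monthly, season, year, "ui", year_convention
                )
        if stb is not None and (stb["year"] == year).any():
            rec = stb[stb["year"] == year].iloc[0]
            row["stb_day"] = float(rec["stb_day"])
            row["stb_anomaly"] = float(rec["stb_anomaly"])
        if sst_grid is not None:
            for r in fii_radii:
                col = f"fii_{int(r)}km"
                members = _year_members(year, year_convention)
                vals = fii_monthly.set_index(["year", "month"])[col]
                present = [vals[m] for m in members if m in vals.index]
                row[col] = float(np.mean(present)) if present else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def covariate_scope(name: str) -> str:
    """Temporal scope of an assembled covariate column, for forecast metadata."""
    parts = name.split("_", 1)
    return parts[1] if len(parts) > 1 else "annual"
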