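"""Seeded synthetic datasets with the statistical structure of a land-based whale count study.

The generators emulate a multi-decade daily whale-count series from a fixed
island observation point together with the in-situ weather, local and
basin-scale environmental series, and monthly entanglement records needed
to exercise the full analysis pipeline with known ground truth:

* unimodal (humpback, blue) and bimodal (gray) within-year count curves,
  with negative-binomial overdispersion, an interannual abundance trend
  and a days-per-year drift in timing;
* weather-driven observation effort, with counts blanked on no-effort
  days so the false-zero ambiguity of legacy records is reproduced;
* AR(1) monthly climate indices (SOI/PDO/NPGO), daily SST/SSS with an
  annual cycle and a slow warming trend, a gridded SST field for front
  detection, and coastal wind with a configurable spring reversal;
* monthly entanglements linearly coupled to monthly counts and arrival day.

Every table is a plain :class:`pandas.DataFrame`; identical config + seed
give identical tables.  Sub-streams are derived per table so regenerating
one table does not disturb the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import yearaxis

HUMPBACK = "humpback"
BLUE = "blue"
GRAY = "gray"


@dataclass
class Peak:
    """One Gaussian component of a within-year sighting curve.

    ``mu`` is the mean day on the species-year axis, ``sigma`` the spread
    in days, ``weight`` the share of the annual total in this component.
    """

    mu: float
    sigma: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class SpeciesProfile:
    """Seasonal shape, abundance level and interannual drifts for one species."""

    name: str
    peaks: list[Peak]
    annual_total: float
    # log-scale polynomial coefficients on the centred year index: the
    # annual total is annual_total * exp(c1*t + c2*t^2 + c3*t^3).
    abundance_trend: tuple[float, ...] = ()
    timing_trend: float = 0.0  # days per year drift of every peak mean
    dispersion: float = 0.5  # NB2 alpha; 0 -> Poisson
    year_convention: str = yearaxis.CALENDAR
    twice_daily: bool = False  # morning + evening surveys (gray winter protocol)


@dataclass
class ARParams:
    mean: float
    sd: float
    phi: float

    def __post_init__(self) -> None:
        if abs(self.phi) >= 1:
            raise ValueError(f"AR(1) coefficient must satisfy |phi| < 1, got {self.phi}")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass
class EnvParams:
    """Environmental series parameters.

    Index means/SDs follow the long-term summaries of the standard SOI,
    PDO and NPGO products; SST follows a coastal-California climatology
    (annual mean ~12.5 degC, warm season late summer) with a slow warming
    trend of ~0.013 degC/yr.
    """

    soi: ARParams = field(default_factory=lambda: ARParams(-0.20, 1.85, 0.6))
    pdo: ARParams = field(default_factory=lambda: ARParams(0.133, 1.14, 0.85))
    npgo: ARParams = field(default_factory=lambda: ARParams(0.245, 1.25, 0.9))
    sst_mean: float = 12.49
    sst_amplitude: float = 1.6  # degC, annual cycle
    sst_peak_day: int = 250  # warmest day of year
    sst_trend: float = 0.013  # degC per year
    sst_noise_sd: float = 0.45
    sst_noise_phi: float = 0.8
    sss_mean: float = 33.40
    sss_amplitude: float = 0.3
    sss_noise_sd: float = 0.2
    # gridded SST field for front detection (km grid centred on the island)
    grid_half_width_km: float = 20.0
    grid_step_km: float = 4.0
    grid_gradient_mean: float = 0.03  # degC/km background front strength
    grid_gradient_sd: float = 0.012
    grid_cell_noise_sd: float = 0.02
    # coastal wind: poleward (downwelling) in winter, equatorward after the
    # spring transition
    reversal_day_mean: float = 100.0
    reversal_day_sd: float = 8.0
    wind_v_winter: float = 2.5  # m/s northward before the reversal
    wind_v_summer: float = -5.5  # m/s (equatorward) after the reversal
    wind_noise_sd: float = 2.0


@dataclass
class EffortParams:
    """Logistic model of daily observation effort on weather.

    Coefficients act on centred weather covariates.  The survey protocol
    is a hard threshold rule (sufficient visibility, moderate wind, low
    swell), so the defaults are steep: effort is near-certain in good
    weather and near-impossible in heavy swell or fog, with Bernoulli
    noise only near the protocol boundary.  Overall effort rate lands
    around 70-80%.
    """

    intercept: float = 2.5
    visibility_km: float = 0.35
    swell_height_ft: float = -1.1
    wind_speed_kn: float = -0.30
    centers: dict = field(
        default_factory=lambda: {"visibility_km": 13.0, "swell_height_ft": 7.0, "wind_speed_kn": 12.0}
    )
    labeled_years: int = 4  # trailing years with recorded effort metadata


@dataclass
class EntanglementParams:
    """Linear-Gaussian model of monthly entanglements, floored at zero."""

    intercept: float = 10.0
    count_slope: float = 0.03
    arrival_slope: float = -0.04
    noise_sd: float = 1.0
    species: str = HUMPBACK


def default_species_profiles() -> dict[str, SpeciesProfile]:
    """The study conditions: three species, 24-year series.

    Humpback and blue peak in the upwelling season (summer/early fall);
    gray whales show a southbound (mid-winter) and a northbound (early
    spring) pulse on the June-1 adjusted axis.  Humpback abundance rises
    quadratically over the series; humpback and blue arrival drift
    earlier by roughly 5 days per year while gray timing is stationary.
    """
    return {
        HUMPBACK: SpeciesProfile(
            name=HUMPBACK,
            peaks=[Peak(mu=250, sigma=40)],
            annual_total=150.0,
            abundance_trend=(0.0, 0.002),
            timing_trend=-5.0,
            dispersion=0.6,
        ),
        BLUE: SpeciesProfile(
            name=BLUE,
            peaks=[Peak(mu=230, sigma=45)],
            annual_total=141.0,
            abundance_trend=(0.0, 0.0, 0.0002),
            timing_trend=-4.3,
            dispersion=0.6,
        ),
        GRAY: SpeciesProfile(
            name=GRAY,
            peaks=[Peak(mu=230, sigma=22, weight=0.55), Peak(mu=290, sigma=18, weight=0.45)],
            annual_total=600.0,
            timing_trend=0.0,
            dispersion=0.4,
            year_convention=yearaxis.JUNE1,
            twice_daily=True,
        ),
    }


@dataclass
class SimulationConfig:
    """Full configuration of one synthetic study."""

    n_years: int = 24
    start_year: int = 1993
    species_profiles: dict[str, SpeciesProfile] = field(default_factory=default_species_profiles)
    env_params: EnvParams = field(default_factory=EnvParams)
    effort_params: EffortParams = field(default_factory=EffortParams)
    entanglement_params: EntanglementParams = field(default_factory=EntanglementParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 3:
            raise ValueError("n_years must be at least 3")
        for prof in self.species_profiles.values():
            for p in prof.peaks:
                if p.sigma <= 0:
                    raise ValueError("peak sigma must be positive")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(
            f"{self.start_year}-01-01", f"{self.start_year + self.n_years - 1}-12-31", freq="D"
        )


# stable per-table sub-streams: same seed regenerates the same table
_STREAMS = {
    "environment": 1,
    "weather": 2,
    "sightings": 3,
    "effort": 4,
    "entanglements": 5,
}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), _STREAMS[stream]]))


def ar1(rng: np.random.Generator, n: int, params: ARParams) -> np.ndarray:
    """Stationary AR(1) draw of length ``n`` with the given mean and marginal SD."""
    if abs(params.phi) >= 1:
        raise ValueError("AR(1) coefficient must satisfy |phi| < 1")
    innov_sd = params.sd * np.sqrt(1.0 - params.phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, params.sd)
    eps = rng.normal(0.0, innov_sd, size=n)
    for t in range(1, n):
        x[t] = params.phi * x[t - 1] + eps[t]
    return params.mean + x


def generate_environment(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Generate environment tables: daily SST/SSS, gridded SST, wind, monthly indices.

    Returns a dict with keys ``climate`` (year, month, soi, pdo, npgo),
    ``sea_surface`` (date, sst, sss), ``sst_grid`` (year, month, x_km,
    y_km, sst) at monthly resolution, and ``wind`` (date, u, v) in m/s.
    """
    rng = _rng(config, "environment")
    env = config.env_params
    dates = config.dates
    n_days = len(dates)

    months = pd.period_range(f"{config.start_year}-01", periods=config.n_years * 12, freq="M")
    climate = pd.DataFrame(
        {
            "year": months.year,
            "month": months.month,
            "soi": ar1(rng, len(months), env.soi),
            "pdo": ar1(rng, len(months), env.pdo),
            "npgo": ar1(rng, len(months), env.npgo),
        }
    )

    doy = dates.dayofyear.to_numpy()
    year_frac = (dates.year - config.start_year).to_numpy(dtype=float)
    cycle = env.sst_amplitude * np.cos(2 * np.pi * (doy - env.sst_peak_day) / 365.25)
    noise = ar1(rng, n_days, ARParams(0.0, env.sst_noise_sd, env.sst_noise_phi))
    sst = env.sst_mean + cycle + env.sst_trend * year_frac + noise
    sss = (
        env.sss_mean
        - env.sss_amplitude * np.cos(2 * np.pi * (doy - env.sst_peak_day) / 365.25)
        + rng.normal(0.0, env.sss_noise_sd, n_days)
    )
    sea_surface = pd.DataFrame({"date": dates, "sst": sst, "sss": sss})

    # monthly gridded SST: monthly-mean background plus a planar front of
    # random strength/orientation and cell noise
    axis = np.arange(-env.grid_half_width_km, env.grid_half_width_km + 1e-9, env.grid_step_km)
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    monthly_sst = sea_surface.assign(
        year=dates.year, month=dates.month
    ).groupby(["year", "month"], as_index=False)["sst"].mean()
    grids = []
    for _, row in monthly_sst.iterrows():
        strength = abs(rng.normal(env.grid_gradient_mean, env.grid_gradient_sd))
        theta = rng.uniform(0, 2 * np.pi)
        fld = (
            row["sst"]
            + strength * (np.cos(theta) * gx + np.sin(theta) * gy)
            + rng.normal(0.0, env.grid_cell_noise_sd, gx.shape)
        )
        grids.append(
            pd.DataFrame(
                {
                    "year": int(row["year"]),
                    "month": int(row["month"]),
                    "x_km": gx.ravel(),
                    "y_km": gy.ravel(),
                    "sst": fld.ravel(),
                }
            )
        )
    sst_grid = pd.concat(grids, ignore_index=True)

    # coastal wind with a spring reversal each calendar year
    reversal = {
        int(y): float(rng.normal(env.reversal_day_mean, env.reversal_day_sd)) for y in config.years
    }
    rev_days = np.array([reversal[y] for y in dates.year])
    v_base = np.where(doy < rev_days, env.wind_v_winter, env.wind_v_summer)
    wind = pd.DataFrame(
        {
            "date": dates,
            "u": rng.normal(0.0, env.wind_noise_sd, n_days),
            "v": v_base + rng.normal(0.0, env.wind_noise_sd, n_days),
        }
    )
    wind.attrs["reversal_days"] = reversal

    return {"climate": climate, "sea_surface": sea_surface, "sst_grid": sst_grid, "wind": wind}


def generate_weather(config: SimulationConfig) -> pd.DataFrame:
    """Daily in-situ weather driving observation effort.

    Units follow the field protocol: visibility km, pressure mb, air
    temperature degC, precipitation inches/day, wind knots, swell feet.
    """
    rng = _rng(config, "weather")
    dates = config.dates
    n = len(dates)
    swell = np.clip(ar1(rng, n, ARParams(6.0, 3.0, 0.7)), 0.0, None)
    vis = np.clip(ar1(rng, n, ARParams(15.0, 6.0, 0.5)), 0.0, 40.0)
    return pd.DataFrame(
        {
            "date": dates,
            "cloud_cover": np.clip(rng.normal(50, 30, n), 0, 100),
            "visibility_km": vis,
            "pressure_mb": rng.normal(1015, 6, n),
            "air_temp_c": 12 + 4 * np.cos(2 * np.pi * (dates.dayofyear - 250) / 365.25)
            + rng.normal(0, 1.5, n),
            "precip_in": np.clip(rng.exponential(0.02, n) - 0.01, 0.0, None),
            "wind_dir_deg": rng.uniform(0, 360, n),
            "wind_speed_kn": np.clip(ar1(rng, n, ARParams(10.0, 5.0, 0.6)), 0.0, None),
            "swell_height_ft": swell,
            "swell_dir_deg": rng.uniform(0, 360, n),
        }
    )


def seasonal_intensity(
    profile: SpeciesProfile, year_index: float, days: np.ndarray, annual_total: float | None = None
) -> np.ndarray:
    """Expected daily count curve on the species-year axis for one year.

    The curve is a (mixture of) Gaussian(s) whose means shift by
    ``timing_trend`` days per year and whose mass follows the abundance
    trend; ``year_index`` counts from 0 at the first simulated year.
    """
    if annual_total is None:
        annual_total = expected_total(profile, year_index)
    wsum = sum(p.weight for p in profile.peaks)
    lam = np.zeros_like(days, dtype=float)
    for p in profile.peaks:
        mu = p.mu + profile.timing_trend * year_index
        lam += (p.weight / wsum) * stats.norm.pdf(days, mu, p.sigma)
    return annual_total * lam


def expected_total(profile: SpeciesProfile, year_index: float, n_years: int = 24) -> float:
    t = year_index - (n_years - 1) / 2.0
    log_mult = sum(c * t ** (k + 1) for k, c in enumerate(profile.abundance_trend))
    return profile.annual_total * float(np.exp(log_mult))


def true_timing(
    profile: SpeciesProfile, year_index: float, percentile: float, n_days: int = 365
) -> float:
    """Percentile day of the noiseless seasonal curve — ground truth for recovery tests."""
    days = np.arange(1, n_days + 1, dtype=float)
    lam = seasonal_intensity(profile, year_index, days, annual_total=1.0)
    cum = np.cumsum(lam) / lam.sum()
    return float(days[np.searchsorted(cum, percentile / 100.0)])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 draw (variance mean + alpha*mean^2) via the gamma-Poisson mixture."""
    mean = np.clip(mean, 1e-12, None)
    if alpha <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam)


def generate_sightings(
    config: SimulationConfig, environment: dict[str, pd.DataFrame] | None = None
) -> pd.DataFrame:
    """Daily sighting table for every configured species.

    Columns: date, species, count, count_am, count_pm.  Twice-daily
    species (gray winter protocol) get morning/evening draws whose mean
    is the day's analysis value; others have count only.
    """
    rng = _rng(config, "sightings")
    dates = config.dates
    rows = []
    for name, profile in config.species_profiles.items():
        day = yearaxis.year_day(pd.Series(dates), profile.year_convention).to_numpy()
        syear = yearaxis.species_year(pd.Series(dates), profile.year_convention).to_numpy()
        counts = np.zeros(len(dates))
        am = np.full(len(dates), np.nan)
        pm = np.full(len(dates), np.nan)
        for y in np.unique(syear):
            sel = syear == y
            yi = float(y - config.start_year)
            lam = seasonal_intensity(profile, yi, day[sel].astype(float))
            # years clipped by the series edge (adjusted years) keep the
            # same daily intensity, just fewer days
            if profile.twice_daily:
                a = _nb_draw(rng, lam, profile.dispersion)
                b = _nb_draw(rng, lam, profile.dispersion)
                am[sel], pm[sel] = a, b
                counts[sel] = (a + b) / 2.0
            else:
                counts[sel] = _nb_draw(rng, lam, profile.dispersion)
        rows.append(
            pd.DataFrame(
                {"date": dates, "species": name, "count": counts, "count_am": am, "count_pm": pm}
            )
        )
    return pd.concat(rows, ignore_index=True)


def effort_probability(config: SimulationConfig, weather: pd.DataFrame) -> np.ndarray:
    """Daily logistic effort probability under the configured weather model."""
    ep = config.effort_params
    logit = np.full(len(weather), ep.intercept, dtype=float)
    for var, center in ep.centers.items():
        coef = getattr(ep, var)
        logit += coef * (weather[var].to_numpy() - center)
    return 1.0 / (1.0 + np.exp(-logit))


def generate_effort(
    config: SimulationConfig, weather: pd.DataFrame, sightings: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw daily effort and censor the sighting table accordingly.

    Returns ``(effort, censored)``.  ``effort`` has date, p_effort and the
    true 0/1 effort label (kept for evaluation only).  ``censored`` is the
    sighting table with counts blanked on no-effort days and an
    ``effort_known`` flag that is True only in the trailing
    ``labeled_years`` years, reproducing the legacy ambiguity between
    true zeros and no-effort days.
    """
    rng = _rng(config, "effort")
    p = effort_probability(config, weather)
    label = rng.random(len(weather)) < p
    effort = pd.DataFrame(
        {"date": pd.to_datetime(weather["date"]), "p_effort": p, "effort": label.astype(int)}
    )

    censored = sightings.copy()
    censored["date"] = pd.to_datetime(censored["date"])
    eff_map = effort.set_index("date")["effort"]
    day_effort = censored["date"].map(eff_map).fillna(1).astype(int)
    no_effort = day_effort == 0
    censored.loc[no_effort, ["count", "count_am", "count_pm"]] = np.nan
    first_labeled = config.start_year + config.n_years - config.effort_params.labeled_years
    censored["effort_known"] = censored["date"].dt.year >= first_labeled
    return effort, censored


def generate_entanglements(
    config: SimulationConfig, monthly_counts: pd.DataFrame, timing_records: pd.DataFrame
) -> pd.DataFrame:
    """Monthly entanglement table coupled to counts and arrival timing.

    ``monthly_counts`` needs columns species, year, month, count;
    ``timing_records`` needs species, species_year, arrival_day.  The
    response is a + b*count + c*arrival_day + Gaussian noise, rounded and
    floored at zero.
    """
    rng = _rng(config, "entanglements")
    ep = config.entanglement_params
    tbl = monthly_counts[monthly_counts["species"] == ep.species].copy()
    arrivals = timing_records[timing_records["species"] == ep.species].set_index("species_year")[
        "arrival_day"
    ]
    tbl["arrival_day"] = tbl["year"].map(arrivals)
    tbl = tbl.dropna(subset=["arrival_day"])
    raw = (
        ep.intercept
        + ep.count_slope * tbl["count"].to_numpy()
        + ep.arrival_slope * tbl["arrival_day"].to_numpy()
        + rng.normal(0.0, ep.noise_sd, len(tbl))
    )
    tbl["entanglements"] = np.maximum(np.round(raw), 0.0).astype(int)
    return tbl[["species", "year", "month", "entanglements"]].reset_index(drop=True)


def simulate_all(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Run every generator and return the full set of input tables."""
    env = generate_environment(config)
    weather = generate_weather(config)
    sightings = generate_sightings(config, env)
    effort, censored = generate_effort(config, weather, sightings)
    out = dict(env)
    out.update(
        weather=weather,
        sightings=sightings,
        effort=effort,
        censored_sightings=censored,
    )
    return out


def config_to_dict(config: SimulationConfig) -> dict:
    """Plain-dict form of the config, for YAML round-tripping."""
    return dataclasses.asdict(config)
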