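"""Monthly entanglement models and t²-based variance attribution.

Confirmed monthly entanglement counts are joined to monthly whale counts
(built from the weekly series by day-proportional apportionment of weeks
that straddle month boundaries) and to the year's arrival/departure days.
Ordinary least squares is appropriate here — entanglement residuals are
roughly normal, unlike the overdispersed weekly sighting counts.  The
relative contribution of two retained predictors is compared via the
squares of their t statistics, since in a linear model the variance in
the response attributable to a predictor is proportional to t².
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import yearaxis
from .modelfit import ALPHA, ModelFit, fit_ols
from .timing import VIF_LIMIT, CandidateTerm, TimingModelResult, backward_eliminate, screen_covariates

MIN_TOTAL_ENTANGLEMENTS = 10


def monthly_counts_from_weekly(
    weekly: pd.DataFrame, species: str, year_convention: str | None = None
) -> pd.DataFrame:
    """Calendar-month whale counts from the weekly series.

    Each species-year week w covers days 7(w-1)+1..7w of the species year
    (week 52 runs to the year's end); a week straddling a month boundary
    contributes count * days_in_month / week_length to each month.
    """
    if year_convention is None:
        year_convention = yearaxis.convention_for(species)
    grp = weekly[weekly["species"] == species]
    acc: dict[tuple[int, int], float] = {}
    for _, row in grp.iterrows():
        sy = int(row["species_year"])
        start_anchor = pd.Timestamp(sy, 1, 1) if year_convention == yearaxis.CALENDAR else pd.Timestamp(sy, 6, 1)
        w = int(row["week"])
        first = start_anchor + pd.Timedelta(days=7 * (w - 1))
        if w < 52:
            last = first + pd.Timedelta(days=6)
        else:  # folded final week runs to the end of the species year
            next_anchor = pd.Timestamp(sy + 1, 1, 1) if year_convention == yearaxis.CALENDAR else pd.Timestamp(sy + 1, 6, 1)
            last = next_anchor - pd.Timedelta(days=1)
        days = pd.date_range(first, last, freq="D")
        share = float(row["count"]) / len(days)
        for d in days:
            key = (d.year, d.month)
            acc[key] = acc.get(key, 0.0) + share
    out = pd.DataFrame(
        [{"species": species, "year": y, "month": m, "count": c} for (y, m), c in sorted(acc.items())]
    )
    return out


def build_monthly_design(
    entanglements: pd.DataFrame,
    weekly: pd.DataFrame,
    timing: pd.DataFrame,
    species: str = "humpback",
) -> pd.DataFrame:
    """Join monthly entanglements with monthly counts and annual timing.

    Output columns: year, month, entanglements, count, arrival_day,
    departure_day, plus ``no_sightings`` flagging months without count
    data.  Timing attaches by calendar year of the entanglement record.
    """
    ent = entanglements[entanglements["species"] == species]
    if ent.empty:
        raise ValueError(f"no entanglement records for species {species!r}")
    monthly = monthly_counts_from_weekly(weekly, species)
    merged = ent.merge(monthly[["year", "month", "count"]], on=["year", "month"], how="left")
    tim = timing[timing["species"] == species]
    for col in ("arrival_day", "departure_day"):
        merged[col] = merged["year"].map(tim.set_index("species_year")[col])
    merged["no_sightings"] = merged["count"].isna()
    merged["count"] = merged["count"].fillna(0.0)
    return merged.reset_index(drop=True)


def fit_entanglement_models(
    monthly: pd.DataFrame,
    alpha: float = ALPHA,
    min_total: int = MIN_TOTAL_ENTANGLEMENTS,
) -> dict:
    """Year-trend and combined counts+timing entanglement models.

    The trend model is OLS of monthly entanglements on year.  The
    combined model screens count, arrival_day and departure_day for
    linear/quadratic/cubic shapes and backward-eliminates to an
    all-significant, VIF-checked model.  Species with fewer than
    ``min_total`` total entanglements are not modelled.
    """
    if len(monthly) < 24:
        raise ValueError(f"need >= 24 monthly rows, got {len(monthly)}")
    total = int(monthly["entanglements"].sum())
    if total < min_total:
        return {"fitted": False, "reason": f"only {total} entanglements in series"}
    y = monthly["entanglements"].to_numpy(dtype=float)
    trend = fit_ols(y, monthly[["year"]].astype(float))
    ok = monthly.dropna(subset=["arrival_day", "departure_day"])
    yd = ok["entanglements"].to_numpy(dtype=float)
    data = ok[["count", "arrival_day", "departure_day"]].astype(float).reset_index(drop=True)
    terms = screen_covariates(yd, data, alpha=alpha)
    combined = backward_eliminate(yd, data, terms, alpha=alpha, vif_limit=VIF_LIMIT)
    return {"fitted": True, "trend": trend, "combined": combined, "n": len(ok), "data": data, "y": yd}


def variance_attribution(model: ModelFit, term_a: str, term_b: str) -> dict:
    """t² of two retained terms and how much more variance term_a explains.

    ``percent_more`` is (t²_a / t²_b - 1) * 100, reported to the nearest
    integer; an exactly-zero t for term_b makes the comparison undefined.
    """
    tsq_a, tsq_b = model.tsq(term_a), model.tsq(term_b)
    if tsq_b == 0:
        return {"term_a": term_a, "term_b": term_b,
                "tsq": {term_a: tsq_a, term_b: tsq_b},
                "percent_more": None, "undefined": True}
    pct = (tsq_a / tsq_b - 1.0) * 100.0
    return {
        "term_a": term_a,
        "term_b": term_b,
        "tsq": {term_a: tsq_a, term_b: tsq_b},
        "percent_more": int(round(pct)),
        "undefined": False,
    }
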