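"""Weekly count aggregation and negative-binomial sighting-trend models.

Daily effort-filtered counts are summed over consecutive 7-day blocks of
the species year, with the number of retained (on-effort) days per block
carried as an exposure offset.  Weekly counts are then modelled as NB2
(variance mu + alpha*mu^2, log link) polynomials in year and month, and
the trend shape (linear / quadratic / cubic in year) is chosen by the
significance of the highest-order year term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from . import yearaxis
from .modelfit import ALPHA, SHAPE_LABELS, ModelFit

GRAY_SPLIT_WEEK = 37  # adjusted-year week separating south- and northbound gray pulses


@dataclass
class DesignSpec:
    """Centred/scaled polynomial design for the NB trend model."""

    degree_year: int = 1
    degree_month: int = 2
    interaction: bool = False
    year_mean: float = 0.0
    year_scale: float = 1.0
    month_mean: float = 6.5
    month_scale: float = 3.0

    def build(self, year: np.ndarray, month: np.ndarray) -> pd.DataFrame:
        yc = (np.asarray(year, float) - self.year_mean) / self.year_scale
        mc = (np.asarray(month, float) - self.month_mean) / self.month_scale
        cols = {}
        for k in range(1, self.degree_year + 1):
            cols["year" if k == 1 else f"year^{k}"] = yc**k
        for k in range(1, self.degree_month + 1):
            cols["month" if k == 1 else f"month^{k}"] = mc**k
        if self.interaction and self.degree_year >= 1 and self.degree_month >= 1:
            cols["year:month"] = yc * mc
        return pd.DataFrame(cols)


def split_gray(daily: pd.DataFrame, split_week: int = GRAY_SPLIT_WEEK) -> pd.DataFrame:
    """Relabel gray whale rows as gray_south / gray_north by adjusted-year week.

    The southbound (breeding) pulse occupies the first part of the
    June-1 adjusted year through mid-winter; weeks after ``split_week``
    belong to the northbound (feeding) pulse.
    """
    out = daily.copy()
    is_gray = out["species"] == "gray"
    if not is_gray.any():
        return out
    week = yearaxis.year_week(out.loc[is_gray, "date"], yearaxis.JUNE1)
    out.loc[is_gray, "species"] = np.where(week <= split_week, "gray_south", "gray_north")
    return out


def aggregate_weekly(
    daily: pd.DataFrame, species: str, year_convention: str | None = None
) -> pd.DataFrame:
    """Sum filtered daily counts into 7-day blocks of the species year.

    Gray rows with morning/evening pairs contribute (am+pm)/2 per day.
    Blocks with zero retained days are omitted (not zero-filled); the
    leftover week 53 folds into week 52.
    """
    if year_convention is None:
        year_convention = yearaxis.convention_for(species)
    grp = daily[daily["species"] == species].copy()
    grp["date"] = pd.to_datetime(grp["date"])
    if grp["date"].duplicated().any():
        raise ValueError(f"duplicate daily records for {species}")
    has_pair = (
        "count_am" in grp.columns
        and grp[["count_am", "count_pm"]].notna().all(axis=1).to_numpy()
    )
    if np.any(has_pair):
        pair_mean = (grp["count_am"] + grp["count_pm"]) / 2.0
        grp["count"] = np.where(has_pair, pair_mean, grp["count"])
    grp["species_year"] = yearaxis.species_year(grp["date"], year_convention)
    grp["week"] = yearaxis.year_week(grp["date"], year_convention)
    weekly = (
        grp.groupby(["species_year", "week"])
        .agg(count=("count", "sum"), effort_days=("count", "size"), month=("date", lambda d: d.dt.month.to_numpy().mean()))
        .reset_index()
    )
    weekly.insert(0, "species", species)
    weekly["year_centered"] = weekly["species_year"] - weekly["species_year"].mean()
    return weekly


def exclude_blue_winter_weeks(weekly: pd.DataFrame) -> pd.DataFrame:
    """Blue whales are near-absent in January-February; those weeks are dropped."""
    keep = ~((weekly["species"] == "blue") & (weekly["month"] < 2.6))
    return weekly[keep].reset_index(drop=True)


def fit_nb_trend(
    weekly: pd.DataFrame,
    degree_year: int = 1,
    degree_month: int = 2,
    interaction: bool = False,
    min_obs_per_param: int = 10,
) -> ModelFit:
    """Maximum-likelihood NB2 regression of weekly counts with a log-effort offset.

    Counts are rounded to integers (gray morning/evening averaging can
    produce halves).  Falls back to Poisson with a warning when the
    dispersion estimate collapses to the boundary; raises on
    non-convergence.
    """
    y = np.round(weekly["count"].to_numpy(dtype=float)).astype(int)
    if (y < 0).any():
        raise ValueError("weekly counts must be nonnegative")
    spec = DesignSpec(
        degree_year=degree_year,
        degree_month=degree_month,
        interaction=interaction,
        year_mean=float(weekly["species_year"].mean()),
        year_scale=float(weekly["species_year"].std() or 1.0),
        month_mean=float(weekly["month"].mean()),
        month_scale=float(weekly["month"].std() or 1.0),
    )
    X = spec.build(weekly["species_year"].to_numpy(), weekly["month"].to_numpy())
    n_params = X.shape[1] + 2  # + intercept + alpha
    if len(y) < min_obs_per_param * n_params:
        raise ValueError(
            f"{len(y)} weeks is too few for {n_params} parameters "
            f"(need {min_obs_per_param} per parameter)"
        )
    X = sm.add_constant(X, has_constant="add")
    exposure = weekly["effort_days"].to_numpy(dtype=float)
    model = sm.NegativeBinomial(y, X, exposure=exposure, loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=500, disp=0)
        if not res.mle_retvals.get("converged", False):
            res = model.fit(method="nm", maxiter=5000, disp=0)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(f"NB fit did not converge: {res.mle_retvals}")
    alpha = float(res.params["alpha"])
    if alpha <= 1e-6:
        warnings.warn("dispersion at the Poisson boundary; refitting as Poisson", stacklevel=2)
        res = sm.GLM(y, X, family=sm.families.Poisson(), exposure=exposure).fit()
        alpha = 0.0
    keep = [i for i in res.params.index if i != "alpha"]
    fit = ModelFit(
        params=res.params[keep],
        bse=res.bse[keep],
        tvalues=res.tvalues[keep],
        pvalues=res.pvalues[keep],
        nobs=int(res.nobs),
        df_resid=float(res.df_resid),
        aic=float(res.aic),
        llf=float(res.llf),
        extra={
            "alpha": alpha,
            "design": spec,
            "cov": res.cov_params().loc[keep, keep],
            "year_range": (
                float(weekly["species_year"].min()),
                float(weekly["species_year"].max()),
            ),
        },
    )
    return fit


def select_trend_shape(
    weekly: pd.DataFrame, degree_month: int = 2, interaction: bool = False, alpha: float = ALPHA
) -> tuple[str, int, ModelFit]:
    """Retain the highest-order significant year term (cubic down to linear).

    Returns ``(label, degree, fit)``; label is e.g. ``"Q(+)"`` or ``"NA"``
    when no year order is significant (the returned fit then has month
    terms only).
    """
    for degree in (3, 2, 1):
        fit = fit_nb_trend(weekly, degree_year=degree, degree_month=degree_month,
                           interaction=interaction)
        top = "year" if degree == 1 else f"year^{degree}"
        if fit.pvalues[top] < alpha:
            sign = "+" if fit.params[top] > 0 else "-"
            return f"{SHAPE_LABELS[degree]}({sign})", degree, fit
    null_fit = fit_nb_trend(weekly, degree_year=0, degree_month=degree_month)
    return "NA", 0, null_fit


def predict_weekly(
    fit: ModelFit,
    years: np.ndarray,
    months: np.ndarray,
    reference_effort: float = 7.0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Predicted mean weekly counts with delta-method CIs on the log scale.

    Predictions outside the fitted year range are allowed and flagged
    ``extrapolated``.
    """
    spec: DesignSpec = fit.extra["design"]
    X = sm.add_constant(spec.build(np.asarray(years), np.asarray(months)), has_constant="add")
    X = X[fit.params.index]
    eta = X.to_numpy() @ fit.params.to_numpy() + np.log(reference_effort)
    cov = fit.extra["cov"].to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", X.to_numpy(), cov, X.to_numpy()))
    z = sps.norm.ppf(0.5 + ci_level / 2)
    lo, hi = eta - z * se, eta + z * se
    y_lo, y_hi = fit.extra.get("year_range", (-np.inf, np.inf))
    return pd.DataFrame(
        {
            "species_year": years,
            "month": months,
            "predicted": np.exp(eta),
            "ci_low": np.exp(lo),
            "ci_high": np.exp(hi),
            "extrapolated": (np.asarray(years) < y_lo) | (np.asarray(years) > y_hi),
        }
    )
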