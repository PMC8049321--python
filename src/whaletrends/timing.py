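"""Environmental attribution of migration timing.

The protocol: each candidate environmental covariate is screened one at a
time against the timing metric with linear, quadratic and cubic
transformations; covariates whose best transformation is significant are
forwarded to a multivariable OLS model; backward stepwise elimination
then drops the worst non-significant covariate block per iteration
(demoting its polynomial order first, per the hierarchy rule) until every
retained top-order term has p < 0.05; collinearity is screened with the
variance inflation factor (VIF < 10) and parsimony confirmed against all
single-deletion submodels by AIC.  The retained model supports
margins-style partial predictions, a pre-season forecast variant, and
year-removal (leave-one-year-out) validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .modelfit import ALPHA, SHAPE_LABELS, ModelFit, fit_ols

VIF_LIMIT = 10.0


@dataclass
class CandidateTerm:
    """One covariate forwarded to the multivariable model.

    ``order`` is the polynomial order (all lower orders are implied);
    ``center`` is the training-sample mean frozen at screening time;
    ``availability_day`` is the last calendar day on which the covariate's
    raw data window closes, used for forecast eligibility.
    """

    name: str
    order: int
    center: float = 0.0
    availability_day: int = 365
    screen_p: float = np.nan

    def columns(self, x: np.ndarray) -> pd.DataFrame:
        xc = np.asarray(x, dtype=float) - self.center
        return pd.DataFrame(
            {self.name if k == 1 else f"{self.name}^{k}": xc**k for k in range(1, self.order + 1)}
        )

    @property
    def top(self) -> str:
        return self.name if self.order == 1 else f"{self.name}^{self.order}"

    @property
    def shape(self) -> str:
        return SHAPE_LABELS[self.order]


@dataclass
class TimingModelResult:
    """Final multivariable timing model."""

    terms: list[CandidateTerm]
    fit: ModelFit | None
    vif: pd.Series | None = None
    significant: bool = True
    aic_check: dict = field(default_factory=dict)
    note: str = ""

    def term_labels(self) -> dict[str, str]:
        """Table-style shape labels per covariate, e.g. ``{"soi_prev_winter": "C(-)"}``."""
        out = {}
        for t in self.terms:
            sign = "+" if self.fit.params[t.top] > 0 else "-"
            out[t.name] = f"{t.shape}({sign})"
        return out


def _design(terms: list[CandidateTerm], data: pd.DataFrame) -> pd.DataFrame:
    blocks = [t.columns(data[t.name].to_numpy()) for t in terms]
    return pd.concat([b.reset_index(drop=True) for b in blocks], axis=1)


def univariate_screen(
    y: np.ndarray,
    x: np.ndarray,
    name: str,
    max_order: int = 3,
    alpha: float = ALPHA,
    availability_day: int = 365,
) -> CandidateTerm | None:
    """Best polynomial order of one covariate against the metric, or None.

    Orders are tried from cubic down; the first whose top term is
    significant wins.  Zero-variance covariates are skipped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 6 or np.nanstd(x) == 0:
        return None
    x, y = x[ok], y[ok]
    center = float(x.mean())
    for order in range(max_order, 0, -1):
        term = CandidateTerm(name, order, center, availability_day)
        fit = fit_ols(y, term.columns(x))
        p = float(fit.pvalues[term.top])
        if p < alpha:
            term.screen_p = p
            return term
    return None


def screen_covariates(
    y: np.ndarray,
    covariates: pd.DataFrame,
    availability: dict[str, int] | None = None,
    max_order: int = 3,
    alpha: float = ALPHA,
) -> list[CandidateTerm]:
    """Screen every covariate column; forward the significant ones."""
    availability = availability or {}
    terms = []
    for name in covariates.columns:
        t = univariate_screen(
            y, covariates[name].to_numpy(), name, max_order, alpha,
            availability.get(name, 365),
        )
        if t is not None:
            terms.append(t)
    return terms


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per design column: 1/(1-R²) of each column
    regressed (with intercept) on all others; +inf on perfect collinearity."""
    cols = list(design.columns)
    if len(cols) < 2:
        return pd.Series(1.0, index=cols)
    out = {}
    X = design.to_numpy(dtype=float)
    for j, name in enumerate(cols):
        yj = X[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        sst = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 1.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def _eliminate(
    y: np.ndarray, data: pd.DataFrame, terms: list[CandidateTerm], alpha: float
) -> tuple[list[CandidateTerm], ModelFit | None]:
    terms = [replace(t) for t in terms]
    while terms:
        fit = fit_ols(y, _design(terms, data))
        worst, worst_p = None, -np.inf
        for t in terms:
            p = float(fit.pvalues[t.top])
            if np.isnan(p):
                p = 1.0
            if p < alpha:
                continue
            # demote the largest p; deterministic tie-break by name
            if p > worst_p or (p == worst_p and worst is not None and t.name < worst.name):
                worst, worst_p = t, p
        if worst is None:
            return terms, fit
        if worst.order > 1:
            worst.order -= 1  # hierarchy: re-test the next-lower order first
        else:
            terms.remove(worst)
    return [], None


def backward_eliminate(
    y: np.ndarray,
    data: pd.DataFrame,
    terms: list[CandidateTerm],
    alpha: float = ALPHA,
    vif_limit: float = VIF_LIMIT,
) -> TimingModelResult:
    """Hierarchy-preserving backward elimination with VIF and AIC checks.

    Per iteration the covariate whose top-order term has the largest
    p >= alpha is demoted one order (its whole block removed once the
    linear term falls).  After convergence any design column with
    VIF >= ``vif_limit`` triggers removal of the higher-p member of the
    offending pair and re-elimination.  An emptied model is flagged not
    significant.  ``aic_check`` reports the final AIC against all
    single-covariate-deletion submodels.
    """
    y = np.asarray(y, dtype=float)
    n_params = sum(t.order for t in terms) + 1
    if len(y) <= n_params + 2:
        # the screen can forward more terms than the sample supports; thin
        # by screening p-value before eliminating
        terms = sorted(terms, key=lambda t: (t.screen_p, t.name))[: max(1, (len(y) - 3) // 2)]
    terms, fit = _eliminate(y, data, terms, alpha)
    if not terms:
        return TimingModelResult(terms=[], fit=None, significant=False,
                                 note="elimination emptied the model")

    while len(terms) >= 1:
        design = _design(terms, data)
        v = vif(design)
        if len(v) < 2 or v.max() < vif_limit:
            break
        offenders = v.sort_values(ascending=False).index[:2]
        parents = []
        for col in offenders:
            base = col.split("^")[0]
            parents.append(next(t for t in terms if t.name == base))
        fit = fit_ols(y, design)
        drop = max(
            {p.name: p for p in parents}.values(),
            key=lambda t: (float(np.nan_to_num(fit.pvalues[t.top], nan=1.0)), t.name),
        )
        terms = [t for t in terms if t.name != drop.name]
        terms, fit = _eliminate(y, data, terms, alpha)
        if not terms:
            return TimingModelResult(terms=[], fit=None, significant=False,
                                     note="VIF screening emptied the model")

    design = _design(terms, data)
    fit = fit_ols(y, design)
    v = vif(design)

    submodels = {}
    for t in terms:
        rest = [u for u in terms if u.name != t.name]
        sub_aic = fit_ols(y, _design(rest, data)).aic if rest else fit_ols(
            y, pd.DataFrame(index=range(len(y)))
        ).aic
        submodels[t.name] = sub_aic
    aic_check = {
        "final_aic": fit.aic,
        "single_deletion_aic": submodels,
        "parsimonious_preferred": any(a < fit.aic for a in submodels.values()),
    }
    return TimingModelResult(terms=terms, fit=fit, vif=v, aic_check=aic_check)


def margins(
    result: TimingModelResult,
    data: pd.DataFrame,
    focus: str,
    grid: np.ndarray,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Partial predictions over ``grid`` of the focus covariate.

    All other covariates are held at their sample means; the CI uses the
    t critical value at residual df.  Grid points outside the observed
    covariate range are flagged.
    """
    if result.fit is None:
        raise ValueError("model is empty")
    grid = np.asarray(grid, dtype=float)
    rows = {}
    for t in result.terms:
        x = np.full(len(grid), float(data[t.name].mean())) if t.name != focus else grid
        rows.update(t.columns(x))
    X = pd.DataFrame(rows)
    X.insert(0, "const", 1.0)
    X = X[result.fit.params.index]
    cov = result.fit.extra["cov_params"].loc[result.fit.params.index, result.fit.params.index].to_numpy()
    pred = X.to_numpy() @ result.fit.params.to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", X.to_numpy(), cov, X.to_numpy()))
    tcrit = sps.t.ppf(0.5 + ci_level / 2, result.fit.df_resid)
    lo_obs, hi_obs = float(data[focus].min()), float(data[focus].max())
    return pd.DataFrame(
        {
            focus: grid,
            "predicted": pred,
            "ci_low": pred - tcrit * se,
            "ci_high": pred + tcrit * se,
            "extrapolated": (grid < lo_obs) | (grid > hi_obs),
        }
    )


def forecast_model(
    result: TimingModelResult,
    y: np.ndarray,
    data: pd.DataFrame,
    min_arrival_day: float,
    lead_days: int = 0,
) -> TimingModelResult:
    """Refit keeping only covariates whose data window closes before migration.

    A term is forecast-eligible when its ``availability_day`` is strictly
    below the species' minimum historical arrival day minus ``lead_days``.
    No re-elimination is performed; when nothing is dropped the forecast
    model equals the full model.
    """
    if result.fit is None:
        raise ValueError("cannot forecast from an empty model")
    keep = [t for t in result.terms if t.availability_day < min_arrival_day - lead_days]
    if not keep:
        return TimingModelResult(terms=[], fit=None, significant=False,
                                 note="no forecast possible: all terms close too late")
    if len(keep) == len(result.terms):
        return TimingModelResult(
            terms=result.terms, fit=result.fit, vif=result.vif,
            note="no variables removed",
        )
    fit = fit_ols(np.asarray(y, float), _design(keep, data))
    return TimingModelResult(terms=keep, fit=fit, vif=vif(_design(keep, data)))


def forecast_to_full_ratio(full_r2: float, forecast_r2: float) -> float:
    """Ratio of forecast-model to full-model (unadjusted) R²."""
    return forecast_r2 / full_r2


def year_removal_validate(
    y: np.ndarray,
    data: pd.DataFrame,
    terms: list[CandidateTerm],
    r2_definition: str = "corr",
) -> tuple[pd.DataFrame, float]:
    """Leave-one-year-out predictions with the fixed retained-term set.

    Each year is predicted from a refit on the remaining years; the
    validation R² is the squared Pearson correlation between observed and
    out-of-sample predictions (``r2_definition="sse"`` uses 1 - SSE/SST
    instead).  Years whose refit is singular get a missing prediction.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    design = _design(terms, data)
    preds = np.full(n, np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr = np.column_stack([np.ones(mask.sum()), design.to_numpy()[mask]])
        if np.linalg.matrix_rank(Xtr) < Xtr.shape[1]:
            continue
        beta, *_ = np.linalg.lstsq(Xtr, y[mask], rcond=None)
        xi = np.concatenate([[1.0], design.to_numpy()[i]])
        preds[i] = xi @ beta
    ok = ~np.isnan(preds)
    if r2_definition == "corr":
        r2 = float(np.corrcoef(y[ok], preds[ok])[0, 1] ** 2) if ok.sum() > 2 else np.nan
    elif r2_definition == "sse":
        sst = np.sum((y[ok] - y[ok].mean()) ** 2)
        r2 = float(1.0 - np.sum((y[ok] - preds[ok]) ** 2) / sst)
    else:
        raise ValueError(f"unknown r2 definition {r2_definition!r}")
    out = pd.DataFrame({"observed": y, "predicted": preds})
    return out, r2


def attribute_timing(
    timing: pd.DataFrame,
    covariates: pd.DataFrame,
    metric: str = "arrival_day",
    availability: dict[str, int] | None = None,
    alpha: float = ALPHA,
    vif_limit: float = VIF_LIMIT,
) -> dict:
    """Full protocol for one species/metric: screen, eliminate, validate.

    ``timing`` and ``covariates`` are joined on species_year.  Returns a
    dict with the full model, forecast model, validation results and the
    forecast-to-full R² ratio.
    """
    ok = timing[~timing["excluded"].astype(bool)] if "excluded" in timing.columns else timing
    merged = ok.merge(covariates, on="species_year", how="inner").dropna(subset=[metric])
    y = merged[metric].to_numpy(dtype=float)
    cov_cols = [c for c in covariates.columns if c != "species_year"]
    usable = [c for c in cov_cols if merged[c].notna().all()]
    data = merged[usable].reset_index(drop=True)
    terms = screen_covariates(y, data, availability, alpha=alpha)
    full = backward_eliminate(y, data, terms, alpha=alpha, vif_limit=vif_limit)
    out = {"metric": metric, "n_years": len(y), "full": full, "data": data, "y": y}
    if full.fit is None:
        out.update(forecast=None, validation_r2=np.nan, ratio=np.nan)
        return out
    min_arrival = float(ok["arrival_day"].min())
    fc = forecast_model(full, y, data, min_arrival)
    preds, val_r2 = year_removal_validate(y, data, full.terms)
    out.update(
        forecast=fc,
        validation=preds,
        validation_r2=val_r2,
        ratio=forecast_to_full_ratio(full.fit.rsquared, fc.fit.rsquared) if fc.fit else np.nan,
        validation_ratio=val_r2 / full.fit.rsquared if full.fit.rsquared else np.nan,
    )
    return out
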