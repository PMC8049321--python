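"""Shared model-result container and polynomial OLS helpers.

Several stages (timing trends, environmental attribution, entanglement
models) share the same protocol: fit ordinary least squares with
linear/quadratic/cubic transformations of a covariate, keep the highest
order whose top term is significant, and report coefficients with the
usual fit statistics.  The helpers here centralise that machinery so the
stage modules agree on conventions (two-sided t tests at residual df,
centred polynomial expansion, shape labels ``L``/``Q``/``C``/``NA``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

ALPHA = 0.05
SHAPE_LABELS = {1: "L", 2: "Q", 3: "C"}


@dataclass
class ModelFit:
    """Coefficients and fit statistics for a fitted regression model.

    ``params``/``bse``/``tvalues``/``pvalues`` are indexed by term name
    (including ``const``).  ``extra`` carries model-family specifics such
    as the negative-binomial dispersion ``alpha``.
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    nobs: int
    df_resid: float
    rsquared: float | None = None
    rsquared_adj: float | None = None
    aic: float | None = None
    llf: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def terms(self) -> list[str]:
        return [t for t in self.params.index if t != "const"]

    def tsq(self, term: str) -> float:
        """Squared t (or Wald z) statistic of one term."""
        return float(self.tvalues[term] ** 2)


def poly_columns(x: np.ndarray, name: str, order: int, center: bool = True) -> pd.DataFrame:
    """Expand ``x`` into polynomial columns ``name``, ``name^2``, ...

    Centring before expansion tames the collinearity of raw polynomials;
    it changes fitted values and top-order tests not at all.
    """
    x = np.asarray(x, dtype=float)
    if center:
        x = x - np.nanmean(x)
    cols = {}
    for k in range(1, order + 1):
        cols[name if k == 1 else f"{name}^{k}"] = x**k
    return pd.DataFrame(cols)


def fit_ols(y: np.ndarray, X: pd.DataFrame, add_const: bool = True) -> ModelFit:
    """OLS of ``y`` on the columns of ``X`` with the shared result container."""
    if add_const:
        X = sm.add_constant(X, has_constant="add")
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return ModelFit(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        nobs=int(res.nobs),
        df_resid=float(res.df_resid),
        rsquared=float(res.rsquared),
        rsquared_adj=float(res.rsquared_adj),
        aic=float(res.aic),
        llf=float(res.llf),
        extra={"fvalue": float(res.fvalue) if res.df_model > 0 else np.nan,
               "f_pvalue": float(res.f_pvalue) if res.df_model > 0 else np.nan,
               "cov_params": res.cov_params(),
               "mse_resid": float(res.mse_resid)},
    )


def top_term(name: str, order: int) -> str:
    return name if order == 1 else f"{name}^{order}"


def select_poly_shape(
    y: np.ndarray,
    x: np.ndarray,
    name: str = "x",
    max_order: int = 3,
    alpha: float = ALPHA,
    extra_X: pd.DataFrame | None = None,
) -> tuple[str, int, ModelFit | None]:
    """Retain the highest polynomial order of ``x`` whose top term is significant.

    Fits orders ``max_order`` down to 1 (each with all lower orders kept)
    and returns ``(label, order, fit)`` where the label carries the sign of
    the top coefficient, e.g. ``"Q(-)"``.  When no order reaches
    significance the label is ``"NA"``, order 0, and the fit is the model
    without any ``x`` term (or ``None`` when that model is empty).
    """
    y = np.asarray(y, dtype=float)
    for order in range(max_order, 0, -1):
        X = poly_columns(x, name, order)
        if extra_X is not None:
            X = pd.concat([X.reset_index(drop=True), extra_X.reset_index(drop=True)], axis=1)
        fit = fit_ols(y, X)
        top = top_term(name, order)
        if fit.pvalues[top] < alpha:
            sign = "+" if fit.params[top] > 0 else "-"
            return f"{SHAPE_LABELS[order]}({sign})", order, fit
    if extra_X is not None and extra_X.shape[1] > 0:
        return "NA", 0, fit_ols(y, extra_X)
    return "NA", 0, None
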