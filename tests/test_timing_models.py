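"""Screening, backward elimination, VIF, margins, forecast and validation."""

import numpy as np
import pandas as pd
import pytest

from whaletrends.modelfit import fit_ols
from whaletrends.timing import (
    CandidateTerm,
    backward_eliminate,
    forecast_model,
    forecast_to_full_ratio,
    margins,
    screen_covariates,
    univariate_screen,
    vif,
    year_removal_validate,
)


def brute_force_vif(design: pd.DataFrame) -> pd.Series:
    """Independent per-column auxiliary regressions rebuilt with numpy."""
    out = {}
    M = design.to_numpy(dtype=float)
    for j, col in enumerate(design.columns):
        yj = M[:, j]
        X = np.column_stack([np.ones(len(M)), np.delete(M, j, axis=1)])
        # normal equations solved explicitly, independent of the package path
        beta = np.linalg.pinv(X.T @ X) @ X.T @ yj
        r2 = 1 - np.sum((yj - X @ beta) ** 2) / np.sum((yj - yj.mean()) ** 2)
        out[col] = np.inf if r2 > 1 - 1e-12 else 1 / (1 - r2)
    return pd.Series(out)


class TestVif:
    def test_orthogonal_terms_have_unit_vif(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(50, 3))
        raw -= raw.mean(axis=0)  # centre first so QR columns stay mean-zero
        q, _ = np.linalg.qr(raw)
        design = pd.DataFrame(q, columns=["a", "b", "c"])
        v = vif(design)
        assert np.allclose(v, 1.0, atol=1e-6)

    def test_pairwise_correlation_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2000)
        r = 0.8
        z = r * x + np.sqrt(1 - r**2) * rng.normal(size=2000)
        design = pd.DataFrame({"x": x, "z": z})
        v = vif(design)
        r_emp = np.corrcoef(x, z)[0, 1]
        assert np.allclose(v, 1 / (1 - r_emp**2), rtol=1e-6)

    def test_matches_brute_force_on_five_term_fixture(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(40, 3))
        design = pd.DataFrame(
            {
                "a": base[:, 0],
                "b": base[:, 1],
                "c": base[:, 0] + 0.5 * base[:, 1] + 0.1 * rng.normal(size=40),
                "d": base[:, 2],
                "e": base[:, 2] ** 2,
            }
        )
        v = vif(design)
        oracle = brute_force_vif(design)
        assert np.allclose(v.to_numpy(), oracle.to_numpy(), rtol=1e-8)

    def test_perfect_collinearity_reports_infinity(self):
        x = np.arange(10.0)
        design = pd.DataFrame({"x": x, "x2": 2 * x})
        assert np.isinf(vif(design)).all()


class TestUnivariateScreen:
    def test_linear_signal_forwarded_at_order_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=24)
        y = 2 * x + rng.normal(0, 0.5, 24)
        term = univariate_screen(y, x, "x")
        assert term is not None and term.order == 1

    def test_quadratic_signal_forwarded_at_order_two(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=24)
        y = x**2 + rng.normal(0, 0.3, 24)
        term = univariate_screen(y, x, "x")
        assert term is not None and term.order == 2

    def test_zero_variance_covariate_skipped(self):
        y = np.random.default_rng(5).normal(size=24)
        assert univariate_screen(y, np.ones(24), "flat") is None


def make_data(rng, n=24, k=5):
    return pd.DataFrame({f"v{i}": rng.normal(size=n) for i in range(k)})


class TestBackwardElimination:
    def test_all_significant_model_is_fixed_point(self):
        rng = np.random.default_rng(6)
        data = make_data(rng, n=40, k=2)
        y = 3 * data["v0"].to_numpy() - 2 * data["v1"].to_numpy() + rng.normal(0, 0.3, 40)
        terms = screen_covariates(y, data)
        res = backward_eliminate(y, data, terms)
        assert {t.name for t in res.terms} == {"v0", "v1"}
        assert all(res.fit.pvalues[t.top] < 0.05 for t in res.terms)

    def test_true_predictor_survives_noise_competitors(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            data = make_data(rng, n=24, k=5)
            y = 2.0 * data["v0"].to_numpy() + rng.normal(0, 1.0, 24)
            res = backward_eliminate(y, data, screen_covariates(y, data))
            if any(t.name == "v0" for t in res.terms):
                hits += 1
        assert hits >= 85

    def test_duplicated_covariate_loses_exactly_one_copy(self):
        rng = np.random.default_rng(8)
        data = make_data(rng, n=30, k=1)
        data["dup"] = data["v0"]
        y = 2 * data["v0"].to_numpy() + rng.normal(0, 0.4, 30)
        terms = [CandidateTerm("v0", 1, float(data["v0"].mean())),
                 CandidateTerm("dup", 1, float(data["dup"].mean()))]
        res = backward_eliminate(y, data, terms)
        assert len(res.terms) == 1  # one copy retained, never both or neither
        assert res.vif.max() < 10

    def test_pure_noise_response_usually_empties_the_model(self):
        rng = np.random.default_rng(9)
        empties = 0
        for _ in range(50):
            data = make_data(rng, n=24, k=4)
            y = rng.normal(size=24)
            res = backward_eliminate(y, data, screen_covariates(y, data))
            if not res.terms:
                empties += 1
                assert not res.significant
        assert empties >= 25  # most replicates carry no surviving term

    def test_hierarchy_no_high_order_without_lower(self):
        rng = np.random.default_rng(10)
        data = make_data(rng, n=40, k=3)
        y = data["v0"].to_numpy() ** 2 + rng.normal(0, 0.3, 40)
        res = backward_eliminate(y, data, screen_covariates(y, data))
        for t in res.terms:
            if t.order >= 2:
                assert t.name in res.fit.params.index  # linear column present
        assert res.aic_check["final_aic"] == res.fit.aic


class TestMargins:
    def test_single_covariate_margins_equal_fitted_line(self):
        rng = np.random.default_rng(11)
        data = pd.DataFrame({"x": rng.normal(size=30)})
        y = 1.5 * data["x"].to_numpy() + rng.normal(0, 0.2, 30)
        res = backward_eliminate(y, data, screen_covariates(y, data))
        grid = np.linspace(-2, 2, 5)
        m = margins(res, data, "x", grid)
        t = res.terms[0]
        expect = res.fit.params["const"] + res.fit.params["x"] * (grid - t.center)
        assert np.allclose(m["predicted"], expect)

    def test_two_covariate_margins_match_hand_linear_algebra(self):
        rng = np.random.default_rng(12)
        data = pd.DataFrame({"x": rng.normal(size=40), "z": rng.normal(size=40)})
        y = 2 * data["x"].to_numpy() - 3 * data["z"].to_numpy() + rng.normal(0, 0.2, 40)
        res = backward_eliminate(y, data, screen_covariates(y, data))
        assert {t.name for t in res.terms} == {"x", "z"}
        grid = np.array([-1.0, 0.0, 2.0])
        m = margins(res, data, "x", grid)
        cx = next(t.center for t in res.terms if t.name == "x")
        cz = next(t.center for t in res.terms if t.name == "z")
        beta = res.fit.params
        hand = (
            beta["const"]
            + beta["x"] * (grid - cx)
            + beta["z"] * (data["z"].mean() - cz)
        )
        assert np.allclose(m["predicted"], hand)
        assert (m["ci_low"] < m["predicted"]).all() and (m["predicted"] < m["ci_high"]).all()

    def test_prediction_at_focus_mean_equals_mean_fitted_value(self):
        rng = np.random.default_rng(13)
        data = pd.DataFrame({"x": rng.normal(size=30)})
        y = 1.5 * data["x"].to_numpy() + rng.normal(0, 0.2, 30)
        res = backward_eliminate(y, data, screen_covariates(y, data))
        m = margins(res, data, "x", np.array([data["x"].mean()]))
        assert m["predicted"].iloc[0] == pytest.approx(float(np.mean(y)), abs=1e-8)


class TestForecast:
    def _fitted(self, rng, availability):
        data = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        y = 2 * data["a"].to_numpy() + 1.5 * data["b"].to_numpy() + rng.normal(0, 0.4, 30)
        terms = screen_covariates(y, data, availability)
        res = backward_eliminate(y, data, terms)
        return data, y, res

    def test_all_preseason_terms_give_ratio_one(self):
        rng = np.random.default_rng(14)
        data, y, res = self._fitted(rng, {"a": 0, "b": 0})  # both close pre-season
        fc = forecast_model(res, y, data, min_arrival_day=150)
        assert fc.note == "no variables removed"
        assert forecast_to_full_ratio(res.fit.rsquared, fc.fit.rsquared) == pytest.approx(1.0)

    def test_late_closing_term_dropped_and_r2_nested(self):
        rng = np.random.default_rng(15)
        data, y, res = self._fitted(rng, {"a": 0, "b": 243})  # b closes after arrival
        fc = forecast_model(res, y, data, min_arrival_day=150)
        assert {t.name for t in fc.terms} == {"a"}
        assert fc.fit.rsquared <= res.fit.rsquared + 1e-12

    def test_no_eligible_terms_flagged(self):
        rng = np.random.default_rng(16)
        data, y, res = self._fitted(rng, {"a": 365, "b": 365})
        fc = forecast_model(res, y, data, min_arrival_day=100)
        assert fc.fit is None and not fc.significant


class TestYearRemoval:
    def test_noiseless_linear_data_validates_perfectly(self):
        x = np.linspace(-2, 2, 24)
        data = pd.DataFrame({"x": x})
        y = 3 * x + 1
        terms = [CandidateTerm("x", 1, float(x.mean()))]
        _, r2 = year_removal_validate(y, data, terms)
        assert r2 == pytest.approx(1.0)

    def test_matches_independent_fold_rebuilding_loop(self):
        rng = np.random.default_rng(17)
        data = pd.DataFrame({"x": rng.normal(size=24), "z": rng.normal(size=24)})
        y = 2 * data["x"].to_numpy() - data["z"].to_numpy() + rng.normal(0, 0.5, 24)
        terms = [CandidateTerm("x", 1, float(data["x"].mean())),
                 CandidateTerm("z", 2, float(data["z"].mean()))]
        preds, _ = year_removal_validate(y, data, terms)
        # oracle: rebuild the raw design per fold from scratch
        for i in range(24):
            mask = np.arange(24) != i
            cols = []
            for t in terms:
                for k in range(1, t.order + 1):
                    cols.append((data[t.name].to_numpy() - t.center) ** k)
            M = np.column_stack([np.ones(24)] + cols)
            beta = np.linalg.lstsq(M[mask], y[mask], rcond=None)[0]
            assert preds["predicted"].iloc[i] == pytest.approx(M[i] @ beta, rel=1e-9)

    def test_noise_response_validates_near_zero(self):
        # under the skill-based (1 - SSE/SST) definition, out-of-sample
        # predictions of pure noise have no skill
        rng = np.random.default_rng(18)
        vals = []
        for _ in range(100):
            data = pd.DataFrame({"x": rng.normal(size=24)})
            y = rng.normal(size=24)
            full = fit_ols(y, data[["x"]])
            _, r2 = year_removal_validate(y, data, [CandidateTerm("x", 1, 0.0)],
                                          r2_definition="sse")
            vals.append((r2, full.rsquared))
        assert np.median([v[0] for v in vals]) < 0.1
        # validation does not systematically beat the in-sample fit
        assert np.mean([v[0] <= v[1] + 0.05 for v in vals]) > 0.8
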