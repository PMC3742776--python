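import json
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.stats import norm

from mirapanel.errors import (
    CollinearityError,
    DegenerateOutcomeError,
    InputError,
    NonIdentifiableError,
    SeparationError,
)
from mirapanel.regression import (
    Logistic,
    LogisticResults,
    Tobit,
    Z_95,
    classify,
    logistic_fit,
    lrt,
    tobit_fit,
)


def _two_by_two():
    """a=10 exposed events, b=5 exposed nonevents, c=5, d=10 -> OR 4."""
    x = np.r_[np.ones(15), np.zeros(15)]
    y = np.r_[np.ones(10), np.zeros(5), np.ones(5), np.zeros(10)]
    X = pd.DataFrame({"intercept": np.ones(30), "exposed": x})
    return X, y


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = logistic_fit(np.ones((100, 1)), y)
        assert fit.params.iloc[0] == pytest.approx(np.log(0.3 / 0.7), abs=1e-8)

    def test_two_by_two_odds_ratio_and_woolf_ci(self):
        X, y = _two_by_two()
        fit = logistic_fit(X, y)
        ors = fit.odds_ratios()
        assert ors.loc["exposed", "or"] == pytest.approx(4.0, abs=1e-8)
        se = np.sqrt(1 / 10 + 1 / 5 + 1 / 5 + 1 / 10)
        assert ors.loc["exposed", "ci_low"] == pytest.approx(np.exp(np.log(4) - Z_95 * se), rel=1e-6)
        assert ors.loc["exposed", "ci_high"] == pytest.approx(np.exp(np.log(4) + Z_95 * se), rel=1e-6)

    def test_symmetric_design_zero_slope(self):
        x = np.r_[1.0, -1.0, 1.0, -1.0]
        y = np.r_[1.0, 1.0, 0.0, 0.0]
        fit = logistic_fit(pd.DataFrame({"intercept": np.ones(4), "x": x}), y)
        assert fit.params["x"] == pytest.approx(0.0, abs=1e-8)

    def test_matches_gradient_free_optimizer(self):
        """Independent oracle: Nelder-Mead on the raw binomial likelihood."""
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(40), rng.standard_normal((40, 2))])
        y = (rng.random(40) < 0.5).astype(float)
        fit = Logistic(X, y).fit()

        def nll(b):
            eta = X @ b
            return -(y @ eta - np.logaddexp(0, eta).sum())

        res = optimize.minimize(nll, np.zeros(3), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        assert fit.llf == pytest.approx(-res.fun, abs=1e-6)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        for _ in range(5):
            X = np.column_stack([np.ones(120), rng.standard_normal((120, 3))])
            y = (rng.random(120) < 1 / (1 + np.exp(-X[:, 1]))).astype(float)
            mine = Logistic(X, y).fit()
            ref = sm.Logit(y, X).fit(disp=0)
            assert mine.llf == pytest.approx(ref.llf, abs=1e-6)
            np.testing.assert_allclose(mine._beta, ref.params, atol=1e-6)
            np.testing.assert_allclose(mine.bse.to_numpy(), ref.bse, rtol=1e-4)

    def test_degenerate_and_collinear_errors(self):
        X = np.ones((20, 1))
        with pytest.raises(DegenerateOutcomeError):
            logistic_fit(X, np.ones(20))
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        Xc = pd.DataFrame({"intercept": np.ones(50), "a": x, "b": 2 * x})
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(CollinearityError, match="b"):
            logistic_fit(Xc, y)

    def test_separation_detected(self):
        x = np.r_[np.linspace(-2, -1, 25), np.linspace(1, 2, 25)]
        y = np.r_[np.zeros(25), np.ones(25)]
        with pytest.raises(SeparationError):
            logistic_fit(pd.DataFrame({"intercept": np.ones(50), "x": x}), y)

    def test_classification_threshold_inclusive(self):
        """Probability exactly 0.5 classifies as impaired (>= rule)."""
        y = np.r_[np.ones(10), np.zeros(10)]
        fit = logistic_fit(np.ones((20, 1)), y)  # fitted p = 0.5 everywhere
        assert fit.predictions[0] == pytest.approx(0.5)
        assert classify(fit).tolist() == [1] * 20
        assert (fit.predictions >= 0.5).astype(int).tolist() == classify(fit).tolist()

    def test_classify_rejects_tobit(self, cohort150):
        from mirapanel.cohort import design_matrix

        X, wmis, _ = design_matrix(cohort150, ("ntprobnp",), ())
        with pytest.raises(InputError):
            classify(tobit_fit(X, wmis))

    def test_deviance_residual_identity(self, cohort150):
        from mirapanel.cohort import design_matrix

        X, _, imp = design_matrix(cohort150, ("ntprobnp", "anterior"), ())
        fit = logistic_fit(X, imp)
        assert (fit.residuals() ** 2).sum() == pytest.approx(-2 * fit.llf, rel=1e-10)


class TestTobit:
    def test_zero_censoring_equals_gaussian_mle(self):
        rng = np.random.default_rng(11)
        X = np.column_stack([np.ones(200), rng.standard_normal(200)])
        y = 5 + 0.7 * X[:, 1] + 0.5 * rng.standard_normal(200)
        fit = tobit_fit(X, y, censor_floor=0.0)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ols
        sigma_mle = np.sqrt(resid @ resid / len(y))  # 1/n, not 1/(n-k)
        np.testing.assert_allclose(fit._beta, beta_ols, atol=1e-6)
        assert fit.scale == pytest.approx(sigma_mle, abs=1e-6)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(5000)
        y = np.clip(1 + 0.5 * x + 0.3 * rng.standard_normal(5000), 1.0, None)
        fit = tobit_fit(pd.DataFrame({"intercept": np.ones(5000), "x": x}), y)
        assert fit.params["x"] == pytest.approx(0.5, abs=0.05)
        assert fit.scale == pytest.approx(0.3, abs=0.03)

    def test_optimum_is_local_maximum(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(300)
        y = np.clip(1 + 0.4 * x + 0.3 * rng.standard_normal(300), 1.0, None)
        X = np.column_stack([np.ones(300), x])
        fit = Tobit(X, y).fit()

        def llf(beta, sigma):
            xb = X @ beta
            cens = y <= 1.0 + 1e-12
            ll = norm.logpdf((y[~cens] - xb[~cens]) / sigma).sum() - (~cens).sum() * np.log(sigma)
            return ll + norm.logcdf((1.0 - xb[cens]) / sigma).sum()

        best = llf(fit._beta, fit.scale)
        assert best == pytest.approx(fit.llf, abs=1e-8)
        for db in ([0.01, 0], [-0.01, 0], [0, 0.01], [0, -0.01]):
            assert llf(fit._beta + np.array(db), fit.scale) <= best
        assert llf(fit._beta, fit.scale + 0.01) <= best
        assert llf(fit._beta, fit.scale - 0.01) <= best

    def test_matches_r_survreg(self, tmp_path):
        """Independent oracle: survival::survreg left-censored gaussian fit."""
        rng = np.random.default_rng(8)
        x1 = rng.standard_normal(80)
        x2 = (rng.random(80) < 0.4).astype(float)
        y = np.clip(1 + 0.5 * x1 - 0.3 * x2 + 0.4 * rng.standard_normal(80), 1.0, None)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = f"""
        d <- read.csv("{csv}")
        library(survival)
        f <- survreg(Surv(y, y > 1, type="left") ~ x1 + x2, data=d, dist="gaussian")
        cat(jsonlite::toJSON(list(coef=as.numeric(coef(f)), scale=f$scale)))
        """
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout[out.stdout.index("{"):])
        fit = tobit_fit(pd.DataFrame({"intercept": np.ones(80), "x1": x1, "x2": x2}), y)
        np.testing.assert_allclose(fit._beta, ref["coef"], atol=1e-4)
        assert fit.scale == pytest.approx(ref["scale"][0], abs=1e-4)

    def test_data_errors(self):
        X = np.ones((10, 1))
        with pytest.raises(InputError):
            tobit_fit(X, np.r_[np.full(9, 1.5), 0.5])  # below the floor
        with pytest.raises(NonIdentifiableError):
            tobit_fit(X, np.ones(10))  # everything censored


@pytest.fixture(scope="module")
def fit150(cohort150):
    from mirapanel.cohort import design_matrix

    X, _, imp = design_matrix(cohort150, ("ntprobnp", "anterior"), ())
    return logistic_fit(X, imp)


class TestTests:

    def test_wald_single_term_equals_z_squared(self, fit150):
        tr = fit150.wald_global(["ntprobnp"])
        b = fit150.params["ntprobnp"]
        se = fit150.bse["ntprobnp"]
        assert tr.statistic == pytest.approx((b / se) ** 2, rel=1e-10)
        assert tr.p_value == pytest.approx(2 * norm.sf(abs(b / se)), rel=1e-9)
        per_term = {t.term: t for t in fit150.term_tests()}
        assert per_term["ntprobnp"].p_value == pytest.approx(tr.p_value, rel=1e-12)

    def test_wald_zero_coefficients(self, fit150):
        degenerate = LogisticResults(
            fit150.exog, fit150.term_names, fit150.endog,
            np.zeros(len(fit150.term_names)), np.eye(len(fit150.term_names)),
            fit150.llf, fit150.k, fit150.predictions, True, 1,
        )
        tr = degenerate.wald_global()
        assert tr.statistic == 0.0 and tr.p_value == 1.0

    def test_lrt_identities(self, cohort150):
        from mirapanel.cohort import design_matrix

        Xb, _, imp = design_matrix(cohort150, ("ntprobnp",), ())
        Xf, _, _ = design_matrix(cohort150, ("ntprobnp",), ("mir_16",))
        fb, ff = logistic_fit(Xb, imp), logistic_fit(Xf, imp)
        same = lrt(fb, fb)
        assert same.statistic == 0.0 and same.p_value == 1.0
        full = lrt(fb, ff)
        assert full.statistic >= 0.0
        assert full.df == 1

    def test_lrt_invariant_to_predictor_rescaling(self, cohort150):
        from mirapanel.cohort import design_matrix

        Xb, _, imp = design_matrix(cohort150, ("ntprobnp",), ())
        Xf, _, _ = design_matrix(cohort150, ("ntprobnp",), ("mir_16",))
        Xf2 = Xf.copy()
        Xf2["mir_16"] = 3.0 * Xf2["mir_16"] + 7.0
        p1 = lrt(logistic_fit(Xb, imp), logistic_fit(Xf, imp)).p_value
        p2 = lrt(logistic_fit(Xb, imp), logistic_fit(Xf2, imp)).p_value
        assert p1 == pytest.approx(p2, rel=1e-8)

    def test_lrt_usage_errors(self, cohort150):
        from mirapanel.cohort import design_matrix

        Xb, wmis, imp = design_matrix(cohort150, ("ntprobnp",), ())
        lf = logistic_fit(Xb, imp)
        tf = tobit_fit(Xb, wmis)
        with pytest.raises(InputError):
            lrt(lf, tf)

    def test_aic_identity_both_families(self, cohort150):
        from mirapanel.cohort import design_matrix

        X, wmis, imp = design_matrix(cohort150, ("ntprobnp", "anterior"), ())
        lf = logistic_fit(X, imp)
        tf = tobit_fit(X, wmis)
        assert lf.aic == pytest.approx(2 * lf.k - 2 * lf.llf, abs=1e-12)
        assert lf.k == X.shape[1]
        assert tf.aic == pytest.approx(2 * tf.k - 2 * tf.llf, abs=1e-12)
        assert tf.k == X.shape[1] + 1  # sigma is estimated too

    def test_tobit_residual_normality(self):
        """On uncensored gaussian data standardized residuals look normal."""
        from scipy.stats import normaltest

        ok = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            x = rng.standard_normal(500)
            y = 5 + 0.5 * x + 0.4 * rng.standard_normal(500)
            f = tobit_fit(np.column_stack([np.ones(500), x]), y, censor_floor=0.0)
            r = f.residuals()
            ok += int(normaltest(r.residual[~r.censored]).pvalue > 0.01)
        assert ok >= 95
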