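"""Maximum-likelihood regression for the two model families.

Two families model the follow-up wall motion index score:

* **logistic** — WMIS dichotomised at a threshold (impaired vs preserved),
  fitted by Newton-Raphson / IRLS on the binomial log-likelihood;
* **tobit** — WMIS as a continuous outcome left-censored at the floor L
  (fully preserved contractility).  The log-likelihood

      ll(b, s) = sum_{y_i > L} [log phi((y_i - x_i b)/s) - log s]
               + sum_{y_i = L}  log Phi((L - x_i b)/s)

  is maximised over (b, log s) with analytic gradients; observations within
  1e-12 of L are treated as censored.

Both families follow the statsmodels convention: a model object built from
data whose ``fit()`` returns a results object carrying estimates, covariance
(inverse observed information), log-likelihood, AIC = 2k - 2*ll, per-patient
predictions, tests and a ``summary()`` table.  ``k`` counts the intercept
and, for tobit, the scale parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .errors import (
    CollinearityError,
    ConvergenceError,
    DegenerateOutcomeError,
    InputError,
    NonIdentifiableError,
    SeparationError,
)

#: z quantile used for all 95% confidence intervals.
Z_95 = 1.959964

#: |beta| * sd(x) beyond which a logistic fit is declared separated.
SEPARATION_BOUND = 15.0

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, degrees of freedom, p-value, kind."""

    statistic: float
    df: int
    p_value: float
    kind: str  # {wald_global, wald_term, z_term, lrt}
    term: str | None = None


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return np.ascontiguousarray(X.to_numpy(dtype=float)), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InputError("design matrix must be 2-D")
    return X, [f"x{j}" for j in range(X.shape[1])]


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    # QR diagonal exposes which columns are (numerically) dependent.
    R = np.linalg.qr(X, mode="r")
    d = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (d.max() if d.size else 0.0)
    bad = [names[j] for j in range(len(d)) if d[j] <= tol]
    if bad:
        raise CollinearityError(bad)


class RegressionResults:
    """Fitted model: coefficients, covariance, likelihood, predictions, tests."""

    family: str = ""

    def __init__(self, X, names, y, beta, cov, llf, k, predictions, converged, iterations,
                 scale=None):
        self.exog = X
        self.term_names = list(names)
        self.endog = y
        self._beta = beta
        self._cov = cov
        self.scale = scale
        self.llf = float(llf)
        self.k = int(k)
        self.nobs = int(len(y))
        self.predictions = predictions
        self.converged = bool(converged)
        self.iterations = int(iterations)

    # ----- basic accessors ---------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self._beta, index=self.term_names, name="coef")

    def cov_params(self) -> pd.DataFrame:
        p = len(self.term_names)
        return pd.DataFrame(self._cov[:p, :p], index=self.term_names, columns=self.term_names)

    @property
    def bse(self) -> pd.Series:
        p = len(self.term_names)
        return pd.Series(np.sqrt(np.diag(self._cov)[:p]), index=self.term_names, name="se")

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.llf

    # ----- tests --------------------------------------------------------
    def wald_global(self, terms: Sequence[str] | None = None) -> TestResult:
        """Wald chi-square for the joint nullity of ``terms``.

        Defaults to every non-intercept coefficient ("global effect of the
        explanatory variables").
        """
        if terms is None:
            terms = [t for t in self.term_names if t != "intercept"]
        idx = []
        for t in terms:
            if t not in self.term_names:
                raise InputError(f"term {t!r} not in fit")
            idx.append(self.term_names.index(t))
        b = self._beta[idx]
        V = self._cov[np.ix_(idx, idx)]
        try:
            W = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError as exc:
            raise InputError(f"singular sub-covariance for terms {list(terms)}") from exc
        df = len(idx)
        return TestResult(W, df, float(chi2_dist.sf(W, df)), "wald_global")

    def term_tests(self) -> list[TestResult]:
        """Per-term nullity tests: Wald chi-square (logistic) or Z (tobit)."""
        out = []
        se = np.sqrt(np.diag(self._cov))
        for j, t in enumerate(self.term_names):
            z = self._beta[j] / se[j]
            if self.family == "logistic":
                out.append(TestResult(z * z, 1, float(chi2_dist.sf(z * z, 1)), "wald_term", t))
            else:
                out.append(TestResult(float(z), 1, float(2 * norm.sf(abs(z))), "z_term", t))
        return out

    def residuals(self):
        raise NotImplementedError

    def summary(self) -> str:
        se = self.bse
        lines = [
            f"{self.family} regression  n={self.nobs}  k={self.k}  "
            f"loglik={self.llf:.4f}  AIC={self.aic:.3f}  "
            f"converged={self.converged} ({self.iterations} it)",
            f"{'term':<24}{'coef':>12}{'se':>12}{'ci_low':>12}{'ci_high':>12}{'p':>12}",
        ]
        for tr in self.term_tests():
            b = self.params[tr.term]
            s = se[tr.term]
            lines.append(
                f"{tr.term:<24}{b:>12.4f}{s:>12.4f}{b - Z_95 * s:>12.4f}"
                f"{b + Z_95 * s:>12.4f}{tr.p_value:>12.4g}"
            )
        if self.scale is not None:
            lines.append(f"{'sigma':<24}{self.scale:>12.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-ready serialisation (coefficients, se, tests, fit statistics)."""
        d = {
            "family": self.family,
            "n": self.nobs,
            "k": self.k,
            "loglik": self.llf,
            "aic": self.aic,
            "converged": self.converged,
            "iterations": self.iterations,
            "coefficients": {t: float(b) for t, b in zip(self.term_names, self._beta)},
            "se": {t: float(s) for t, s in self.bse.items()},
            "p_values": {tr.term: tr.p_value for tr in self.term_tests()},
        }
        if self.scale is not None:
            d["sigma"] = float(self.scale)
        if self.family == "logistic":
            d["odds_ratios"] = {
                t: {"or": float(r["or"]), "ci_low": float(r["ci_low"]),
                    "ci_high": float(r["ci_high"])}
                for t, r in self.odds_ratios().iterrows()
            }
        return d


class LogisticResults(RegressionResults):
    family = "logistic"

    def predict(self, X) -> np.ndarray:
        """Fitted event probabilities for design matrix ``X``."""
        M, _ = _as_matrix(X)
        return special.expit(M @ self._beta)

    def classify(self, X=None) -> np.ndarray:
        """Predicted class: 1 iff fitted probability >= 0.5 (inclusive)."""
        p = self.predictions if X is None else self.predict(X)
        return (p >= 0.5).astype(int)

    def odds_ratios(self, level: float = 0.95) -> pd.DataFrame:
        """exp(beta) with Wald confidence limits, intercept excluded."""
        z = Z_95 if level == 0.95 else float(norm.ppf(0.5 + level / 2.0))
        rows = {}
        se = self.bse
        for t in self.term_names:
            if t == "intercept":
                continue
            b, s = self.params[t], se[t]
            rows[t] = {"or": np.exp(b), "ci_low": np.exp(b - z * s), "ci_high": np.exp(b + z * s)}
        return pd.DataFrame.from_dict(rows, orient="index")

    def residuals(self) -> np.ndarray:
        """Deviance residuals; their sum of squares is the model deviance."""
        y, p = self.endog, np.clip(self.predictions, 1e-12, 1 - 1e-12)
        dev = -2.0 * (y * np.log(p) + (1 - y) * np.log1p(-p))
        return np.sign(y - p) * np.sqrt(np.maximum(dev, 0.0))


class TobitResults(RegressionResults):
    family = "tobit"

    def __init__(self, *args, censor_floor=1.0, **kwargs):
        super().__init__(*args, **kwargs)
        self.censor_floor = float(censor_floor)

    def predict(self, X) -> np.ndarray:
        """Latent mean x @ beta."""
        M, _ = _as_matrix(X)
        return M @ self._beta

    def exceedance_prob(self, X, threshold: float) -> np.ndarray:
        """Model-implied P(latent outcome > threshold | x) = 1 - Phi((t - xb)/s)."""
        return norm.sf((threshold - self.predict(X)) / self.scale)

    def residuals(self) -> pd.DataFrame:
        """Standardised residuals for uncensored rows; censored rows flagged (NaN)."""
        xb = self.exog @ self._beta
        cens = self.endog <= self.censor_floor + 1e-12
        r = (self.endog - xb) / self.scale
        r = np.where(cens, np.nan, r)
        return pd.DataFrame({"residual": r, "censored": cens})


class Logistic:
    """Binary-outcome logistic regression model (statsmodels-style)."""

    def __init__(self, X, y):
        self.X, self.names = _as_matrix(X)
        self.y = np.asarray(y, dtype=float).ravel()
        if len(self.y) != self.X.shape[0]:
            raise InputError("X and y lengths differ")
        if not np.all(np.isin(self.y, (0.0, 1.0))):
            raise InputError("y must be binary 0/1")

    def fit(self, tol: float = 1e-10, max_iter: int = 200) -> LogisticResults:
        X, y, names = self.X, self.y, self.names
        if y.min() == y.max():
            raise DegenerateOutcomeError("outcome has a single class")
        _check_rank(X, names)
        n, p = X.shape
        beta = np.zeros(p)
        llf = -n * np.log(2.0)  # ll at beta = 0
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            eta = X @ beta
            mu = special.expit(eta)
            w = mu * (1.0 - mu)
            grad = X.T @ (y - mu)
            H = (X * w[:, None]).T @ X
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError("singular information matrix") from exc
            new_beta = beta + step
            new_llf = self._llf(new_beta)
            # step-halving if the full Newton step overshoots
            halvings = 0
            while new_llf < llf - 1e-12 and halvings < 30:
                step *= 0.5
                new_beta = beta + step
                new_llf = self._llf(new_beta)
                halvings += 1
            rel = abs(new_llf - llf) / (abs(new_llf) + 0.1)
            beta, llf = new_beta, new_llf
            if rel < tol:
                converged = True
                break
        # quasi-separation: runaway standardized coefficients
        sds = X.std(axis=0)
        scaled = np.abs(beta) * np.where(sds > 0, sds, 0.0)
        if np.any(scaled > SEPARATION_BOUND):
            bad = [names[j] for j in np.nonzero(scaled > SEPARATION_BOUND)[0]]
            raise SeparationError(
                f"quasi-complete separation suspected (|beta|*sd > {SEPARATION_BOUND}) "
                f"for columns: {bad}"
            )
        if not converged:
            raise ConvergenceError(f"logistic IRLS did not converge in {max_iter} iterations")
        eta = X @ beta
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        cov = np.linalg.inv(H)
        return LogisticResults(X, names, y, beta, cov, llf, p, mu, converged, it)

    def _llf(self, beta: np.ndarray) -> float:
        eta = self.X @ beta
        return float(self.y @ eta - np.logaddexp(0.0, eta).sum())


class Tobit:
    """Left-censored (tobit) regression with a known censoring floor."""

    def __init__(self, X, y, censor_floor: float = 1.0):
        self.X, self.names = _as_matrix(X)
        self.y = np.asarray(y, dtype=float).ravel()
        self.censor_floor = float(censor_floor)
        if len(self.y) != self.X.shape[0]:
            raise InputError("X and y lengths differ")
        if np.any(self.y < self.censor_floor - 1e-12):
            raise InputError("observations below the censoring floor")

    def fit(self, max_iter: int = 300) -> TobitResults:
        X, y, names, L = self.X, self.y, self.names, self.censor_floor
        _check_rank(X, names)
        n, p = X.shape
        cens = y <= L + 1e-12
        if cens.all():
            raise NonIdentifiableError("all observations censored at the floor")

        if not cens.any():
            # Likelihood reduces to the uncensored normal: closed-form MLE.
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            sigma = float(np.sqrt(resid @ resid / n))
            llf = float(-0.5 * n * (_LOG_2PI + 1.0) - n * np.log(sigma))
            cov = np.zeros((p + 1, p + 1))
            cov[:p, :p] = sigma**2 * np.linalg.inv(X.T @ X)
            cov[p, p] = sigma**2 / (2.0 * n)
            return TobitResults(X, names, y, beta, cov, llf, p + 1, X @ beta, True, 0,
                                scale=sigma, censor_floor=L)

        Xu, yu = X[~cens], y[~cens]
        Xc = X[cens]

        def negll_grad(theta):
            beta, logs = theta[:p], theta[p]
            s = np.exp(logs)
            ru = (yu - Xu @ beta) / s
            zc = (L - Xc @ beta) / s
            logcdf = norm.logcdf(zc)
            nll = -(
                -0.5 * (ru @ ru) - len(yu) * (0.5 * _LOG_2PI + logs) + logcdf.sum()
            )
            lam = np.exp(norm.logpdf(zc) - logcdf)  # inverse Mills ratio
            gbeta = Xu.T @ (ru / s) - Xc.T @ (lam / s)
            glogs = float((ru @ ru) - len(yu) - (lam @ zc))
            return nll, -np.concatenate([gbeta, [glogs]])

        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta0
        s0 = max(float(np.sqrt(resid @ resid / n)), 1e-3)
        theta0 = np.concatenate([beta0, [np.log(s0)]])
        res = optimize.minimize(negll_grad, theta0, jac=True, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": max_iter})
        theta, n_iter = res.x, res.nit
        gmax = float(np.max(np.abs(res.jac)))
        # Newton polish: BFGS near the optimum can stall on line-search
        # precision loss; a few damped Newton steps restore |grad| < 1e-6.
        for _ in range(20):
            if gmax < 1e-6:
                break
            g = negll_grad(theta)[1]
            H = _fd_hessian(lambda t: negll_grad(t)[1], theta)
            try:
                step = np.linalg.solve(0.5 * (H + H.T), g)
            except np.linalg.LinAlgError:
                break
            f0 = negll_grad(theta)[0]
            scale_ = 1.0
            while scale_ > 1e-4 and negll_grad(theta - scale_ * step)[0] > f0 + 1e-12:
                scale_ *= 0.5
            theta = theta - scale_ * step
            gmax = float(np.max(np.abs(negll_grad(theta)[1])))
            n_iter += 1
        if not (gmax < 1e-4 * (1.0 + abs(negll_grad(theta)[0]))):
            raise ConvergenceError(f"tobit optimizer failed: {res.message} (|grad|={gmax:.2e})")
        beta, sigma = theta[:p], float(np.exp(theta[p]))
        H = _fd_hessian(lambda t: negll_grad(t)[1], theta)
        H = 0.5 * (H + H.T)
        try:
            cov_theta = np.linalg.inv(H)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular observed information at the tobit optimum") from exc
        # delta method (beta, log s) -> (beta, s)
        J = np.eye(p + 1)
        J[p, p] = sigma
        cov = J @ cov_theta @ J
        llf = float(-negll_grad(theta)[0])
        return TobitResults(X, names, y, beta, cov, llf, p + 1, X @ beta, True, n_iter,
                            scale=sigma, censor_floor=L)


def _fd_hessian(grad_fn, theta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of an analytic gradient."""
    m = len(theta)
    H = np.empty((m, m))
    for j in range(m):
        h = eps * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2.0 * h)
    return H


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def logistic_fit(X, y) -> LogisticResults:
    """Fit a logistic regression; see :class:`Logistic`."""
    return Logistic(X, y).fit()


def tobit_fit(X, y, censor_floor: float = 1.0) -> TobitResults:
    """Fit a left-censored tobit regression; see :class:`Tobit`."""
    return Tobit(X, y, censor_floor=censor_floor).fit()


def lrt(nested: RegressionResults, full: RegressionResults) -> TestResult:
    """Likelihood ratio test of ``nested`` within ``full``."""
    if nested.family != full.family:
        raise InputError("LRT requires the same model family")
    if nested.nobs != full.nobs:
        raise InputError("LRT requires the same observations")
    if not set(nested.term_names) <= set(full.term_names):
        raise InputError("models are not nested")
    stat = 2.0 * (full.llf - nested.llf)
    if stat < -1e-6:
        raise InputError("full-model likelihood below nested-model likelihood")
    stat = max(stat, 0.0)
    df = full.k - nested.k
    p = float(chi2_dist.sf(stat, df)) if df > 0 else 1.0
    return TestResult(stat, max(df, 1), p if df > 0 else 1.0, "lrt")


def wald_global(fit: RegressionResults, terms: Sequence[str] | None = None) -> TestResult:
    """Module-level alias for :meth:`RegressionResults.wald_global`."""
    return fit.wald_global(terms)


def classify(fit: LogisticResults, X=None) -> np.ndarray:
    """Module-level alias for :meth:`LogisticResults.classify`."""
    if fit.family != "logistic":
        raise InputError("classification is defined for logistic fits only")
    return fit.classify(X)


def odds_ratios(fit: LogisticResults, level: float = 0.95) -> pd.DataFrame:
    if fit.family != "logistic":
        raise InputError("odds ratios are defined for logistic fits only")
    return fit.odds_ratios(level)
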