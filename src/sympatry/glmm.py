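"""Maximum-likelihood binomial GLMM with a single random intercept.

The marginal likelihood of each cluster integrates the Bernoulli likelihood
over a Gaussian random intercept; the integral is evaluated by Gauss-Hermite
quadrature (exact for polynomial integrands, accurate here for the modest
intercept SDs typical of presence/absence data).  The fixed effects and the
intercept SD are optimised jointly by L-BFGS-B on (beta, log sigma_u).

This mirrors what ``glmer`` does for a random-intercept logistic model and
is validated against it in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats


def _bernoulli_loglik(logit: np.ndarray, y: np.ndarray) -> np.ndarray:
    # -log(1 + exp(-logit)) if y==1 else -log(1 + exp(logit)), stably
    signed = np.where(y[:, None] > 0, -logit, logit)
    return -np.logaddexp(0.0, signed)


@dataclass
class BinomialGLMMResult:
    """Fitted random-intercept logistic model."""

    exog_names: list
    params: np.ndarray          # fixed effects
    bse: np.ndarray
    sigma_u: float              # random-intercept SD
    llf: float
    aic: float
    nobs: int
    n_groups: int
    converged: bool
    cov_params: np.ndarray = field(repr=False, default=None)

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.zvalues))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.exog_names, "estimate": self.params,
            "se": self.bse, "stat": self.zvalues, "p": self.pvalues,
        })

    def predict(self, exog: np.ndarray) -> np.ndarray:
        """Population-level predicted probabilities (random intercept 0)."""
        return special.expit(np.asarray(exog, dtype=float) @ self.params)


class BinomialRandomInterceptGLMM:
    """ML estimation of ``y ~ X + (1 | group)`` with binomial errors."""

    def __init__(self, endog, exog, groups, exog_names=None,
                 n_quad: int = 21):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        codes, _ = pd.factorize(np.asarray(groups), sort=True)
        order = np.argsort(codes, kind="stable")
        self.y, self.X, self.codes = y[order], X[order], codes[order]
        self.starts = np.flatnonzero(
            np.diff(self.codes, prepend=self.codes[0] - 1))
        self.n_groups = len(self.starts)
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{j}" for j in range(X.shape[1])])
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
        self.nodes = nodes * np.sqrt(2.0)
        self.logw = np.log(weights) - 0.5 * np.log(np.pi)

    def loglike(self, params: np.ndarray) -> float:
        beta, log_sigma = params[:-1], params[-1]
        sigma = np.exp(log_sigma)
        logit = self.X @ beta
        ll_obs = _bernoulli_loglik(
            logit[:, None] + sigma * self.nodes[None, :], self.y)
        group_ll = np.add.reduceat(ll_obs, self.starts, axis=0)
        return float(special.logsumexp(group_ll + self.logw[None, :],
                                       axis=1).sum())

    def fit(self, start_params=None, maxiter: int = 200
            ) -> BinomialGLMMResult:
        p = self.X.shape[1]
        if start_params is None:
            # ordinary logistic regression start
            import statsmodels.api as sm
            try:
                beta0 = sm.GLM(self.y, self.X,
                               family=sm.families.Binomial()).fit().params
            except Exception:
                beta0 = np.zeros(p)
            start_params = np.append(beta0, np.log(0.5))
        res = optimize.minimize(
            lambda th: -self.loglike(th), start_params, method="L-BFGS-B",
            bounds=[(None, None)] * p + [(-8.0, 3.0)],
            options={"maxiter": maxiter})
        theta = res.x
        hess = _numeric_hessian(lambda th: -self.loglike(th), theta)
        try:
            cov = np.linalg.inv(hess)
            ok = np.all(np.diag(cov)[:p] > 0)
        except np.linalg.LinAlgError:
            cov, ok = np.linalg.pinv(hess), False
        bse = np.sqrt(np.abs(np.diag(cov)[:p]))
        llf = -res.fun
        k = p + 1
        return BinomialGLMMResult(
            exog_names=self.exog_names, params=theta[:p], bse=bse,
            sigma_u=float(np.exp(theta[-1])), llf=llf,
            aic=2 * k - 2 * llf, nobs=self.y.size,
            n_groups=self.n_groups, converged=bool(res.success and ok),
            cov_params=cov)


def _numeric_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    h = eps * np.maximum(np.abs(x), 1.0)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            out[i, j] = out[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return out
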