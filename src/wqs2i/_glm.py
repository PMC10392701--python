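"""Generalized linear model helpers shared by the validation-step fits.

Unconstrained fits go through statsmodels; sign-bounded fits (used for
the joint two-index validation model) are solved by bound-constrained
maximum likelihood with standard errors from the observed information
at the solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.stats
import statsmodels.api as sm
from scipy.special import expit

__all__ = ["GLMFit", "glm_fit", "model_aic", "check_full_rank"]


@dataclass
class GLMFit:
    """Coefficient table of a fitted (possibly sign-bounded) GLM."""

    names: list
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    llf: float
    nobs: int
    link: str
    k_params: int
    aic: float
    active_bounds: list = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])

    def table(self):
        import pandas as pd
        return pd.DataFrame({"coef": self.params, "se": self.bse,
                             "pvalue": self.pvalues}, index=self.names)


def model_aic(llf: float, n_coef: int, link: str) -> float:
    """AIC = -2 llf + 2 k, counting the residual-variance parameter
    under the identity link (k = n_coef + 1) and only the mean
    parameters under the logit link."""
    k = n_coef + (1 if link == "identity" else 0)
    return -2.0 * llf + 2.0 * k


def check_full_rank(X: np.ndarray, names) -> None:
    """Raise naming the dependent columns if ``X`` is rank deficient."""
    rank = np.linalg.matrix_rank(X)
    if rank >= X.shape[1]:
        return
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    tol = np.abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps
    bad = sorted(piv[rank:]) if np.abs(np.diag(R)[rank:]).max(initial=0) <= tol \
        else sorted(piv[np.abs(np.diag(R)) <= tol])
    bad_names = [names[i] for i in bad]
    raise ValueError(f"singular design: dependent columns {bad_names}")


def _gaussian_llf(rss: float, n: int) -> float:
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def glm_fit(y, X, names, link: str = "identity", bounds=None) -> GLMFit:
    """Fit a GLM of ``y`` on ``X`` (which must already include any
    intercept column).

    ``bounds`` is an optional list of (lo, hi) per coefficient; when
    given, the fit maximizes the (Gaussian or binomial) likelihood
    subject to the box constraints and reports Wald standard errors
    from the observed information at the solution, flagging
    coefficients sitting on an active bound.
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    names = list(names)
    check_full_rank(X, names)
    n, k = X.shape

    if bounds is None:
        if link == "identity":
            res = sm.OLS(y, X).fit()
            llf = float(res.llf)
        else:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            llf = float(res.llf)
        params = np.asarray(res.params, float)
        bse = np.asarray(res.bse, float)
        pvals = np.asarray(res.pvalues, float)
        return GLMFit(names, params, bse, pvals, llf, n, link, k,
                      model_aic(llf, k, link))

    # bound-constrained maximum likelihood
    if link == "identity":
        def obj(b):
            r = y - X @ b
            return r @ r, -2.0 * (X.T @ r)
    else:
        def obj(b):
            eta = X @ b
            loss = -2.0 * np.sum(y * eta - np.logaddexp(0.0, eta))
            return loss, -2.0 * (X.T @ (y - expit(eta)))

    b0 = np.linalg.lstsq(X, y if link == "identity" else (y - 0.5) * 4, rcond=None)[0]
    lo = np.array([-np.inf if b is None or b[0] is None else b[0] for b in bounds])
    hi = np.array([np.inf if b is None or b[1] is None else b[1] for b in bounds])
    b0 = np.clip(b0, lo, hi)
    res = scipy.optimize.minimize(obj, b0, jac=True, method="L-BFGS-B",
                                  bounds=list(zip(lo, hi)),
                                  options={"maxiter": 500, "ftol": 1e-12})
    beta = res.x
    if link == "identity":
        rss = float(np.sum((y - X @ beta) ** 2))
        llf = _gaussian_llf(rss, n)
        dof = max(n - k, 1)
        cov = rss / dof * np.linalg.pinv(X.T @ X)
        bse = np.sqrt(np.diag(cov))
        tstat = np.divide(beta, bse, out=np.zeros_like(beta), where=bse > 0)
        pvals = 2.0 * scipy.stats.t.sf(np.abs(tstat), dof)
    else:
        eta = X @ beta
        p = expit(eta)
        llf = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        W = np.clip(p * (1.0 - p), 1e-12, None)
        cov = np.linalg.pinv((X * W[:, None]).T @ X)
        bse = np.sqrt(np.diag(cov))
        z = np.divide(beta, bse, out=np.zeros_like(beta), where=bse > 0)
        pvals = 2.0 * scipy.stats.norm.sf(np.abs(z))
    atol = 1e-9
    active = [names[i] for i in range(k)
              if (np.isfinite(lo[i]) and abs(beta[i] - lo[i]) < atol)
              or (np.isfinite(hi[i]) and abs(beta[i] - hi[i]) < atol)]
    return GLMFit(names, beta, bse, pvals, llf, n, link, k,
                  model_aic(llf, k, link), active_bounds=active)
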