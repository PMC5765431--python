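"""Binomial mixed model with a single random intercept, Laplace likelihood.

Model: y_ij ~ Bernoulli(p_ij), logit(p_ij) = x_ij' beta + u_i with
u_i ~ N(0, sigma_u^2) per group.  The marginal likelihood integrates the
random intercepts out; with one scalar intercept per group the integral
factorises, and each factor is approximated by Laplace's method around the
group's posterior mode — the same approximation lme4's ``glmer`` uses by
default.  The mode is found by a per-group Newton iteration (vectorised
across groups), and (beta, log sigma_u) is optimised by BFGS on the Laplace
objective.  Wald intervals come from the numerical Hessian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_hess1

__all__ = ["BinomialGlmmFit", "fit_binomial_glmm"]


@dataclass
class BinomialGlmmFit:
    estimates: dict  # name -> (coef, ci_low, ci_high)
    sigma_u: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    separation: bool = False

    def coef(self, name: str) -> float:
        return self.estimates[name][0]

    def ci(self, name: str) -> tuple[float, float]:
        return self.estimates[name][1:]


def _laplace_loglik(theta, y, X, codes, k, newton_iter=50):
    beta = theta[:-1]
    sigma2 = np.exp(2.0 * theta[-1])
    eta_fix = X @ beta
    u = np.zeros(k)
    for _ in range(newton_iter):
        eta = eta_fix + u[codes]
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = np.bincount(codes, weights=y - p, minlength=k) - u / sigma2
        hess = np.bincount(codes, weights=p * (1.0 - p), minlength=k) + 1.0 / sigma2
        step = grad / hess
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta_fix + u[codes]
    # log f(y|u) evaluated stably
    ll_data = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = 1.0 / (1.0 + np.exp(-eta))
    H = np.bincount(codes, weights=p * (1.0 - p), minlength=k) + 1.0 / sigma2
    ll = ll_data - float(np.sum(u**2)) / (2.0 * sigma2) - 0.5 * float(
        np.sum(np.log(sigma2 * H))
    )
    return ll


def fit_binomial_glmm(
    y,
    X,
    groups,
    names: list[str] | None = None,
    start_log_sigma: float = -1.0,
) -> BinomialGlmmFit:
    """Fit the random-intercept binomial GLMM by maximising the Laplace
    marginal likelihood over (beta, log sigma_u)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, _ = pd.factorize(np.asarray(groups))
    k = int(codes.max()) + 1
    p = X.shape[1]
    names = names or [f"x{j}" for j in range(p)]

    # GLM start values
    from statsmodels.api import GLM, families

    beta0 = GLM(y, X, family=families.Binomial()).fit().params
    separation = bool(np.max(np.abs(X @ beta0)) > 30.0)

    def nll(theta):
        return -_laplace_loglik(theta, y, X, codes, k)

    theta0 = np.concatenate([beta0, [start_log_sigma]])
    res = minimize(nll, theta0, method="BFGS",
                   options={"gtol": 1e-6, "maxiter": 300})
    converged = bool(res.success)
    if not converged:
        # sigma_u on the boundary makes the objective flat in log sigma;
        # polish with a derivative-free pass and accept a stationary point
        res2 = minimize(nll, res.x, method="Nelder-Mead",
                        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if res2.fun <= res.fun:
            res = res2
        converged = bool(res.success or res2.success)
    theta = res.x
    hess = approx_hess1(theta, nll)
    se = np.full(p, np.nan)
    for block in (hess, hess[:p, :p]):
        try:
            cov = np.linalg.inv(block)
            d = np.diag(cov)[:p]
            if np.all(np.isfinite(d)) and np.all(d > 0):
                se = np.sqrt(d)
                break
        except np.linalg.LinAlgError:
            continue
    estimates = {
        nm: (float(b), float(b - 1.96 * s), float(b + 1.96 * s))
        for nm, b, s in zip(names, theta[:p], se)
    }
    separation = separation or bool(np.max(np.abs(theta[:p])) > 15.0)
    return BinomialGlmmFit(
        estimates=estimates,
        sigma_u=float(np.exp(theta[-1])),
        loglik=float(-res.fun),
        n_obs=len(y),
        n_groups=k,
        converged=converged,
        separation=separation,
    )
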