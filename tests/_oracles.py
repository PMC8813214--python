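"""Independent reference computations used by the tests.

Everything here is deliberately written against textbook parameterizations
(scipy.stats distributions, direct likelihood maximization, hand-expanded
partial likelihoods) and never calls the package's own fitting code paths.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats


def weibull_censored_mle(time: np.ndarray, status: np.ndarray) -> tuple[float, float, float]:
    """Direct (lambda, gamma) censored Weibull MLE; returns (lam, gam, loglik).

    Density lam*gam*t^(gam-1)*exp(-lam*t^gam), survival exp(-lam*t^gam).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(status) == 1

    def nll(par):
        lam, gam = np.exp(par)
        ll = np.sum(e * (np.log(lam) + np.log(gam) + (gam - 1) * np.log(t))) - np.sum(
            lam * t**gam
        )
        return -ll

    res = optimize.minimize(
        nll, [np.log(0.2), 0.0], method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 5000},
    )
    lam, gam = np.exp(res.x)
    return lam, gam, -res.fun


def loglogistic_censored_mle(time: np.ndarray, status: np.ndarray) -> tuple[float, float, float]:
    """Direct (alpha, beta) censored log-logistic MLE via scipy's fisk
    distribution; returns (alpha, beta, loglik)."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(status) == 1

    def nll(par):
        alpha, beta = np.exp(par)
        logpdf = stats.fisk.logpdf(t, c=beta, scale=alpha)
        logsf = stats.fisk.logsf(t, c=beta, scale=alpha)
        return -(np.sum(logpdf[e]) + np.sum(logsf[~e]))

    res = optimize.minimize(
        nll, [np.log(np.median(t)), 0.0], method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 5000},
    )
    alpha, beta = np.exp(res.x)
    return alpha, beta, -res.fun


def lognormal_censored_mle(time: np.ndarray, status: np.ndarray) -> tuple[float, float, float]:
    """Direct (mu, sigma) censored lognormal MLE; returns (mu, sigma, loglik)."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(status) == 1
    lt = np.log(t)

    def nll(par):
        mu, log_sigma = par
        sigma = np.exp(log_sigma)
        z = (lt - mu) / sigma
        logpdf = stats.norm.logpdf(z) - np.log(sigma) - lt
        logsf = stats.norm.logsf(z)
        return -(np.sum(logpdf[e]) + np.sum(logsf[~e]))

    res = optimize.minimize(
        nll, [lt.mean(), np.log(max(lt.std(), 1e-3))], method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 5000},
    )
    return res.x[0], np.exp(res.x[1]), -res.fun


def breslow_free_partial_loglik(
    time: np.ndarray, status: np.ndarray, x: np.ndarray, beta: float
) -> float:
    """Hand-expanded untied Cox partial log-likelihood for one covariate."""
    order = np.argsort(time)
    t, s, xv = time[order], status[order], x[order]
    total = 0.0
    for i in range(len(t)):
        if s[i] != 1:
            continue
        risk = xv[t >= t[i]]
        total += beta * xv[i] - np.log(np.sum(np.exp(beta * risk)))
    return total


def efron_partial_loglik(
    time: np.ndarray, status: np.ndarray, X: np.ndarray, beta: np.ndarray
) -> float:
    """Efron-corrected partial log-likelihood, written from the definition."""
    xb = X @ beta
    risk = np.exp(xb)
    total = 0.0
    for et in np.unique(time[status == 1]):
        tied = (time == et) & (status == 1)
        d = int(tied.sum())
        r_sum = risk[time >= et].sum()
        t_sum = risk[tied].sum()
        total += xb[tied].sum()
        for l in range(d):
            total -= np.log(r_sum - (l / d) * t_sum)
    return total


def efron_cox_mle(time: np.ndarray, status: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximize the Efron partial likelihood directly with scipy."""
    p = X.shape[1]

    def nll(beta):
        return -efron_partial_loglik(time, status, X, beta)

    res = optimize.minimize(
        nll, np.zeros(p), method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 20000},
    )
    # polish: quasi-Newton from the simplex solution for tight coefficients
    res = optimize.minimize(nll, res.x, method="BFGS", options={"gtol": 1e-11})
    return res.x, -res.fun
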