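"""Modelling scales for the flexible parametric survival model.

Each scale is an invertible link between the linear predictor
``eta = s(ln t) + x beta`` and the survival function:

* ``hazard``: eta is the log cumulative hazard, ``S = exp(-exp(eta))``;
  with a linear spline this is the Weibull model.
* ``odds``: eta is the log cumulative odds of failure,
  ``S = 1 / (1 + exp(eta))``; linear spline gives the log-logistic model.
* ``normal``: eta is the probit of failure, ``S = Phi(-eta)``; linear spline
  gives the lognormal model.

Per-subject log-likelihood contributions are ``log S(t)`` for censored rows
and ``log f(t) = log(-dS/d eta) + log(d eta/d ln t) - ln t`` for events, so
the event term requires the spline derivative with respect to log time.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtri_exp

__all__ = [
    "HAZARD",
    "ODDS",
    "NORMAL",
    "SCALES",
    "log_survival_from_eta",
    "survival_from_eta",
    "eta_from_log_survival",
    "eta_from_survival",
    "cumulative_hazard_from_eta",
    "log_likelihood_contributions",
    "improper_event_mask",
]

HAZARD = "hazard"
ODDS = "odds"
NORMAL = "normal"
SCALES = (HAZARD, ODDS, NORMAL)

# linear predictors beyond this are clamped before exponentiation; exp(700)
# is still finite in float64, so likelihoods stay finite for |eta| <= 700
_ETA_CLAMP = 700.0
# floor for d eta / d ln t in event terms; below it the likelihood is improper
_DERIV_FLOOR = 1e-12
# slope of the linear penalty pushing the optimizer back to d eta/d ln t > 0
_PENALTY_SLOPE = 1e4

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


def _check_scale(scale: str) -> None:
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")


def _softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x), stable for large |x|
    return np.logaddexp(0.0, x)


def log_survival_from_eta(eta: np.ndarray, scale: str) -> np.ndarray:
    """``log S`` as a function of the linear predictor, overflow-safe."""
    _check_scale(scale)
    eta = np.clip(np.asarray(eta, dtype=float), -_ETA_CLAMP, _ETA_CLAMP)
    if scale == HAZARD:
        return -np.exp(eta)
    if scale == ODDS:
        return -_softplus(eta)
    return log_ndtr(-eta)


def survival_from_eta(eta: np.ndarray, scale: str) -> np.ndarray:
    """Survival probability ``S(eta)``, strictly decreasing in eta."""
    return np.exp(log_survival_from_eta(eta, scale))


def eta_from_log_survival(log_s: np.ndarray, scale: str) -> np.ndarray:
    """Inverse link: recover eta from ``log S``."""
    _check_scale(scale)
    log_s = np.asarray(log_s, dtype=float)
    if scale == HAZARD:
        return np.log(-log_s)
    if scale == ODDS:
        # eta = log(1 - S) - log S with 1 - S computed as -expm1(log S)
        return np.log(-np.expm1(log_s)) - log_s
    return -ndtri_exp(log_s)


def eta_from_survival(s: np.ndarray, scale: str) -> np.ndarray:
    return eta_from_log_survival(np.log(np.asarray(s, dtype=float)), scale)


def cumulative_hazard_from_eta(eta: np.ndarray, scale: str) -> np.ndarray:
    """``H = -log S``; on the hazard scale this is just ``exp(eta)``."""
    return -log_survival_from_eta(eta, scale)


def _event_density_terms(eta: np.ndarray, scale: str) -> tuple[np.ndarray, np.ndarray]:
    """``log(-dS/d eta)`` and its derivative with respect to eta."""
    if scale == HAZARD:
        # -dS/deta = exp(eta - exp(eta))
        value = eta - np.exp(eta)
        grad = 1.0 - np.exp(eta)
    elif scale == ODDS:
        # -dS/deta = e^eta / (1 + e^eta)^2
        value = eta - 2.0 * _softplus(eta)
        grad = 1.0 - 2.0 / (1.0 + np.exp(-eta))
    else:
        # -dS/deta = phi(eta)
        value = -0.5 * eta**2 - _HALF_LOG_2PI
        grad = -eta
    return value, grad


def _censor_terms(eta: np.ndarray, scale: str) -> tuple[np.ndarray, np.ndarray]:
    """``log S`` and its derivative with respect to eta."""
    value = log_survival_from_eta(eta, scale)
    if scale == HAZARD:
        grad = -np.exp(np.clip(eta, -_ETA_CLAMP, _ETA_CLAMP))
    elif scale == ODDS:
        grad = -1.0 / (1.0 + np.exp(-eta))
    else:
        # d log Phi(-eta) / d eta = -phi(eta) / Phi(-eta)
        log_phi = -0.5 * eta**2 - _HALF_LOG_2PI
        grad = -np.exp(log_phi - log_ndtr(-eta))
    return value, grad


def improper_event_mask(deta_dlogt: np.ndarray, status: np.ndarray) -> np.ndarray:
    """Events where the fitted predictor decreases in log time.

    At such points the implied density is negative and the likelihood is
    improper; fitting replaces the contribution with a steep penalty.
    """
    return (np.asarray(status) == 1) & (np.asarray(deta_dlogt) <= _DERIV_FLOOR)


def log_likelihood_contributions(
    eta: np.ndarray,
    deta_dlogt: np.ndarray,
    log_t: np.ndarray,
    status: np.ndarray,
    scale: str,
) -> np.ndarray:
    """Per-subject log-likelihood contributions.

    Censored subjects contribute ``log S``; events contribute the log density.
    Event rows with ``d eta / d ln t <= 0`` are penalized (see
    :func:`improper_event_mask`) rather than producing NaN, so optimizers are
    steered back into the proper region.
    """
    _check_scale(scale)
    eta = np.clip(np.atleast_1d(np.asarray(eta, dtype=float)), -_ETA_CLAMP, _ETA_CLAMP)
    ds = np.atleast_1d(np.asarray(deta_dlogt, dtype=float))
    log_t = np.atleast_1d(np.asarray(log_t, dtype=float))
    event = np.atleast_1d(np.asarray(status)) == 1

    out = np.empty_like(eta)
    cens_val, _ = _censor_terms(eta[~event], scale)
    out[~event] = cens_val
    ev_val, _ = _event_density_terms(eta[event], scale)
    ds_ev = ds[event]
    ds_safe = np.maximum(ds_ev, _DERIV_FLOOR)
    penalty = _PENALTY_SLOPE * np.minimum(ds_ev - _DERIV_FLOOR, 0.0)
    out[event] = ev_val + np.log(ds_safe) - log_t[event] + penalty
    return out


def _loglik_value_and_eta_grads(
    eta: np.ndarray,
    deta_dlogt: np.ndarray,
    log_t: np.ndarray,
    event: np.ndarray,
    scale: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Total log-likelihood plus per-row gradients for the fitting routine.

    Returns ``(total, d/d eta, d/d (d eta/d ln t))`` with the derivative
    gradient zero on censored rows.
    """
    eta = np.clip(eta, -_ETA_CLAMP, _ETA_CLAMP)
    n = eta.shape[0]
    val = np.empty(n)
    g_eta = np.empty(n)
    g_ds = np.zeros(n)

    cens_val, cens_grad = _censor_terms(eta[~event], scale)
    val[~event] = cens_val
    g_eta[~event] = cens_grad

    ev_val, ev_grad = _event_density_terms(eta[event], scale)
    ds_ev = deta_dlogt[event]
    ds_safe = np.maximum(ds_ev, _DERIV_FLOOR)
    below = ds_ev < _DERIV_FLOOR
    val[event] = (
        ev_val
        + np.log(ds_safe)
        - log_t[event]
        + _PENALTY_SLOPE * np.minimum(ds_ev - _DERIV_FLOOR, 0.0)
    )
    g_eta[event] = ev_grad
    g_ds[event] = np.where(below, _PENALTY_SLOPE, 1.0 / ds_safe)
    return float(val.sum()), g_eta, g_ds
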