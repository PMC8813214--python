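"""Partial least squares latent components and their composition with the
survival stages.

With p collinear covariates (possibly p >= n) a direct multivariate survival
fit is ill-posed.  PLS extracts C <= min(p, n-1) orthogonal latent components
that maximize covariance with a working response — here the log observed
follow-up time — and the survival model is then fitted on the n x C score
matrix.  Component-level coefficients are mapped back to per-covariate
coefficients (on the standardized covariate scale) through the PLS rotation
``R = W (P' W)^{-1}``, so that ``scores @ b_components = X_std @ b_covariates``
exactly.

The same decomposition feeds both the flexible parametric (spline) stage and
the Cox benchmark stage, so model comparisons isolate the survival stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .cox import CoxFit, fit_cox
from .data import SurvivalData
from .rp import RPFit, fit_rp

__all__ = [
    "PLSDecomposition",
    "CompositeFit",
    "extract_components",
    "project",
    "back_project",
    "fit_pls_spline",
    "fit_pls_cox",
]

_RANK_TOL = 1e-10


@dataclass
class PLSDecomposition:
    """Weights, loadings and scores of a univariate-response PLS fit.

    ``scores = X_standardized @ rotations`` with
    ``rotations = weights @ inv(loadings.T @ weights)``; the stored center and
    scale are the training means and standard deviations, so held-out rows can
    be projected with :func:`project`.
    """

    weights: np.ndarray       # p x C
    loadings: np.ndarray      # p x C
    scores: np.ndarray        # n x C
    center: np.ndarray        # length p
    scale_factors: np.ndarray # length p
    y_loadings: np.ndarray    # length C

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def rotations(self) -> np.ndarray:
        return self.weights @ np.linalg.inv(self.loadings.T @ self.weights)


@dataclass
class CompositeFit:
    """A PLS decomposition composed with a survival-stage fit.

    ``covariate_coefficients`` are the component coefficients back-projected
    to the original covariates, on the standardized covariate scale.
    """

    decomposition: PLSDecomposition
    survival_stage: Union[RPFit, CoxFit]
    covariate_coefficients: np.ndarray
    covariate_names: list[str]


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(scale == 0)
    if zero.size:
        raise ValueError(
            f"covariate column(s) {zero.tolist()} have zero variance; "
            "remove them before PLS extraction"
        )
    return (X - center) / scale, center, scale


def extract_components(X: np.ndarray, response: np.ndarray, C: int) -> PLSDecomposition:
    """Univariate-response NIPALS with X deflation.

    Covariates are standardized to training mean 0 and unit variance first.
    Each weight vector is sign-fixed so its largest-magnitude entry is
    positive, making decompositions reproducible across runs and platforms.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("response length must match the number of rows of X")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    if not 1 <= C <= min(p, n - 1):
        raise ValueError(f"C must satisfy 1 <= C <= min(p, n-1) = {min(p, n - 1)}")

    Xs, center, scale = _standardize(X)
    ys = y - y.mean()
    sd = ys.std(ddof=1)
    if sd > 0:
        ys = ys / sd

    Xc = Xs.copy()
    W = np.empty((p, C))
    P = np.empty((p, C))
    T = np.empty((n, C))
    q = np.empty(C)
    x_norm0 = np.linalg.norm(Xs)
    for c in range(C):
        w = Xc.T @ ys
        wn = np.linalg.norm(w)
        if wn == 0 or np.linalg.norm(Xc) < _RANK_TOL * max(x_norm0, 1.0):
            raise ValueError(
                f"C={C} exceeds the effective rank of X (failed at component {c + 1})"
            )
        w = w / wn
        # deterministic sign: largest-magnitude weight entry positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        t = Xc @ w
        tt = float(t @ t)
        if tt < _RANK_TOL:
            raise ValueError(
                f"C={C} exceeds the effective rank of X (degenerate score {c + 1})"
            )
        pvec = Xc.T @ t / tt
        q[c] = float(ys @ t / tt)
        Xc = Xc - np.outer(t, pvec)
        W[:, c], P[:, c], T[:, c] = w, pvec, t
    return PLSDecomposition(
        weights=W, loadings=P, scores=T, center=center, scale_factors=scale, y_loadings=q
    )


def project(decomposition: PLSDecomposition, X_new: np.ndarray) -> np.ndarray:
    """Score new rows with the stored centering, scaling and rotation."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != decomposition.p:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns; decomposition expects {decomposition.p}"
        )
    Xs = (X_new - decomposition.center) / decomposition.scale_factors
    return Xs @ decomposition.rotations


def back_project(decomposition: PLSDecomposition, component_coefficients: np.ndarray) -> np.ndarray:
    """Map component-level coefficients to standardized-covariate coefficients."""
    b = np.asarray(component_coefficients, dtype=float)
    if b.shape[0] != decomposition.n_components:
        raise ValueError("component coefficient length must equal n_components")
    return decomposition.rotations @ b


def _component_data(data: SurvivalData, decomposition: PLSDecomposition) -> SurvivalData:
    C = decomposition.n_components
    return SurvivalData(
        time=data.time,
        status=data.status,
        covariates=decomposition.scores,
        covariate_names=[f"comp{c + 1}" for c in range(C)],
    )


def _extract_for_survival(data: SurvivalData, C: int) -> PLSDecomposition:
    # working response: log observed follow-up time (censoring ignored at the
    # extraction stage; the survival stage handles it)
    return extract_components(data.covariates, np.log(data.time), C)


def fit_pls_spline(
    data: SurvivalData, C: int, scale: str, n_internal_knots: int = 0,
    decomposition: PLSDecomposition | None = None,
) -> CompositeFit:
    """PLS extraction followed by a flexible parametric fit on the scores.

    A precomputed ``decomposition`` may be supplied (e.g. to share one
    extraction across several survival-stage variants).
    """
    try:
        dec = decomposition if decomposition is not None else _extract_for_survival(data, C)
    except ValueError as err:
        raise ValueError(f"PLS stage: {err}") from err
    try:
        stage = fit_rp(_component_data(data, dec), scale, n_internal_knots)
    except ValueError as err:
        raise ValueError(f"survival stage: {err}") from err
    comp_beta = stage.beta
    return CompositeFit(
        decomposition=dec,
        survival_stage=stage,
        covariate_coefficients=back_project(dec, comp_beta),
        covariate_names=list(data.covariate_names),
    )


def fit_pls_cox(
    data: SurvivalData, C: int, decomposition: PLSDecomposition | None = None,
) -> CompositeFit:
    """PLS extraction followed by a Cox fit on the scores (the benchmark).

    The extraction stage is identical to :func:`fit_pls_spline`, so spline
    and Cox composites built on the same data and C share one decomposition.
    """
    try:
        dec = decomposition if decomposition is not None else _extract_for_survival(data, C)
    except ValueError as err:
        raise ValueError(f"PLS stage: {err}") from err
    try:
        stage = fit_cox(_component_data(data, dec))
    except ValueError as err:
        raise ValueError(f"survival stage: {err}") from err
    return CompositeFit(
        decomposition=dec,
        survival_stage=stage,
        covariate_coefficients=back_project(dec, stage.beta),
        covariate_names=list(data.covariate_names),
    )
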