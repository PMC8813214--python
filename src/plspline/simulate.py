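"""Survival data simulator: correlated Gaussian covariates, Weibull event
times under proportional hazards, and administrative censoring.

The default configuration emulates a high-multicollinearity surveillance
setting: n = 100 subjects, p = 200 covariates whose pairwise correlations span
0 to 0.9, event times Weibull with scale 0.1 and shape 1.5, and administrative
censoring at 5 time units.  Covariates are drawn from a block-structured
multivariate normal — within each block the target correlation is first-order
autoregressive at a level spaced over [0, corr_max], which keeps the target
matrix positive definite for any corr_max < 1 while realizing the full
correlation range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .data import SurvivalData

__all__ = [
    "SimulationSpec",
    "correlation_matrix",
    "simulate_covariates",
    "simulate_times",
    "simulate_dataset",
    "split_train_test",
]


def _default_beta(p: int) -> np.ndarray:
    """Sparse default effects: the first min(10, p) covariates at 0.2."""
    beta = np.zeros(p)
    beta[: min(10, p)] = 0.2
    return beta


@dataclass
class SimulationSpec:
    """Configuration of one simulated survival dataset.

    ``weibull_scale`` (lambda) and ``weibull_shape`` (gamma) parameterize the
    baseline cumulative hazard ``H0(t) = lambda * t**gamma``; subjects with
    linear predictor ``x beta`` have hazard multiplied by ``exp(x beta)``.
    Anyone event-free at ``censor_horizon`` is censored there (Type I).
    """

    n: int = 100
    p: int = 200
    corr_max: float = 0.9
    weibull_scale: float = 0.1
    weibull_shape: float = 1.5
    censor_horizon: float = 5.0
    true_beta: np.ndarray | None = None
    seed: int = 0
    n_blocks: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if not 0.0 <= self.corr_max < 1.0:
            raise ValueError("corr_max must lie in [0, 1)")
        if self.weibull_scale <= 0 or self.weibull_shape <= 0:
            raise ValueError("Weibull scale and shape must be positive")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be positive")
        if self.true_beta is None:
            self.true_beta = _default_beta(self.p)
        self.true_beta = np.asarray(self.true_beta, dtype=float)
        if self.true_beta.shape[0] != self.p:
            raise ValueError("true_beta must have length p")
        if self.n_blocks is None:
            self.n_blocks = min(10, self.p)
        if not 1 <= self.n_blocks <= self.p:
            raise ValueError("n_blocks must lie in [1, p]")

    def to_yaml(self, path) -> None:
        doc = {
            "n": self.n,
            "p": self.p,
            "corr_max": self.corr_max,
            "weibull_scale": self.weibull_scale,
            "weibull_shape": self.weibull_shape,
            "censor_horizon": self.censor_horizon,
            "true_beta": self.true_beta.tolist(),
            "seed": self.seed,
            "n_blocks": self.n_blocks,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "SimulationSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "true_beta" in doc and doc["true_beta"] is not None:
            doc["true_beta"] = np.asarray(doc["true_beta"], dtype=float)
        return cls(**doc)


def _block_sizes(p: int, n_blocks: int) -> list[int]:
    base, extra = divmod(p, n_blocks)
    return [base + (1 if b < extra else 0) for b in range(n_blocks)]


def correlation_matrix(spec: SimulationSpec) -> np.ndarray:
    """Block-diagonal target correlation with AR(1) blocks at levels spaced
    over [0, corr_max]."""
    rhos = (
        np.linspace(0.0, spec.corr_max, spec.n_blocks)
        if spec.n_blocks > 1
        else np.array([spec.corr_max])
    )
    sigma = np.zeros((spec.p, spec.p))
    start = 0
    for size, rho in zip(_block_sizes(spec.p, spec.n_blocks), rhos):
        idx = np.arange(size)
        sigma[start : start + size, start : start + size] = rho ** np.abs(
            idx[:, None] - idx[None, :]
        )
        start += size
    return sigma


def simulate_covariates(spec: SimulationSpec) -> np.ndarray:
    """Draw the n x p covariate matrix; deterministic given ``spec.seed``."""
    rng = np.random.default_rng((spec.seed, 0))
    z = rng.standard_normal((spec.n, spec.p))
    rhos = (
        np.linspace(0.0, spec.corr_max, spec.n_blocks)
        if spec.n_blocks > 1
        else np.array([spec.corr_max])
    )
    X = np.empty_like(z)
    start = 0
    for size, rho in zip(_block_sizes(spec.p, spec.n_blocks), rhos):
        idx = np.arange(size)
        block = rho ** np.abs(idx[:, None] - idx[None, :])
        try:
            L = np.linalg.cholesky(block)
        except np.linalg.LinAlgError as err:  # unreachable for AR blocks
            raise ValueError("target correlation block is not positive definite") from err
        X[:, start : start + size] = z[:, start : start + size] @ L.T
        start += size
    return X


def simulate_times(X: np.ndarray, spec: SimulationSpec) -> SurvivalData:
    """Inverse-transform Weibull event times under proportional hazards.

    ``T = (-ln U / (lambda * exp(x beta)))**(1/gamma)`` with U ~ Uniform(0,1);
    the observed time is ``min(T, horizon)`` and status marks events that
    precede the horizon.  Deterministic given ``spec.seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != spec.n:
        raise ValueError(f"X has {X.shape[0]} rows; spec.n is {spec.n}")
    rng = np.random.default_rng((spec.seed, 1))
    u = rng.uniform(size=spec.n)
    xb = X @ spec.true_beta if X.shape[1] == spec.p else np.zeros(spec.n)
    latent = (-np.log(u) / (spec.weibull_scale * np.exp(xb))) ** (1.0 / spec.weibull_shape)
    status = (latent < spec.censor_horizon).astype(int)
    time = np.minimum(latent, spec.censor_horizon)
    return SurvivalData(time=time, status=status, covariates=X)


def simulate_dataset(spec: SimulationSpec) -> SurvivalData:
    """Covariates and times in one call."""
    return simulate_times(simulate_covariates(spec), spec)


def split_train_test(
    data: SurvivalData, train_fraction: float, seed: int
) -> tuple[SurvivalData, SurvivalData]:
    """Uniform random partition into ceil(n * fraction) training rows and the
    remainder; deterministic given ``seed``."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n)
    n_train = math.ceil(data.n * train_fraction)
    train = data.subset(np.sort(perm[:n_train]))
    test = data.subset(np.sort(perm[n_train:]))
    if train.n_events < 2:
        raise ValueError(
            "training partition has fewer than 2 events; use a different seed"
        )
    return train, test
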