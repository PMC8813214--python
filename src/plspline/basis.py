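"""Restricted (natural) cubic spline basis in log time.

The spline ``s(x) = eta_0 + eta_1 x + sum_j eta_{j+1} v_j(x)`` is evaluated at
``x = ln t``.  Boundary knots sit at the extremes of the uncensored log event
times; each internal knot ``k_j`` contributes one derived variable

    v_j(x) = (x - k_j)_+^3 - lam_j (x - k_min)_+^3 - (1 - lam_j) (x - k_max)_+^3

with ``lam_j = (k_max - k_j) / (k_max - k_min)``.  The two correction terms
cancel the quadratic and cubic growth beyond the boundary knots, so the spline
is exactly linear outside ``[k_min, k_max]`` — which is what licenses
extrapolating fitted cumulative hazards beyond the observed follow-up.  With no
internal knots the basis is the single column ``x`` and the spline collapses to
a straight line in log time (the Weibull / log-logistic / lognormal case,
depending on the modelling scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KnotVector",
    "SplineBasis",
    "place_knots",
    "evaluate_basis",
    "evaluate_basis_derivative",
]


@dataclass(frozen=True)
class KnotVector:
    """Boundary and internal knot locations on the log-time axis."""

    boundary_low: float
    boundary_high: float
    internal: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "internal", tuple(float(k) for k in self.internal))
        if not self.boundary_low < self.boundary_high:
            raise ValueError("boundary_low must be strictly below boundary_high")
        if any(not self.boundary_low < k < self.boundary_high for k in self.internal):
            raise ValueError("internal knots must lie strictly between the boundaries")
        if any(a >= b for a, b in zip(self.internal, self.internal[1:])):
            raise ValueError("internal knots must be strictly increasing")

    @property
    def all_knots(self) -> np.ndarray:
        return np.array((self.boundary_low, *self.internal, self.boundary_high))


@dataclass(frozen=True)
class SplineBasis:
    """A knot vector together with its derived-variable count.

    ``n_basis`` excludes the intercept: one linear term in log time plus one
    derived variable per internal knot.
    """

    knots: KnotVector

    @property
    def n_basis(self) -> int:
        return 1 + len(self.knots.internal)


def place_knots(log_event_times: np.ndarray, n_internal: int) -> KnotVector:
    """Place boundary and internal knots from uncensored log event times.

    Boundary knots go at the min and max; ``n_internal`` internal knots go at
    equally spaced centiles (a single knot sits at the median).  Censored
    observations must not be passed in.
    """
    x = np.asarray(log_event_times, dtype=float)
    if x.size == 0:
        raise ValueError("no uncensored event times supplied")
    if n_internal < 0:
        raise ValueError("n_internal must be >= 0")
    distinct = np.unique(x)
    if distinct.size < 2:
        raise ValueError(
            "need at least 2 distinct uncensored log event times to place knots"
        )
    lo, hi = float(distinct[0]), float(distinct[-1])
    if n_internal == 0:
        return KnotVector(lo, hi)
    q = np.arange(1, n_internal + 1) / (n_internal + 1)
    internal = np.quantile(x, q)
    knots = np.concatenate(([lo], internal, [hi]))
    if np.unique(knots).size != knots.size:
        raise ValueError(
            "centile-based knot placement produced duplicate knots; "
            "reduce n_internal or supply less granular data"
        )
    return KnotVector(lo, hi, tuple(internal))


def _plus(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def evaluate_basis(log_t: np.ndarray, basis: SplineBasis) -> np.ndarray:
    """Evaluate the spline's derived variables (no intercept column).

    Returns an ``(len(log_t), n_basis)`` matrix: column 0 is ``log_t`` itself,
    column ``j+1`` is the derived variable ``v_j`` for internal knot ``j``.
    Values beyond the boundary knots continue the linear tails.
    """
    x = np.atleast_1d(np.asarray(log_t, dtype=float))
    cols = [x]
    kv = basis.knots
    kmin, kmax = kv.boundary_low, kv.boundary_high
    for kj in kv.internal:
        lam = (kmax - kj) / (kmax - kmin)
        cols.append(
            _plus(x - kj) ** 3
            - lam * _plus(x - kmin) ** 3
            - (1.0 - lam) * _plus(x - kmax) ** 3
        )
    return np.column_stack(cols)


def evaluate_basis_derivative(log_t: np.ndarray, basis: SplineBasis) -> np.ndarray:
    """Analytic derivative of each basis column with respect to log time."""
    x = np.atleast_1d(np.asarray(log_t, dtype=float))
    cols = [np.ones_like(x)]
    kv = basis.knots
    kmin, kmax = kv.boundary_low, kv.boundary_high
    for kj in kv.internal:
        lam = (kmax - kj) / (kmax - kmin)
        cols.append(
            3.0 * _plus(x - kj) ** 2
            - 3.0 * lam * _plus(x - kmin) ** 2
            - 3.0 * (1.0 - lam) * _plus(x - kmax) ** 2
        )
    return np.column_stack(cols)
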