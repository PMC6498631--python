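"""Cubic B-spline machinery for the time-varying causal-effect curve λ(t).

λ(t) is the coefficient by which the entry-day weight contributes to the weight
t days later,

    λ(t) = Σ_j P_j S_j(t),    j = 0..N_p-1,

with S_j cubic B-spline basis functions on a clamped knot vector spanning
[0, 5 T_L / 4], where T_L is the last measurement day in the data.  The default
N_p = 8 gives 12 knots: four repeated at 0, interior knots at T_L/4, T_L/2,
3T_L/4 and T_L, and four repeated at 5T_L/4.

The spline weights carry a second-order random-walk prior,

    P_0, P_1 ~ N(0, 1000 σ²_p),    P_j ~ N(2 P_{j-1} - P_{j-2}, σ²_p)  (j ≥ 2),

which shrinks λ toward a straight line while leaving level and slope vague.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "KnotVector",
    "CausalCurve",
    "build_knots",
    "bspline_basis",
    "basis_matrix",
    "lambda_eval",
    "curve_prior_logdensity",
    "decline_extinction_time",
]

DEGREE = 3
BOUNDARY_VARIANCE_FACTOR = 1000.0


@dataclass(frozen=True)
class KnotVector:
    """Clamped knot sequence for a cubic basis with ``n_basis`` functions."""

    knots: np.ndarray
    degree: int = DEGREE

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        object.__setattr__(self, "knots", k)
        d = self.degree
        if len(k) < 2 * (d + 1):
            raise ValueError("knot vector too short")
        if np.any(np.diff(k) < 0):
            raise ValueError("knots must be nondecreasing")
        if not (np.all(k[: d + 1] == k[0]) and np.all(k[-(d + 1):] == k[-1])):
            raise ValueError("first/last degree+1 knots must repeat (clamped)")
        interior = k[d + 1 : -(d + 1)]
        if interior.size and not np.all((interior > k[0]) & (interior < k[-1])):
            raise ValueError("interior knots must lie strictly inside the span")

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    @property
    def domain(self) -> tuple[float, float]:
        """Half-open evaluation interval [t0, t_end)."""
        return float(self.knots[0]), float(self.knots[-1])


def build_knots(T_L: float, n_basis: int = 8) -> KnotVector:
    """Knot vector spanning [0, 5 T_L/4] with equally spaced interior knots.

    ``n_basis = 8`` yields 12 knots with interior knots at T_L/4, T_L/2,
    3T_L/4 and T_L.
    """
    if T_L <= 0:
        raise ValueError("T_L must be positive")
    if n_basis < DEGREE + 1:
        raise ValueError(f"n_basis must be at least {DEGREE + 1}")
    end = 5.0 * T_L / 4.0
    n_interior = n_basis - DEGREE - 1
    interior = np.linspace(0.0, end, n_interior + 2)[1:-1]
    knots = np.concatenate([np.zeros(DEGREE + 1), interior, np.full(DEGREE + 1, end)])
    return KnotVector(knots)


def _check_domain(t: np.ndarray, kv: KnotVector) -> None:
    lo, hi = kv.domain
    t = np.asarray(t, dtype=float)
    if np.any(t < lo) or np.any(t >= hi):
        bad = t[(t < lo) | (t >= hi)]
        raise ValueError(
            f"time {bad.flat[0]!r} outside the curve domain [{lo}, {hi})"
        )


def basis_matrix(t, kv: KnotVector) -> np.ndarray:
    """Dense (len(t), n_basis) matrix of basis values S_j(t)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    _check_domain(t, kv)
    m = BSpline.design_matrix(t, kv.knots, kv.degree, extrapolate=False)
    return np.asarray(m.todense())


def bspline_basis(t: float, kv: KnotVector) -> np.ndarray:
    """Basis values (S_0(t), ..., S_{N_p-1}(t)); partition of unity on the domain."""
    return basis_matrix([t], kv)[0]


@dataclass
class CausalCurve:
    """λ(t) = Σ P_j S_j(t): knots, N_p spline weights and their prior variance σ²_p."""

    knots: KnotVector
    weights: np.ndarray
    weight_variance: float = 1.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.knots.n_basis,):
            raise ValueError(
                f"expected {self.knots.n_basis} weights, got {self.weights.shape}"
            )

    def __call__(self, t):
        out = basis_matrix(t, self.knots) @ self.weights
        return float(out[0]) if np.isscalar(t) else out


def lambda_eval(t, curve: CausalCurve):
    """Evaluate the causal-effect curve at time(s) t (days)."""
    return curve(t)


def second_differences(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    return w[2:] - 2.0 * w[1:-1] + w[:-2]


def curve_prior_logdensity(curve: CausalCurve) -> float:
    """Log-density of the spline weights under the random-walk prior."""
    s2 = float(curve.weight_variance)
    if s2 <= 0:
        raise ValueError("weight variance must be positive")
    w = curve.weights
    v0 = BOUNDARY_VARIANCE_FACTOR * s2
    lp = -0.5 * (np.log(2 * np.pi * v0) + w[0] ** 2 / v0)
    lp += -0.5 * (np.log(2 * np.pi * v0) + w[1] ** 2 / v0)
    d2 = second_differences(w)
    lp += float(np.sum(-0.5 * (np.log(2 * np.pi * s2) + d2**2 / s2)))
    return float(lp)


def decline_extinction_time(t: np.ndarray, lam: np.ndarray) -> float:
    """Day at which a plateau-then-decline effect curve disappears.

    Fits a straight line to the declining flank (between 70% and 20% of the
    curve's maximum, past the maximum) and returns its zero crossing — the
    natural reading of "declined linearly until it disappeared" that is
    robust to small level offsets near zero.
    """
    t = np.asarray(t, dtype=float)
    lam = np.asarray(lam, dtype=float)
    m = lam.max()
    if m <= 0:
        raise ValueError("curve has no positive part; extinction undefined")
    start = int(np.argmax(lam))
    seg = (np.arange(t.size) > start) & (lam >= 0.2 * m) & (lam <= 0.7 * m)
    if seg.sum() < 2:
        raise ValueError("no declining flank found between 20% and 70% of max")
    slope, intercept = np.polyfit(t[seg], lam[seg], 1)
    if slope >= 0:
        raise ValueError("flank is not declining")
    return float(-intercept / slope)


def curve_grid(curve: CausalCurve, n: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """(t, λ(t)) on an evenly spaced grid over the curve domain."""
    lo, hi = curve.knots.domain
    t = np.linspace(lo, hi, n, endpoint=False)
    return t, curve(t)
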