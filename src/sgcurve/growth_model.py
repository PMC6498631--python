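"""Gompertz growth function and the hierarchical parameter structure.

Each animal grows along a Gompertz curve

    f(t; A, B, K) = A exp{-B exp(-K t)},

with A the asymptotic weight (kg), B a dimensionless time-shift and K the
maturing rate (1/day).  The structural model adds a causal contribution of the
entry-day weight:

    Y_{i,t} = Y_{i,0} λ(t) + f(t; A_i, B_i, K_i) + e_{i,t}.

The per-animal parameters carry an animal-model hierarchy: each of A, B, K is
fixed effects (sex, station) plus an additive genetic effect plus a residual;
the four genetic vectors (u_A, u_B, u_K, u_0) are jointly N(0, Σ_u ⊗ A_u) and
the three growth residual vectors are N(0, Σ_e ⊗ I).  The entry-day weight has
its own linear mixed model with maternal and reproduction-farm random effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .splines import CausalCurve

__all__ = [
    "GrowthParams",
    "GrowthHierarchy",
    "EntryDayModel",
    "gompertz",
    "gompertz_inflection",
    "predict_weight",
    "variance_explained",
]


@dataclass
class GrowthParams:
    """Per-animal Gompertz parameter triples (A in kg, B dimensionless, K per day)."""

    A: np.ndarray
    B: np.ndarray
    K: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.atleast_1d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_1d(np.asarray(self.B, dtype=float))
        self.K = np.atleast_1d(np.asarray(self.K, dtype=float))
        if not (self.A.shape == self.B.shape == self.K.shape):
            raise ValueError("A, B, K must have identical shapes")
        if np.any(self.A <= 0) or np.any(self.B <= 0) or np.any(self.K <= 0):
            raise ValueError("A, B, K must all be positive")

    def __len__(self) -> int:
        return self.A.size

    def as_matrix(self) -> np.ndarray:
        return np.column_stack([self.A, self.B, self.K])


@dataclass
class GrowthHierarchy:
    """Fixed effects, genetic effects and covariances of the growth parameters.

    ``X`` is the (N, p) design (intercept + treatment contrasts for sex and
    station), ``beta`` the (p, 3) fixed-effect matrix for (A, B, K), ``u`` the
    (N, 3) or (N, 4) genetic effects (4th column = entry-weight effect u_0),
    ``Sigma_u`` the genetic covariance and ``Sigma_e`` the 3x3 growth-residual
    covariance.
    """

    X: np.ndarray
    beta: np.ndarray
    u: np.ndarray
    Sigma_u: np.ndarray
    Sigma_e: np.ndarray

    def mean_params(self) -> np.ndarray:
        """Conditional mean of (A_i, B_i, K_i): Xβ + u (N, 3)."""
        return self.X @ self.beta + self.u[:, :3]


@dataclass
class EntryDayModel:
    """Linear mixed model for the entry-day weight Y_{i,0}.

    Y_{i,0} = x_{i,0} β_0 + u_{i,0} + Σ_j v_{j,i} + e_{i,0}, with v_1 the
    maternal effect (pedigree covariance), v_2 the reproduction-farm effect
    (identity covariance).  ``random_levels`` maps each extra random effect to
    the per-animal level index; ``random_values`` holds the level effects.
    """

    X0: np.ndarray
    beta0: np.ndarray
    u0: np.ndarray
    random_levels: list[np.ndarray] = field(default_factory=list)
    random_values: list[np.ndarray] = field(default_factory=list)
    sigma2_v: list[float] = field(default_factory=list)
    sigma2_e0: float = 1.0

    def mean(self) -> np.ndarray:
        """Conditional mean of Y_{i,0} given all effects."""
        m = self.X0 @ self.beta0 + self.u0
        for idx, vals in zip(self.random_levels, self.random_values):
            m = m + vals[idx]
        return m


def gompertz(t, A, B, K):
    """Gompertz weight A·exp{-B·exp(-K t)} at time t days; vectorized."""
    t = np.asarray(t, dtype=float)
    return A * np.exp(-B * np.exp(-K * t))


def gompertz_inflection(A, B, K):
    """(time, weight) of the inflection point: t = ln B / K, f = A/e."""
    return np.log(B) / K, A / np.e


def predict_weight(t, Y0, curve: CausalCurve, A, B, K):
    """Expected weight Y0·λ(t) + f(t; A, B, K) under the structural model."""
    lam = curve(t)
    return Y0 * lam + gompertz(t, A, B, K)


def variance_explained(coefficient) -> float:
    """Percent of phenotypic variance explained by the initial weight.

    A causal coefficient λ means the initial weight contributes λ·Y_0, hence
    the fraction of variance explained is λ²; returned as a percentage
    (square of the coefficient magnitude × 100).
    """
    c = np.asarray(coefficient, dtype=float)
    out = 100.0 * c**2
    return float(out) if out.ndim == 0 else out
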