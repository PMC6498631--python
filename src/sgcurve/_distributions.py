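"""Conjugate-draw helpers shared by the samplers."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "draw_scaled_inv_chisq",
    "scaled_inv_chisq_posterior",
    "draw_invwishart",
    "nearest_pd",
]


def scaled_inv_chisq_posterior(nu0: float, s0sq: float, ss: float, n: int) -> tuple[float, float]:
    """Posterior (ν, s²) of a scaled-inverse-χ² prior after observing sum of squares.

    Prior χ⁻²(ν0, s0²); n residuals with sum of squares ``ss`` give
    χ⁻²(ν0 + n, (ν0 s0² + ss) / (ν0 + n)).  The non-informative choice
    (ν0, s0²) = (−2, 0) requires n > 2 for a proper posterior.
    """
    df = nu0 + n
    if df <= 0:
        raise ValueError(
            f"improper posterior: prior df {nu0} with only n={n} observations"
        )
    return df, (nu0 * s0sq + ss) / df


def draw_scaled_inv_chisq(rng: np.random.Generator, df: float, scale: float) -> float:
    """One draw from χ⁻²(df, scale): df·scale / χ²_df."""
    return df * scale / rng.chisquare(df)


def draw_invwishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """One draw from IW(df, scale-matrix); mean is scale/(df - p - 1)."""
    return stats.invwishart.rvs(df=df, scale=scale, random_state=rng)


def nearest_pd(mat: np.ndarray, floor: float = 1e-10) -> tuple[np.ndarray, bool]:
    """Project a symmetric matrix to the nearest PD matrix by eigenvalue clipping.

    Returns (matrix, adjusted-flag); the flag signals that clipping occurred.
    """
    sym = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(sym)
    if w.min() > 0:
        return sym, False
    lim = max(floor, floor * abs(w).max())
    w = np.clip(w, lim, None)
    return (v * w) @ v.T, True
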