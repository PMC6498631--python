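"""Structural-equation transformation and exact joint log-likelihoods.

Writing the two-equation system as Λ Y_i (Λ unit lower triangular with -λ(t)
down the first column), the Jacobian determinant |Λ| is exactly 1, so the joint
density of the observed weights equals the product of the entry-day normal
density and the per-record normal densities of Y_{i,t} - λ(t) Y_{i,0} -
f(t; A_i, B_i, K_i).  Full normalizing constants (-½ log 2πσ² per record) are
included so that likelihood values are comparable across models for DIC/WAIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .growth_model import EntryDayModel, GrowthParams, gompertz
from .splines import CausalCurve

__all__ = [
    "ObservationSet",
    "ResidualParams",
    "build_structural_matrix",
    "sgc_log_likelihood",
    "gc_log_likelihood",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ObservationSet:
    """Ragged longitudinal weight records.

    ``entry_weight`` is Y_{i,0} (kg) measured on the entry day (t = 0);
    ``times``/``weights`` hold each animal's post-entry records (days since
    entry, kg), strictly increasing within animal.
    """

    entry_weight: np.ndarray
    times: list[np.ndarray]
    weights: list[np.ndarray]

    # flattened views, built once
    obs_animal: np.ndarray = field(init=False, repr=False)
    obs_t: np.ndarray = field(init=False, repr=False)
    obs_y: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.entry_weight = np.asarray(self.entry_weight, dtype=float)
        n = self.entry_weight.size
        if not (len(self.times) == len(self.weights) == n):
            raise ValueError("entry_weight, times, weights must align")
        self.times = [np.atleast_1d(np.asarray(t, dtype=float)) for t in self.times]
        self.weights = [np.atleast_1d(np.asarray(w, dtype=float)) for w in self.weights]
        for i, (t, w) in enumerate(zip(self.times, self.weights)):
            if t.shape != w.shape:
                raise ValueError(f"animal {i}: times/weights length mismatch")
            if t.size and (np.any(np.diff(t) <= 0) or t[0] <= 0):
                raise ValueError(f"animal {i}: times must be strictly increasing and > 0")
        self.obs_animal = np.repeat(np.arange(n), [t.size for t in self.times])
        self.obs_t = (
            np.concatenate(self.times) if n else np.empty(0)
        )
        self.obs_y = (
            np.concatenate(self.weights) if n else np.empty(0)
        )

    @property
    def n_animals(self) -> int:
        return self.entry_weight.size

    @property
    def n_records(self) -> int:
        """Post-entry record count (entry-day weights not included)."""
        return self.obs_t.size

    @property
    def T_i(self) -> np.ndarray:
        """Last measurement day per animal (0 if no post-entry record)."""
        return np.array([t[-1] if t.size else 0.0 for t in self.times])

    @property
    def T_L(self) -> float:
        """Greatest last-measurement day across animals."""
        return float(self.T_i.max()) if self.n_animals else 0.0


@dataclass
class ResidualParams:
    """Entry-day and trajectory residual variances (kg²)."""

    sigma2_e0: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if self.sigma2_e0 <= 0 or self.sigma2_e <= 0:
            raise ValueError("residual variances must be positive")


def build_structural_matrix(curve: CausalCurve, times) -> np.ndarray:
    """Unit-lower-triangular transformation for one animal's record vector.

    Row 0 corresponds to the entry-day record; the row for measurement time t
    has -λ(t) in column 0 and 1 on the diagonal.  Its determinant is exactly 1
    for any curve and measurement grid.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.unique(times).size != times.size:
        raise ValueError("duplicate measurement times")
    T = times.size
    lam = curve(times)
    m = np.eye(T + 1)
    m[1:, 0] = -lam
    return m


def _normal_logpdf(resid: np.ndarray, sigma2: float) -> np.ndarray:
    return -0.5 * (LOG_2PI + np.log(sigma2) + resid**2 / sigma2)


def sgc_pointwise_logdensities(
    data: ObservationSet,
    entry_mean: np.ndarray,
    growth: GrowthParams,
    curve: CausalCurve,
    resid: ResidualParams,
) -> tuple[np.ndarray, np.ndarray]:
    """(entry-record, post-entry-record) pointwise log-densities.

    ``entry_mean`` is the conditional mean of Y_{i,0} (fixed + genetic +
    maternal/farm effects); the trajectory terms condition on the latent
    growth parameters.
    """
    e0 = data.entry_weight - np.asarray(entry_mean, dtype=float)
    lp0 = _normal_logpdf(e0, resid.sigma2_e0)
    idx = data.obs_animal
    lam = curve(data.obs_t)
    f = gompertz(data.obs_t, growth.A[idx], growth.B[idx], growth.K[idx])
    r = data.obs_y - lam * data.entry_weight[idx] - f
    lp = _normal_logpdf(r, resid.sigma2_e)
    return lp0, lp


def sgc_log_likelihood(
    data: ObservationSet,
    entry: EntryDayModel | np.ndarray,
    growth: GrowthParams,
    curve: CausalCurve,
    resid: ResidualParams,
) -> float:
    """Exact joint log-likelihood of the structural growth curve model.

    ``entry`` may be an EntryDayModel (its conditional mean is used) or the
    precomputed mean vector itself.
    """
    mean = entry.mean() if isinstance(entry, EntryDayModel) else entry
    lp0, lp = sgc_pointwise_logdensities(data, mean, growth, curve, resid)
    return float(lp0.sum() + lp.sum())


def gc_pointwise_logdensities(
    times: np.ndarray,
    y: np.ndarray,
    animal_idx: np.ndarray,
    growth: GrowthParams,
    sigma2_e: float,
) -> np.ndarray:
    f = gompertz(times, growth.A[animal_idx], growth.B[animal_idx], growth.K[animal_idx])
    return _normal_logpdf(y - f, sigma2_e)


def gc_log_likelihood(
    data: ObservationSet,
    growth: GrowthParams,
    sigma2_e: float,
    include_entry: bool = True,
    time_offset: np.ndarray | float = 0.0,
) -> float:
    """Log-likelihood of the ordinary growth curve model Y_{i,t} = f(t) + e.

    With ``include_entry`` the entry-day weight is an ordinary record at t = 0
    (entry-day origin, GC_A) or at the entry age when a per-animal
    ``time_offset`` of ages is given (birth-day origin, GC_B).
    """
    if sigma2_e <= 0:
        raise ValueError("sigma2_e must be positive")
    offset = np.asarray(time_offset, dtype=float)
    idx = data.obs_animal
    t = data.obs_t + (offset[idx] if offset.ndim else offset)
    lp = gc_pointwise_logdensities(t, data.obs_y, idx, growth, sigma2_e)
    total = float(lp.sum())
    if include_entry:
        t0 = offset if offset.ndim else np.full(data.n_animals, offset)
        idx0 = np.arange(data.n_animals)
        lp0 = gc_pointwise_logdensities(
            t0, data.entry_weight, idx0, growth, sigma2_e
        )
        total += float(lp0.sum())
    return total
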