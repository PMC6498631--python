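"""Model comparison: mean log-likelihood, DIC, WAIC, and R-hat diagnostics.

Deviance is D(θ) = −2 log p(y | θ) with the likelihood conditional on the
latent growth parameters (observation-level focus); the "posterior mean"
plugged into DIC is the per-parameter posterior mean including latents.  WAIC
uses one weight record as the pointwise unit and the variance form of the
effective-parameter count (pWAIC2).  R-hat is the classic two-moment
Gelman–Rubin potential scale reduction factor without chain splitting; values
below 1.1 are taken as converged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mcmc import PosteriorSamples

__all__ = [
    "FitSummary",
    "compute_dic",
    "compute_waic",
    "compute_rhat",
    "rhat_table",
    "summarize_fit",
    "compare_models",
    "hpd_interval",
]


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Highest posterior density interval of a scalar sample (minimal width)."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    k = max(int(np.ceil(prob * n)), 2)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])

RHAT_THRESHOLD = 1.1


@dataclass
class FitSummary:
    """Comparison-ready summary of one fitted model."""

    model: str
    mean_loglik: float
    dic: float
    p_d: float
    waic: float
    p_waic: float
    rhat: dict[str, float] = field(default_factory=dict)
    n_records: int = 0

    def converged(self, threshold: float = RHAT_THRESHOLD) -> bool:
        vals = [v for v in self.rhat.values() if np.isfinite(v)]
        return bool(vals) and max(vals) < threshold


def compute_dic(samples: PosteriorSamples) -> tuple[float, float]:
    """(DIC, pD): D̄ + pD with pD = D̄ − D(posterior-mean parameters)."""
    ll = samples.loglik
    if ll.size < 2:
        raise ValueError("DIC requires at least two posterior draws")
    if samples.loglik_at_mean is None:
        raise ValueError("samples carry no log-likelihood at the posterior mean")
    d_bar = float(np.mean(-2.0 * ll))
    d_at_mean = -2.0 * samples.loglik_at_mean
    p_d = d_bar - d_at_mean
    if p_d < 0:
        warnings.warn(f"negative effective parameter count pD = {p_d:.3f}", stacklevel=2)
    return d_bar + p_d, p_d


def compute_waic(samples: PosteriorSamples) -> tuple[float, float]:
    """(WAIC, pWAIC): −2(lppd − pWAIC) from pointwise log-densities."""
    lp = samples.pointwise
    if lp.shape[0] < 2:
        raise ValueError("WAIC requires at least two posterior draws")
    m = lp.max(axis=0)
    lppd = float(np.sum(np.log(np.mean(np.exp(lp - m), axis=0)) + m))
    p_waic = float(np.sum(np.var(lp, axis=0, ddof=1)))
    if p_waic < 0:
        warnings.warn(f"negative pWAIC = {p_waic:.3f}", stacklevel=2)
    return -2.0 * (lppd - p_waic), p_waic


def compute_rhat(chains: np.ndarray) -> float:
    """Gelman–Rubin potential scale reduction for one scalar parameter.

    ``chains`` is (m, n): m ≥ 2 chains of n ≥ 2 draws.  Returns inf (with a
    warning) when the within-chain variance is zero but chains disagree.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains of >= 2 draws each")
    m, n = chains.shape
    w = float(np.mean(np.var(chains, axis=1, ddof=1)))
    b = n * float(np.var(np.mean(chains, axis=1), ddof=1))
    if w == 0.0:
        if b == 0.0:
            return 1.0  # all draws identical everywhere
        warnings.warn("zero within-chain variance; R-hat is infinite", stacklevel=2)
        return np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def rhat_table(samples: PosteriorSamples, include_loglik: bool = True) -> dict[str, float]:
    """R-hat for every scalar component of every recorded block (and loglik)."""
    out: dict[str, float] = {}
    if samples.n_chains < 2:
        return out
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in samples.names():
            arr = samples.stacked(name)
            flatdim = int(np.prod(arr.shape[2:])) if arr.ndim > 2 else 1
            arr2 = arr.reshape(arr.shape[0], arr.shape[1], flatdim)
            for k in range(flatdim):
                key = name if flatdim == 1 else f"{name}[{k}]"
                out[key] = compute_rhat(arr2[:, :, k])
        if include_loglik:
            out["loglik"] = compute_rhat(samples.stacked("_loglik"))
    return out


def summarize_fit(samples: PosteriorSamples, scalar_rhat_only: bool = True) -> FitSummary:
    """FitSummary from a PosteriorSamples: criteria plus convergence table.

    ``scalar_rhat_only`` restricts the R-hat table to variance components,
    spline weights and the log-likelihood (the per-animal latents would add
    thousands of rows).
    """
    dic, p_d = compute_dic(samples)
    waic, p_waic = compute_waic(samples)
    rhat: dict[str, float] = {}
    if samples.n_chains >= 2:
        skip = {"u", "G", "v_0", "v_1"} if scalar_rhat_only else set()
        names = [n for n in samples.names() if n not in skip]
        sub = _SubsetView(samples, names)
        rhat = rhat_table(sub)
    return FitSummary(
        model=samples.model,
        mean_loglik=float(samples.loglik.mean()),
        dic=dic,
        p_d=p_d,
        waic=waic,
        p_waic=p_waic,
        rhat=rhat,
        n_records=samples.pointwise.shape[1],
    )


class _SubsetView:
    """Read-only view of a PosteriorSamples restricted to some blocks."""

    def __init__(self, samples: PosteriorSamples, names: list[str]):
        self._s = samples
        self._names = names
        self.n_chains = samples.n_chains

    def names(self) -> list[str]:
        return self._names

    def stacked(self, name: str) -> np.ndarray:
        return self._s.stacked(name)


def compare_models(fits: list[FitSummary]) -> list[dict]:
    """Ranking report: one row per model with ranks under each criterion.

    Lower DIC/WAIC is better; higher mean log-likelihood is better.  All fits
    must cover the same number of records (same data).
    """
    if not fits:
        raise ValueError("no fits to compare")
    sizes = {f.n_records for f in fits}
    if len(sizes) != 1:
        raise ValueError(f"fits cover different data (record counts {sorted(sizes)})")

    def ranks(vals, reverse=False):
        order = sorted(range(len(vals)), key=lambda i: vals[i], reverse=reverse)
        rk = [0] * len(vals)
        pos = 1
        for j, i in enumerate(order):
            if j > 0 and vals[i] == vals[order[j - 1]]:
                rk[i] = rk[order[j - 1]]  # ties share a rank
            else:
                rk[i] = pos
            pos += 1
        return rk

    r_ll = ranks([f.mean_loglik for f in fits], reverse=True)
    r_dic = ranks([f.dic for f in fits])
    r_waic = ranks([f.waic for f in fits])
    rows = []
    for i, f in enumerate(fits):
        rows.append(
            {
                "model": f.model,
                "mean_loglik": f.mean_loglik,
                "dic": f.dic,
                "p_d": f.p_d,
                "waic": f.waic,
                "p_waic": f.p_waic,
                "rank_loglik": r_ll[i],
                "rank_dic": r_dic[i],
                "rank_waic": r_waic[i],
            }
        )
    rows.sort(key=lambda r: r["rank_dic"])
    return rows
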