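"""Classic (no-death) fluctuation-test estimation.

Implements the Luria-Delbruck mutant-count distribution via the
Ma-Sandri-Sarkar (MSS) recursion,

    p_0 = exp(-m),    p_k = (m / k) * sum_{i=0}^{k-1} p_i / (k - i + 1),

maximum-likelihood estimation of the expected number of mutational events m
per culture, and the uncorrected mutation rate mu = m / N_final. This is
the estimator used by FALCOR-style calculators; it assumes every division
produces a net cell (no death) and full plating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .types import FluctuationDataset, RateEstimate

__all__ = ["LDDistribution", "MutationNumberEstimate", "mss_pmf", "mle_m", "uncorrected_rate", "classic_rate"]

# likelihood-ratio drop for a ~95% profile-likelihood interval (chi2_1/2)
_LLR_DROP = 1.92
# jackpot guard: the O(kmax^2) recursion is pooled above this index
_KMAX_CAP = 1500
_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class LDDistribution:
    """Truncated Luria-Delbruck pmf p_0..p_kmax for a given m."""

    m: float
    probs: np.ndarray
    kmax: int

    @property
    def tail_mass(self) -> float:
        """Probability mass beyond kmax (pooled jackpot bin)."""
        return max(0.0, 1.0 - float(self.probs.sum()))


def mss_pmf(m: float, kmax: int) -> LDDistribution:
    """Luria-Delbruck probabilities p_0..p_kmax by the MSS recursion."""
    if m < 0:
        raise ValueError("m must be non-negative")
    if kmax < 0:
        raise ValueError("kmax must be non-negative")
    p = np.zeros(kmax + 1)
    p[0] = math.exp(-m)
    if kmax >= 1 and m > 0:
        # weights 1/(k-i+1) for i=0..k-1 run through 1/(k+1)..1/2
        recip = 1.0 / np.arange(2.0, kmax + 2.0)
        for k in range(1, kmax + 1):
            p[k] = (m / k) * np.dot(p[k - 1 :: -1], recip[:k])
    return LDDistribution(m=float(m), probs=p, kmax=kmax)


@dataclass(frozen=True)
class MutationNumberEstimate:
    """MLE of the expected mutational events per culture, with profile CI."""

    m: float
    ci_low: float
    ci_high: float
    loglik: float
    kmax: int
    diagnostics: dict = field(default_factory=dict, compare=False)


def _make_loglik(counts: np.ndarray, kmax: int):
    uniq, mult = np.unique(counts, return_counts=True)
    in_range = uniq <= kmax
    idx = uniq[in_range]
    w_in = mult[in_range]
    n_tail = int(mult[~in_range].sum())

    def loglik(m: float) -> float:
        dist = mss_pmf(m, kmax)
        ll = float(np.dot(w_in, np.log(np.maximum(dist.probs[idx], _LOG_FLOOR))))
        if n_tail:
            ll += n_tail * math.log(max(dist.tail_mass, _LOG_FLOOR))
        return ll

    return loglik


def mle_m(counts, kmax: int | None = None) -> MutationNumberEstimate:
    """Maximum-likelihood m from mutant counts of parallel cultures.

    The confidence interval is the profile-likelihood interval at a
    log-likelihood drop of 1.92 (asymptotic 95%). Counts above ``kmax``
    (default: the largest observed count, capped at 1500) are pooled into
    the distribution's tail bin, which keeps single jackpot cultures from
    dominating the fit and bounds the cost of the recursion.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    C = counts.size
    if np.all(counts == 0):
        # likelihood is exp(-C m): maximized at 0, drops by 1.92 at m = 1.92/C
        return MutationNumberEstimate(
            m=0.0, ci_low=0.0, ci_high=_LLR_DROP / C, loglik=0.0, kmax=0
        )
    if kmax is None:
        kmax = int(min(counts.max(), _KMAX_CAP))
    kmax = max(kmax, 1)
    loglik = _make_loglik(counts, kmax)

    hi = max(50.0, float(np.mean(counts)))
    res = optimize.minimize_scalar(
        lambda lg: -loglik(math.exp(lg)),
        bounds=(math.log(1e-9), math.log(hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    m_hat = math.exp(res.x)
    ll_max = -res.fun
    thresh = ll_max - _LLR_DROP

    def gap(m: float) -> float:
        return loglik(m) - thresh

    # lower CI bound
    lo_probe = 1e-12
    ci_low = 0.0 if gap(lo_probe) >= 0 else optimize.brentq(gap, lo_probe, m_hat)
    # upper CI bound: expand bracket geometrically
    upper = max(m_hat * 2, 1.0)
    while gap(upper) > 0 and upper < 1e6:
        upper *= 2
    ci_high = float("inf") if gap(upper) > 0 else optimize.brentq(gap, m_hat, upper)
    return MutationNumberEstimate(
        m=m_hat, ci_low=float(ci_low), ci_high=float(ci_high), loglik=ll_max, kmax=kmax
    )


def uncorrected_rate(
    m_est: MutationNumberEstimate, dataset: FluctuationDataset
) -> RateEstimate:
    """Classic mutation rate mu = m / N_final (no death correction).

    Requires full plating: partial plating distorts the count distribution
    in a way the MSS likelihood does not model, so such data must go through
    the simulation-based corrected estimator where thinning is exact.
    """
    if dataset.plating_fraction < 1.0:
        raise ValueError(
            "classic estimator assumes full plating; use the corrected "
            "(simulation-based) estimator for partial plating"
        )
    N = dataset.final_size
    return RateEstimate(
        rate=m_est.m / N,
        ci_low=m_est.ci_low / N,
        ci_high=m_est.ci_high / N,
        method="uncorrected",
        m_hat=m_est.m,
        diagnostics={"kmax": m_est.kmax, "loglik": m_est.loglik},
    )


def classic_rate(dataset: FluctuationDataset, kmax: int | None = None) -> RateEstimate:
    """Convenience pipeline: MSS MLE then mu = m / N_final."""
    return uncorrected_rate(mle_m(dataset.counts, kmax=kmax), dataset)
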