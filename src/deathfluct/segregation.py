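"""Death-rate estimation from plasmid-segregation time series.

A conditionally replicating plasmid stops replicating once its inducer is
removed and is then diluted at cell division: the plasmid-bearing fraction
F obeys

    F_final = F_initial * ((1 + res) / 2) ** g

where ``res`` is the residual plasmid replication rate relative to cell
division and ``g`` the number of generations (genome duplications per
surviving lineage). Inverting this gives g from observed F, and comparing g
with the generations implied by the net size change gives the relative
death rate

    d = 1 - log2(N_final / N_initial) / g.

``res`` is a property of the plasmid/host system and is fitted once from
untreated cultures, where death is assumed negligible so that
g = log2(N_final / N_initial).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import GrowthProfile, SegregationParameter, SegregationSeries

__all__ = [
    "fit_segregation_parameter",
    "generations_between",
    "relative_death_rate",
    "profile_from_segregation",
    "DeathRateResult",
    "DEFAULT_DEATH_CAP",
]

DEFAULT_DEATH_CAP = 5.0


class NoSegregationSignalError(ValueError):
    pass


def fit_segregation_parameter(
    untreated: SegregationSeries | Sequence[SegregationSeries],
) -> SegregationParameter:
    """Fit the retention factor sigma = log2((1+res)/2) from untreated growth.

    In untreated cultures death is assumed absent, so generations elapsed
    equal log2 of the fold-growth in total counts. log2 F is regressed on
    cumulative log2 fold-growth with the intercept anchored at log2 F(t0),
    jointly across all supplied replicate series: the slope is sigma.

    Raises
    ------
    ValueError
        If F does not decrease ("no segregation signal") or N does not grow
        ("cannot anchor generations without growth").
    """
    series = [untreated] if isinstance(untreated, SegregationSeries) else list(untreated)
    if not series:
        raise ValueError("need at least one untreated series")

    xs: list[float] = []
    ys: list[float] = []
    for s in series:
        total = np.asarray(s.total, dtype=float)
        frac = s.fractions
        if not np.all(np.diff(total) > 0):
            raise ValueError("cannot anchor generations without growth")
        if not frac[-1] < frac[0]:
            raise NoSegregationSignalError("no segregation signal")
        # Regression through the t0 anchor: x = cumulative log2 fold-growth,
        # y = log2 F relative to F(t0).
        x = np.log2(total / total[0])
        y = np.log2(frac / frac[0])
        xs.extend(x[1:])
        ys.extend(y[1:])

    x_arr = np.asarray(xs)
    y_arr = np.asarray(ys)
    sigma = float(x_arr @ y_arr / (x_arr @ x_arr))
    residuals = y_arr - sigma * x_arr
    diagnostics = {
        "n_points": int(x_arr.size),
        "rss": float(residuals @ residuals),
        "rmse": float(np.sqrt(np.mean(residuals**2))),
    }
    if sigma >= 0:
        raise NoSegregationSignalError("no segregation signal")
    # Retention cannot exceed pure dilution: a fitted sigma below -1 (possible
    # with plating noise) is clamped to res = 0.
    sigma = max(sigma, -1.0)
    return SegregationParameter.from_sigma(sigma, diagnostics)


def generations_between(
    F_initial: float, F_final: float, param: SegregationParameter
) -> float:
    """Generations elapsed between two plasmid-fraction measurements.

    g = log2(F_final / F_initial) / log2((1 + res) / 2)
    """
    if not 0 < F_final <= F_initial <= 1:
        if F_final > F_initial:
            raise ValueError("plasmid fraction increased")
        raise ValueError("fractions must lie in (0, 1] with F_final <= F_initial")
    if not param.sigma < 0:
        raise ValueError("segregation parameter carries no signal (sigma >= 0)")
    return math.log2(F_final / F_initial) / param.sigma


@dataclass(frozen=True)
class DeathRateResult:
    """Capped-and-clamped death rate plus the raw inverted value."""

    d: float
    d_raw: float
    generations: float
    clamped: bool
    capped: bool


def relative_death_rate(
    N_initial: float,
    N_final: float,
    F_initial: float,
    F_final: float,
    param: SegregationParameter,
    cap: float = DEFAULT_DEATH_CAP,
) -> DeathRateResult:
    """Relative death rate over one interval: d = 1 - log2(N_final/N_initial)/g.

    The raw value is clamped below at 0 (negative values can only arise from
    measurement noise) and capped above at ``cap``; both the processed and
    raw values are returned.
    """
    if N_initial <= 0 or N_final <= 0:
        raise ValueError("population sizes must be positive")
    g = generations_between(F_initial, F_final, param)
    log_ratio = math.log2(N_final / N_initial)
    if g == 0:
        if abs(log_ratio) > 1e-12:
            raise ValueError("divisions inconsistent with size change")
        return DeathRateResult(d=0.0, d_raw=0.0, generations=0.0, clamped=False, capped=False)
    d_raw = 1.0 - log_ratio / g
    d = d_raw
    clamped = capped = False
    if d < 0.0:
        d, clamped = 0.0, True
    if d > cap:
        d, capped = cap, True
    return DeathRateResult(d=d, d_raw=d_raw, generations=g, clamped=clamped, capped=capped)


def profile_from_segregation(
    series: SegregationSeries,
    param: SegregationParameter,
    cap: float = DEFAULT_DEATH_CAP,
) -> tuple[GrowthProfile, list[DeathRateResult]]:
    """Assemble a GrowthProfile with one inverted death rate per interval.

    Death rates are additionally adjusted where needed to restore sign
    consistency with the size trajectory (d forced above 1 on declining
    intervals, below 1 on growing ones); such intervals carry
    ``clamped=True`` in the returned per-interval results.
    """
    frac = series.fractions
    results: list[DeathRateResult] = []
    death_rates: list[float] = []
    for k in range(len(series.times) - 1):
        res = relative_death_rate(
            series.total[k],
            series.total[k + 1],
            frac[k],
            frac[k + 1],
            param,
            cap=cap,
        )
        d = res.d
        delta = series.total[k + 1] - series.total[k]
        # restore sign consistency lost to clamping/capping under noise
        if delta > 0 and d >= 1.0:
            d = 1.0 - 1e-6
            res = DeathRateResult(d, res.d_raw, res.generations, True, res.capped)
        elif delta < 0 and d <= 1.0:
            d = 1.0 + 1e-6
            res = DeathRateResult(d, res.d_raw, res.generations, True, res.capped)
        elif delta == 0 and d != 1.0:
            d = 1.0
            res = DeathRateResult(d, res.d_raw, res.generations, True, res.capped)
        results.append(res)
        death_rates.append(d)
    profile = GrowthProfile(series.times, series.total, death_rates)
    return profile, results
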