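"""Shared domain types for fluctuation assays under cell death.

The central object is a :class:`GrowthProfile`: a piecewise description of
one culture's population dynamics as (timepoint, viable count) pairs plus a
relative death rate ``d`` for each interval between successive timepoints.
``d`` is dimensionless — deaths per division event — so ``d < 1`` means net
growth, ``d > 1`` net decline, and ``d = 0`` the classical no-death regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GrowthProfile",
    "SegregationSeries",
    "SegregationParameter",
    "FluctuationDataset",
    "RateEstimate",
    "EvolvabilitySummary",
]

_SIGN_TOL = 1e-9


@dataclass(frozen=True)
class GrowthProfile:
    """Piecewise population dynamics of one culture.

    Parameters
    ----------
    times
        Strictly increasing timepoints, hours.
    sizes
        Viable population size (cells) at each timepoint.
    death_rates
        Relative death rate ``d`` (deaths per division) on each interval;
        one fewer entry than ``times``.
    initial_size
        Inoculum size in cells; defaults to ``sizes[0]``.
    """

    times: tuple[float, ...]
    sizes: tuple[float, ...]
    death_rates: tuple[float, ...]
    initial_size: float = 0.0

    def __init__(
        self,
        times: Sequence[float],
        sizes: Sequence[float],
        death_rates: Sequence[float],
        initial_size: float | None = None,
    ) -> None:
        times = tuple(float(t) for t in times)
        sizes = tuple(float(s) for s in sizes)
        death_rates = tuple(float(d) for d in death_rates)
        if len(times) < 2:
            raise ValueError("profile needs at least two timepoints")
        if len(sizes) != len(times):
            raise ValueError("sizes and times length mismatch")
        if len(death_rates) != len(times) - 1:
            raise ValueError("need one death rate per interval")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(s <= 0 for s in sizes):
            raise ValueError("sizes must be positive")
        if any(d < 0 for d in death_rates):
            raise ValueError("death rates must be non-negative")
        for k, d in enumerate(death_rates):
            delta = sizes[k + 1] - sizes[k]
            if abs(d - 1.0) < _SIGN_TOL:
                if abs(delta) > _SIGN_TOL * max(sizes[k], 1.0):
                    raise ValueError(
                        f"interval {k}: d = 1 requires a constant population size"
                    )
            elif delta * (1.0 - d) < -_SIGN_TOL * max(sizes[k], 1.0):
                raise ValueError(
                    f"interval {k}: size change and death rate are sign-inconsistent "
                    f"(dN = {delta:g}, d = {d:g})"
                )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "death_rates", death_rates)
        object.__setattr__(
            self, "initial_size", float(initial_size) if initial_size else sizes[0]
        )

    @property
    def n_intervals(self) -> int:
        return len(self.death_rates)

    @property
    def final_size(self) -> float:
        return self.sizes[-1]

    def without_death(self) -> "GrowthProfile":
        """Same size trajectory with every death rate set to zero.

        Only valid when the trajectory never declines (a decline cannot be
        produced without death).
        """
        if any(b < a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError("declining trajectory has no zero-death counterpart")
        return GrowthProfile(
            self.times, self.sizes, (0.0,) * self.n_intervals, self.initial_size
        )

    def rescaled(self, scale: float) -> "GrowthProfile":
        """Divide all population sizes by ``scale`` (desk-scale runs)."""
        if scale < 1:
            raise ValueError("scale must be >= 1")
        return GrowthProfile(
            self.times,
            tuple(s / scale for s in self.sizes),
            self.death_rates,
            self.initial_size / scale,
        )


@dataclass(frozen=True)
class SegregationSeries:
    """Paired total and plasmid-bearing viable counts over time.

    The plasmid-bearing fraction F = plasmid_bearing / total decays with the
    number of cell divisions, which is what makes death observable.
    """

    times: tuple[float, ...]
    total: tuple[float, ...]
    plasmid_bearing: tuple[float, ...]

    def __init__(
        self,
        times: Sequence[float],
        total: Sequence[float],
        plasmid_bearing: Sequence[float],
    ) -> None:
        times = tuple(float(t) for t in times)
        total = tuple(float(n) for n in total)
        plasmid_bearing = tuple(float(p) for p in plasmid_bearing)
        if not (len(times) == len(total) == len(plasmid_bearing)):
            raise ValueError("times, total, plasmid_bearing length mismatch")
        if len(times) < 2:
            raise ValueError("need at least two timepoints")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        for n, p in zip(total, plasmid_bearing):
            if not (0 < p <= n):
                raise ValueError("need 0 < plasmid_bearing <= total at every timepoint")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "total", total)
        object.__setattr__(self, "plasmid_bearing", plasmid_bearing)

    @property
    def fractions(self) -> np.ndarray:
        """Plasmid-bearing fraction F at each timepoint."""
        return np.asarray(self.plasmid_bearing) / np.asarray(self.total)


@dataclass(frozen=True)
class SegregationParameter:
    """Fitted per-generation plasmid retention.

    ``sigma = log2((1 + res) / 2)`` is the log2 retention factor per
    generation; ``res`` is the residual plasmid replication rate relative to
    the cell division rate once induction is removed. ``res = 0`` means pure
    dilution (F halves every generation, sigma = -1); ``res -> 1`` means the
    plasmid keeps up with division and there is no segregation signal.
    """

    sigma: float
    res: float
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not -1.0 <= self.sigma < 0.0:
            raise ValueError("sigma must lie in [-1, 0) for a usable signal")
        if not 0.0 <= self.res < 1.0:
            raise ValueError("res must lie in [0, 1)")
        if abs(self.sigma - np.log2((1.0 + self.res) / 2.0)) > 1e-9:
            raise ValueError("sigma and res are inconsistent")

    @classmethod
    def from_res(cls, res: float) -> "SegregationParameter":
        return cls(sigma=float(np.log2((1.0 + res) / 2.0)), res=float(res))

    @classmethod
    def from_sigma(cls, sigma: float, diagnostics: dict | None = None) -> "SegregationParameter":
        res = float(np.clip(2.0 ** (sigma + 1.0) - 1.0, 0.0, 1.0 - 1e-12))
        sigma = float(np.log2((1.0 + res) / 2.0))
        return cls(sigma=sigma, res=res, diagnostics=diagnostics or {})


@dataclass(frozen=True)
class FluctuationDataset:
    """Mutant colony counts across parallel cultures of one condition."""

    counts: tuple[int, ...]
    final_size: float
    initial_size: float
    plating_fraction: float = 1.0

    def __init__(
        self,
        counts: Sequence[int],
        final_size: float,
        initial_size: float,
        plating_fraction: float = 1.0,
    ) -> None:
        counts = tuple(int(c) for c in counts)
        if len(counts) == 0:
            raise ValueError("need at least one culture")
        if any(c < 0 for c in counts):
            raise ValueError("mutant counts must be non-negative")
        if not 0 < plating_fraction <= 1:
            raise ValueError("plating_fraction must lie in (0, 1]")
        if not final_size > initial_size >= 1:
            raise ValueError("need final_size > initial_size >= 1")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "final_size", float(final_size))
        object.__setattr__(self, "initial_size", float(initial_size))
        object.__setattr__(self, "plating_fraction", float(plating_fraction))

    @property
    def n_cultures(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class RateEstimate:
    """Mutation-rate point estimate (per division) with uncertainty interval."""

    rate: float
    ci_low: float
    ci_high: float
    method: str  # "uncorrected" | "corrected"
    m_hat: float
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if not self.ci_low <= self.rate <= self.ci_high:
            raise ValueError("need ci_low <= rate <= ci_high")
        if self.method not in ("uncorrected", "corrected"):
            raise ValueError("method must be 'uncorrected' or 'corrected'")


@dataclass(frozen=True)
class EvolvabilitySummary:
    """Absolute mutant supply in the final population (whole-culture scale)."""

    mean_mutants: float
    per_culture: tuple[float, ...]
    source: str  # "observed" | "simulated_no_death" | "simulated_with_death"

    def __init__(self, per_culture: Sequence[float], source: str) -> None:
        per_culture = tuple(float(x) for x in per_culture)
        if any(x < 0 for x in per_culture):
            raise ValueError("mutant numbers must be non-negative")
        if source not in ("observed", "simulated_no_death", "simulated_with_death"):
            raise ValueError(f"unknown source tag: {source}")
        object.__setattr__(self, "per_culture", per_culture)
        object.__setattr__(self, "mean_mutants", float(np.mean(per_culture)))
        object.__setattr__(self, "source", source)
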