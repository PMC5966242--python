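"""Stochastic simulation of fluctuation cultures under arbitrary death rates.

Two algorithms simulate the mutant count in the final population of a
culture growing along a :class:`~deathfluct.types.GrowthProfile`:

``hybrid``
    The production algorithm. The wild-type population follows the profile
    deterministically; mutational events arrive as a Poisson process with
    mean mu * B_k per interval, where B_k = dN / (1 - d_k) is the number of
    division events the interval requires. Each event seeds a clone that is
    propagated to the final timepoint as a linear birth-death process whose
    death/birth ratio matches the interval death rates; only the clones are
    stochastic, which makes the algorithm fast at realistic population
    sizes.

``gillespie``
    An exact event-by-event oracle for small populations: every single
    division and death is drawn explicitly, with the event schedule
    conditioned to reproduce the profile's sizes. Used to validate the
    hybrid algorithm.

Mutants are neutral: they divide and die at the same rates as the wild
type. Mutation is per division (a daughter cell of a wild-type division
mutates with probability mu), so results depend on the profile only through
its sizes and death rates, never through wall-clock interval durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import FluctuationDataset, GrowthProfile

__all__ = [
    "SimulationSettings",
    "CloneRecord",
    "GillespieResult",
    "interval_divisions",
    "simulate_culture",
    "simulate_mutant_counts",
    "gillespie_oracle",
    "simulate_fluctuation_assay",
]

_GILLESPIE_SIZE_GUARD = 100_000


@dataclass(frozen=True)
class SimulationSettings:
    """Algorithm choice, seed and optional desk-scale downscaling."""

    algorithm: str = "hybrid"
    seed: int = 0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.algorithm not in ("hybrid", "gillespie"):
            raise ValueError("algorithm must be 'hybrid' or 'gillespie'")
        if self.scale < 1:
            raise ValueError("scale must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class CloneRecord:
    """One mutational event and the fate of its descendants."""

    origin_interval: int
    origin_progress: float
    final_cells: int

    def __post_init__(self) -> None:
        if self.final_cells < 0:
            raise ValueError("final_cells must be >= 0")


def interval_divisions(N_start: float, N_end: float, d: float) -> float:
    """Division events needed to go from N_start to N_end at death rate d.

    Each division adds one cell net of (1 - d) once deaths are paid for, so
    B = (N_end - N_start) / (1 - d). With d = 0.8 a net increase of one cell
    requires five actual divisions. Declining intervals (d > 1) still
    require divisions: B = dN / (1 - d) > 0 because both factors flip sign.
    """
    delta = N_end - N_start
    if d == 1.0:
        if delta != 0:
            raise ValueError("d = 1 cannot produce a net size change")
        return 0.0
    if delta * (1.0 - d) < 0:
        raise ValueError(
            f"sign mismatch: dN = {delta:g} is impossible at death rate d = {d:g}"
        )
    return delta / (1.0 - d)


def _interval_schedule(profile: GrowthProfile) -> list[tuple[float, float, float]]:
    """(divisions B_k, duration T_k, d_k) per interval.

    Durations are internal bookkeeping: per-capita birth rate is fixed at 1
    per interval and the duration solved so the deterministic wild-type
    trajectory N(t) = N_k * exp((1 - d_k) t) hits the next size.
    """
    sched = []
    for k in range(profile.n_intervals):
        n0, n1, d = profile.sizes[k], profile.sizes[k + 1], profile.death_rates[k]
        B = interval_divisions(n0, n1, d)
        T = 0.0 if d == 1.0 else float(np.log(n1 / n0) / (1.0 - d))
        sched.append((B, T, d))
    return sched


def _bd_params(t, d: float):
    """Extinction probability p0 and geometric parameter pb for a linear
    birth-death process started from one cell, birth rate 1, death rate d,
    run for time t. The number of descendants is 0 with probability p0 and
    otherwise geometric: P(Z = j | Z > 0) = (1 - pb) pb**(j-1)."""
    t = np.asarray(t, dtype=float)
    if d == 1.0:
        p0 = t / (1.0 + t)
        return p0, p0.copy()
    w = np.exp((1.0 - d) * t)
    p0 = d * (w - 1.0) / (w - d)
    pb = (w - 1.0) / (w - d)
    return p0, pb


def _bd_propagate(
    cells: np.ndarray, t, d: float, rng: np.random.Generator
) -> np.ndarray:
    """Propagate clone sizes through time t of a birth-death interval."""
    p0, pb = _bd_params(t, d)
    alive = cells > 0
    out = np.zeros_like(cells)
    if not np.any(alive):
        return out
    n = cells[alive]
    p0a = np.broadcast_to(p0, cells.shape)[alive]
    pba = np.broadcast_to(pb, cells.shape)[alive]
    survivors = rng.binomial(n, 1.0 - p0a)
    extra = np.zeros_like(survivors)
    pos = survivors > 0
    if np.any(pos):
        extra[pos] = rng.negative_binomial(survivors[pos], 1.0 - pba[pos])
    out[alive] = survivors + extra
    return out


def simulate_mutant_counts(
    profile: GrowthProfile,
    mu: float,
    n_cultures: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hybrid simulation of final mutant counts for n_cultures cultures.

    Vectorized across cultures and clones; the per-culture mutant count is
    the sum of its clones' descendant numbers at the final timepoint.
    """
    if mu < 0:
        raise ValueError("mutation rate must be non-negative")
    if n_cultures < 1:
        raise ValueError("need at least one culture")
    sched = _interval_schedule(profile)
    counts = np.zeros(n_cultures, dtype=np.int64)
    if mu == 0:
        return counts
    for k, (B, T, d) in enumerate(sched):
        if B == 0:
            continue
        events = rng.poisson(mu * B, n_cultures)
        total = int(events.sum())
        if total == 0:
            continue
        culture_idx = np.repeat(np.arange(n_cultures), events)
        # progress through the interval, uniform over its divisions; division
        # progress maps linearly onto net size change
        u = rng.random(total)
        n0 = profile.sizes[k]
        delta = profile.sizes[k + 1] - n0
        n_at_mut = n0 + u * delta
        t_mut = np.log(n_at_mut / n0) / (1.0 - d)
        sizes = _bd_propagate(np.ones(total, dtype=np.int64), T - t_mut, d, rng)
        for B_j, T_j, d_j in sched[k + 1 :]:
            if T_j == 0.0:
                continue
            sizes = _bd_propagate(sizes, T_j, d_j, rng)
        np.add.at(counts, culture_idx, sizes)
    return counts


def simulate_culture(
    profile: GrowthProfile,
    mu: float,
    settings: SimulationSettings,
    record_clones: bool = False,
) -> int | tuple[int, list[CloneRecord]]:
    """Mutant count at the final timepoint of one culture.

    With ``record_clones=True`` additionally returns one
    :class:`CloneRecord` per mutational event (hybrid algorithm only).
    """
    if settings.scale > 1:
        profile = profile.rescaled(settings.scale)
        mu = mu * settings.scale
    rng = settings.rng()
    if settings.algorithm == "gillespie":
        if record_clones:
            raise ValueError("clone records are only available from the hybrid algorithm")
        return gillespie_oracle(profile, mu, settings).mutants
    if not record_clones:
        return int(simulate_mutant_counts(profile, mu, 1, rng)[0])
    # clone-by-clone path, sequential but identical in law
    sched = _interval_schedule(profile)
    records: list[CloneRecord] = []
    total = 0
    for k, (B, T, d) in enumerate(sched):
        if B == 0:
            continue
        n_events = rng.poisson(mu * B)
        for _ in range(n_events):
            u = float(rng.random())
            n0 = profile.sizes[k]
            n_at_mut = n0 + u * (profile.sizes[k + 1] - n0)
            t_mut = float(np.log(n_at_mut / n0) / (1.0 - d))
            size = _bd_propagate(np.array([1], dtype=np.int64), T - t_mut, d, rng)
            for B_j, T_j, d_j in sched[k + 1 :]:
                if T_j > 0.0:
                    size = _bd_propagate(size, T_j, d_j, rng)
            final = int(size[0])
            records.append(CloneRecord(k, u, final))
            total += final
    return total, records


@dataclass(frozen=True)
class GillespieResult:
    """Outcome and bookkeeping of one exact event-by-event run."""

    mutants: int
    divisions: tuple[int, ...]
    deaths: tuple[int, ...]
    clone_records: tuple = field(default=(), compare=False)


def _event_order(B: int, D: int, n0: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random interleaving of B births (+1) and D deaths (-1)
    conditioned on the population never reaching zero."""
    events = np.concatenate([np.ones(B, dtype=np.int64), -np.ones(D, dtype=np.int64)])
    for _ in range(100_000):
        rng.shuffle(events)
        if D == 0 or (n0 + np.cumsum(events)).min() >= 1:
            return events
    raise RuntimeError("could not schedule a non-extinct event order")


def gillespie_oracle(
    profile: GrowthProfile, mu: float, settings: SimulationSettings | None = None,
    rng: np.random.Generator | None = None,
) -> GillespieResult:
    """Exact single-cell-event simulation of one culture (small sizes only).

    Per interval, B_k = dN / (1 - d_k) division events and B_k - dN death
    events are interleaved uniformly at random subject to non-extinction.
    Each event picks a uniform random cell; each wild-type division produces
    a mutant daughter with probability mu. Conservation holds exactly:
    divisions - deaths = dN on every interval of every run.
    """
    if mu < 0:
        raise ValueError("mutation rate must be non-negative")
    if max(profile.sizes) > _GILLESPIE_SIZE_GUARD:
        raise ValueError(
            f"gillespie oracle is guarded to sizes <= {_GILLESPIE_SIZE_GUARD}"
        )
    if rng is None:
        rng = (settings or SimulationSettings(algorithm="gillespie")).rng()
    wt = int(round(profile.sizes[0]))
    mut = 0
    divisions: list[int] = []
    deaths: list[int] = []
    for k in range(profile.n_intervals):
        n0 = int(round(profile.sizes[k]))
        n1 = int(round(profile.sizes[k + 1]))
        d = profile.death_rates[k]
        delta = n1 - n0
        B = int(round(interval_divisions(n0, n1, d)))
        D = B - delta
        if D < 0:
            raise ValueError("death rate implies negative death count at this size")
        order = _event_order(B, D, n0, rng)
        b_count = 0
        d_count = 0
        for ev in order:
            pop = wt + mut
            is_mut = rng.random() < mut / pop
            if ev > 0:
                b_count += 1
                if is_mut:
                    mut += 1
                elif rng.random() < mu:
                    mut += 1
                else:
                    wt += 1
            else:
                d_count += 1
                if is_mut:
                    mut -= 1
                else:
                    wt -= 1
        divisions.append(b_count)
        deaths.append(d_count)
    return GillespieResult(mutants=mut, divisions=tuple(divisions), deaths=tuple(deaths))


def simulate_fluctuation_assay(
    profile: GrowthProfile,
    mu: float,
    n_cultures: int,
    plating_fraction: float,
    settings: SimulationSettings,
) -> FluctuationDataset:
    """Simulate a parallel-culture fluctuation assay with plating.

    Each culture is an independent draw; observed counts are a binomial
    thinning of each culture's true mutant number with the plating fraction.
    """
    if n_cultures < 1:
        raise ValueError("need at least one culture")
    if not 0 < plating_fraction <= 1:
        raise ValueError("plating_fraction must lie in (0, 1]")
    if settings.scale > 1:
        profile = profile.rescaled(settings.scale)
        mu = mu * settings.scale
    rng = settings.rng()
    if settings.algorithm == "gillespie":
        raw = np.array(
            [gillespie_oracle(profile, mu, rng=rng).mutants for _ in range(n_cultures)],
            dtype=np.int64,
        )
    else:
        raw = simulate_mutant_counts(profile, mu, n_cultures, rng)
    plated = raw if plating_fraction == 1.0 else rng.binomial(raw, plating_fraction)
    return FluctuationDataset(
        counts=plated,
        final_size=profile.final_size,
        initial_size=profile.initial_size,
        plating_fraction=plating_fraction,
    )
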