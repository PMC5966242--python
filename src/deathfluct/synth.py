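"""Synthetic fixtures emulating sub-MIC stress regimes.

Each fixture bundles, for one culture condition, everything the analysis
pipeline consumes plus the ground truth it should recover: a plasmid
segregation time series (optionally with plate-count sampling noise), the
true growth profile that generated it, a simulated fluctuation dataset, and
the true mutation rate.

Four regimes are provided, mirroring qualitatively distinct population
dynamics observed under subinhibitory antimicrobials:

``untreated``
    No death; steady growth to carrying capacity.
``norfloxacin_like``
    Persistent substantial death throughout growth and a reduced final
    population size.
``h2o2_like``
    Mostly bacteriostatic during exponential growth, with death appearing
    only at the approach to stationary phase; final size unaffected.
``kanamycin_like``
    An early bactericidal phase (net decline, d > 1) followed by recovery
    to near the untreated final size, with death continuing during
    regrowth.

Sizes are desk scale (final ~1e4-1e5 cells with mutation rates ~1e-5 per
division, keeping the expected number of mutational events per culture of
order one, as in typical assays at full scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SimulationSettings, simulate_fluctuation_assay
from .types import FluctuationDataset, GrowthProfile, SegregationSeries

__all__ = ["Fixture", "REGIMES", "make_fixture", "forward_segregation"]

# sampling grid used for the plate counts, hours
_TIMES = (0.0, 3.0, 6.0, 24.0)

# regime -> (sizes at the four timepoints, death rate per interval)
REGIMES: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "untreated": ((50.0, 2e3, 2e4, 1e5), (0.0, 0.0, 0.0)),
    "norfloxacin_like": ((50.0, 1e3, 5e3, 2e4), (0.5, 0.7, 0.8)),
    "h2o2_like": ((50.0, 2e3, 2e4, 1e5), (0.0, 0.0, 0.6)),
    "kanamycin_like": ((2e3, 8e2, 5e2, 8e4), (2.5, 2.0, 0.5)),
}

DEFAULT_RES = 0.1
DEFAULT_F0 = 0.95
DEFAULT_MU = 1e-5


def forward_segregation(
    profile: GrowthProfile, res: float, F0: float = DEFAULT_F0
) -> np.ndarray:
    """Noise-free plasmid-bearing fraction at each profile timepoint.

    Per interval, generations g = log2(N_ratio) / (1 - d) and the fraction
    multiplies by ((1 + res) / 2) ** g.
    """
    retention = (1.0 + res) / 2.0
    F = [F0]
    for k in range(profile.n_intervals):
        ratio = profile.sizes[k + 1] / profile.sizes[k]
        g = np.log2(ratio) / (1.0 - profile.death_rates[k])
        F.append(F[-1] * retention**g)
    return np.asarray(F)


@dataclass(frozen=True)
class Fixture:
    """One condition's synthetic data plus its generating ground truth."""

    regime: str
    series: SegregationSeries
    profile: GrowthProfile
    dataset: FluctuationDataset
    true_mu: float
    true_res: float
    true_fractions: np.ndarray


def _noisy_series(
    profile: GrowthProfile,
    fractions: np.ndarray,
    rng: np.random.Generator,
    colonies_per_plate: float,
) -> SegregationSeries:
    """Plate-count sampling noise: each measurement is a Poisson colony
    count at a dilution targeting ``colonies_per_plate`` colonies."""
    total = []
    plasmid = []
    for N, F in zip(profile.sizes, fractions):
        dil_t = colonies_per_plate / N
        c_total = max(int(rng.poisson(colonies_per_plate)), 1)
        n_hat = c_total / dil_t
        dil_p = colonies_per_plate / (N * F)
        c_plasmid = max(int(rng.poisson(colonies_per_plate)), 1)
        p_hat = c_plasmid / dil_p
        total.append(n_hat)
        plasmid.append(min(p_hat, n_hat))
    return SegregationSeries(profile.times, total, plasmid)


def make_fixture(
    regime: str,
    seed: int = 0,
    true_mu: float = DEFAULT_MU,
    res: float = DEFAULT_RES,
    n_cultures: int = 24,
    plating_fraction: float = 1.0,
    noise: bool = True,
    colonies_per_plate: float = 300.0,
) -> Fixture:
    """Generate one condition's synthetic dataset with known ground truth.

    Deterministic given ``seed``. With ``noise=False`` the segregation
    series carries the exact deterministic recursion values (useful for
    round-trip tests); with noise, plate counts are Poisson at about
    ``colonies_per_plate`` colonies per plate.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; choose from {sorted(REGIMES)}")
    sizes, death_rates = REGIMES[regime]
    profile = GrowthProfile(_TIMES, sizes, death_rates)
    fractions = forward_segregation(profile, res)
    rng = np.random.default_rng(seed)
    if noise:
        series = _noisy_series(profile, fractions, rng, colonies_per_plate)
    else:
        series = SegregationSeries(
            profile.times, profile.sizes, fractions * np.asarray(profile.sizes)
        )
    sim = SimulationSettings(
        algorithm="hybrid", seed=int(rng.integers(0, 2**31 - 1))
    )
    dataset = simulate_fluctuation_assay(
        profile, true_mu, n_cultures, plating_fraction, sim
    )
    return Fixture(
        regime=regime,
        series=series,
        profile=profile,
        dataset=dataset,
        true_mu=true_mu,
        true_res=res,
        true_fractions=fractions,
    )
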