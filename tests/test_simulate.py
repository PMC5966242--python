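"""Birth-death culture simulation: hybrid algorithm vs event-by-event oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import deathfluct as df
from deathfluct.simulate import (
    SimulationSettings,
    gillespie_oracle,
    interval_divisions,
    simulate_culture,
    simulate_fluctuation_assay,
    simulate_mutant_counts,
)


class TestIntervalDivisions:
    def test_one_net_cell_at_d08_needs_five_divisions(self):
        assert interval_divisions(10, 11, 0.8) == pytest.approx(5.0)

    @given(k=st.integers(1, 10**6))
    def test_no_death_one_division_per_net_cell(self, k):
        assert interval_divisions(100, 100 + k, 0.0) == k

    def test_declining_phase_still_requires_divisions(self):
        assert interval_divisions(300, 200, 2.0) == pytest.approx(100.0)

    def test_d_one_with_size_change_rejected(self):
        with pytest.raises(ValueError):
            interval_divisions(100, 200, 1.0)
        assert interval_divisions(100, 100, 1.0) == 0.0

    def test_sign_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sign mismatch"):
            interval_divisions(100, 200, 1.5)
        with pytest.raises(ValueError, match="sign mismatch"):
            interval_divisions(200, 100, 0.5)


class TestHybrid:
    def test_zero_rate_never_produces_mutants(self, growth_profile, rng):
        counts = simulate_mutant_counts(growth_profile, 0.0, 100, rng)
        assert np.all(counts == 0)

    def test_deterministic_given_seed(self, death_profile):
        s = SimulationSettings(seed=7)
        a = simulate_fluctuation_assay(death_profile, 1e-5, 24, 0.5, s)
        b = simulate_fluctuation_assay(death_profile, 1e-5, 24, 0.5, s)
        assert a.counts == b.counts

    def test_results_independent_of_wallclock_times(self):
        # mutation is per division: stretching the time axis changes nothing
        p1 = df.GrowthProfile((0, 24), (100, 1e4), (0.5,))
        p2 = df.GrowthProfile((0, 240), (100, 1e4), (0.5,))
        a = simulate_mutant_counts(p1, 1e-4, 200, np.random.default_rng(3))
        b = simulate_mutant_counts(p2, 1e-4, 200, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_matches_ld_distribution_without_death(self, rng):
        # cross-module oracle: d = 0 empirical pmf vs MSS recursion
        from scipy import stats

        prof = df.GrowthProfile((0, 10), (1, 1e6), (0.0,))
        m = 1.0
        counts = simulate_mutant_counts(prof, m / (1e6 - 1), 50_000, rng)
        pmf = df.mss_pmf(m, 40)
        exp = np.append(pmf.probs, pmf.tail_mass) * counts.size
        obs = np.bincount(np.minimum(counts, 41), minlength=42).astype(float)
        keep = exp >= 5
        obs_p, exp_p = obs[keep], exp[keep]
        if (~keep).any():
            obs_p = np.append(obs_p, obs[~keep].sum())
            exp_p = np.append(exp_p, exp[~keep].sum())
        p = stats.chisquare(obs_p, exp_p * obs_p.sum() / exp_p.sum()).pvalue
        assert p > 0.01

    def test_clone_records_sum_to_count(self, tiny_profile):
        total, records = simulate_culture(
            tiny_profile, 0.05, SimulationSettings(seed=11), record_clones=True
        )
        assert total == sum(r.final_cells for r in records)
        assert all(0 <= r.origin_progress <= 1 for r in records)

    def test_scale_preserves_expected_events(self):
        # downscaling sizes while scaling mu up keeps m = mu * divisions
        prof = df.GrowthProfile((0, 24), (100, 1e5), (0.0,))
        a = simulate_fluctuation_assay(prof, 1e-5, 500, 1.0, SimulationSettings(seed=5))
        b = simulate_fluctuation_assay(
            prof, 1e-5, 500, 1.0, SimulationSettings(seed=5, scale=10)
        )
        # same expected number of mutational events; means agree loosely
        assert np.mean(b.counts) == pytest.approx(np.mean(a.counts), rel=0.5)


class TestGillespieOracle:
    def test_zero_rate(self, tiny_profile):
        assert gillespie_oracle(tiny_profile, 0.0).mutants == 0

    def test_conservation_no_death(self):
        prof = df.GrowthProfile((0, 5), (10, 200), (0.0,))
        res = gillespie_oracle(prof, 0.01, SimulationSettings(seed=3))
        assert res.divisions == (190,)
        assert res.deaths == (0,)

    def test_conservation_with_death_every_run(self, rng):
        prof = df.GrowthProfile((0, 5, 10), (10, 100, 60), (0.8, 2.0))
        for _ in range(20):
            res = gillespie_oracle(prof, 0.01, rng=rng)
            assert res.divisions[0] - res.deaths[0] == 90
            assert res.divisions[1] - res.deaths[1] == -40

    def test_division_death_ratio_matches_d(self, rng):
        prof = df.GrowthProfile((0, 5), (20, 120), (0.8,))
        res = gillespie_oracle(prof, 0.0, rng=rng)
        assert res.deaths[0] / res.divisions[0] == pytest.approx(0.8, abs=0.01)

    def test_size_guard(self):
        prof = df.GrowthProfile((0, 5), (10, 1e6), (0.0,))
        with pytest.raises(ValueError, match="guard"):
            gillespie_oracle(prof, 0.0)


_TV_EDGES = np.array([0, 1, 2, 3, 4, 5, 6, 8, 10, 15, 25, 50, 10**9])


def _binned_tv(a, b):
    # pooled bins keep the sparse-support sampling noise of a raw TV
    # estimate from swamping a genuine distributional difference
    ha = np.histogram(a, _TV_EDGES)[0] / a.size
    hb = np.histogram(b, _TV_EDGES)[0] / b.size
    return 0.5 * np.abs(ha - hb).sum()


@pytest.mark.parametrize(
    "d,profile_args,mu,n",
    [
        (0.0, ((0, 5), (5, 50), (0.0,)), 0.01, 15_000),
        (0.5, ((0, 5), (5, 50), (0.5,)), 0.01, 15_000),
        (0.9, ((0, 5), (10, 100), (0.9,)), 0.002, 12_000),
        (2.0, ((0, 2, 5), (5, 60, 30), (0.0, 2.0)), 0.01, 15_000),
    ],
)
def test_hybrid_agrees_with_oracle(d, profile_args, mu, n, rng):
    """Total-variation distance between hybrid and exact pmfs < 0.02."""
    prof = df.GrowthProfile(*profile_args)
    h = simulate_mutant_counts(prof, mu, n, rng)
    g = np.array([gillespie_oracle(prof, mu, rng=rng).mutants for _ in range(n)])
    assert _binned_tv(h, g) < 0.02


def test_neutral_clone_mean_matches_oracle(rng):
    """Marginal expected mutant number agrees between hybrid and oracle."""
    prof = df.GrowthProfile((0, 5), (10, 100), (0.5,))
    mu = 0.02
    n = 20_000
    h = simulate_mutant_counts(prof, mu, n, rng).mean()
    g = np.mean([gillespie_oracle(prof, mu, rng=rng).mutants for _ in range(n)])
    assert h == pytest.approx(g, rel=0.1)


class TestFluctuationAssay:
    def test_vanishing_plating_fraction_gives_zero_counts(self, growth_profile):
        ds = simulate_fluctuation_assay(
            growth_profile, 1e-5, 24, 1e-12, SimulationSettings(seed=1)
        )
        assert all(c == 0 for c in ds.counts)

    def test_zero_rate_gives_zero_counts(self, growth_profile):
        ds = simulate_fluctuation_assay(
            growth_profile, 0.0, 24, 1.0, SimulationSettings(seed=1)
        )
        assert all(c == 0 for c in ds.counts)

    def test_mss_mle_recovers_m_from_simulated_counts(self, growth_profile):
        # d = 0, full plating, m = 2: estimator consistency at large C
        m = 2.0
        mu = m / (growth_profile.final_size - growth_profile.initial_size)
        ds = simulate_fluctuation_assay(
            growth_profile, mu, 5000, 1.0, SimulationSettings(seed=9)
        )
        m_hat = df.mle_m(ds.counts).m
        assert m_hat == pytest.approx(m, rel=0.05)
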