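"""Plasmid-segregation algebra: retention fit, generations, death rates."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import deathfluct as df
from deathfluct.segregation import (
    fit_segregation_parameter,
    generations_between,
    profile_from_segregation,
    relative_death_rate,
)
from deathfluct.synth import forward_segregation, make_fixture


def _series_from_profile(profile, res, F0=0.95):
    F = forward_segregation(profile, res, F0=F0)
    return df.SegregationSeries(
        profile.times, profile.sizes, F * np.asarray(profile.sizes)
    )


class TestFitSegregationParameter:
    def test_one_generation_exact_halving(self):
        # F 0.9 -> 0.45 while N doubles: one generation, pure dilution
        s = df.SegregationSeries((0, 3), (1e6, 2e6), (0.9e6, 0.45 * 2e6))
        p = fit_segregation_parameter(s)
        assert p.sigma == pytest.approx(-1.0, abs=1e-12)
        assert p.res == pytest.approx(0.0, abs=1e-9)

    def test_constant_fraction_is_no_signal(self):
        s = df.SegregationSeries((0, 3), (1e6, 2e6), (0.5e6, 1e6))
        with pytest.raises(ValueError, match="no segregation signal"):
            fit_segregation_parameter(s)

    def test_non_growing_population_cannot_anchor(self):
        s = df.SegregationSeries((0, 3), (2e6, 1e6), (1.8e6, 0.5e6))
        with pytest.raises(ValueError, match="cannot anchor"):
            fit_segregation_parameter(s)

    def test_recovers_res_from_noiseless_ten_generations(self):
        # forward recursion F_g = F0 * ((1+res)/2)^g with res = 0.2
        res = 0.2
        g = np.arange(11.0)
        total = 1e3 * 2.0**g
        F = 0.95 * ((1 + res) / 2) ** g
        s = df.SegregationSeries(g, total, F * total)
        p = fit_segregation_parameter(s)
        assert p.sigma == pytest.approx(np.log2(0.6), abs=1e-9)
        assert p.res == pytest.approx(res, abs=1e-9)

    def test_joint_fit_across_replicates(self):
        res = 0.3
        reps = []
        for n0 in (1e3, 5e3):
            prof = df.GrowthProfile((0, 3, 6), (n0, 4 * n0, 32 * n0), (0.0, 0.0))
            reps.append(_series_from_profile(prof, res))
        p = fit_segregation_parameter(reps)
        assert p.res == pytest.approx(res, abs=1e-9)


class TestGenerationsBetween:
    def test_two_halvings(self):
        p = df.SegregationParameter.from_res(0.0)
        assert generations_between(0.4, 0.1, p) == pytest.approx(2.0)

    def test_unchanged_fraction_is_zero_generations(self):
        p = df.SegregationParameter.from_res(0.0)
        assert generations_between(0.5, 0.5, p) == 0.0

    def test_plug_in_with_residual_replication(self):
        p = df.SegregationParameter.from_sigma(np.log2(0.6))
        assert generations_between(0.9, 0.9 * 0.6**3, p) == pytest.approx(3.0, rel=1e-9)

    def test_increasing_fraction_rejected(self):
        p = df.SegregationParameter.from_res(0.0)
        with pytest.raises(ValueError, match="plasmid fraction increased"):
            generations_between(0.4, 0.5, p)

    @given(
        f0=st.floats(0.2, 1.0),
        ratio1=st.floats(0.05, 0.95),
        ratio2=st.floats(0.05, 0.95),
    )
    def test_monotone_in_fraction_decay(self, f0, ratio1, ratio2):
        # faster F decay (smaller final fraction) => more generations
        p = df.SegregationParameter.from_res(0.1)
        g1 = generations_between(f0, f0 * ratio1, p)
        g2 = generations_between(f0, f0 * ratio2, p)
        if ratio1 < ratio2:
            assert g1 > g2


class TestRelativeDeathRate:
    def test_fourfold_growth_over_two_generations_is_no_death(self):
        p = df.SegregationParameter.from_res(0.0)
        r = relative_death_rate(1e3, 4e3, 0.4, 0.1, p)
        assert r.d == pytest.approx(0.0, abs=1e-12)

    def test_twofold_growth_over_two_generations_is_half(self):
        p = df.SegregationParameter.from_res(0.0)
        r = relative_death_rate(1e3, 2e3, 0.4, 0.1, p)
        assert r.d == pytest.approx(0.5)

    def test_cap_at_five(self):
        # raw d = 7: 2 generations with 2^(-12)-fold 'growth'
        p = df.SegregationParameter.from_res(0.0)
        r = relative_death_rate(4096e3, 1e3, 0.4, 0.1, p)
        assert r.d_raw == pytest.approx(7.0)
        assert r.d == 5.0
        assert r.capped

    def test_negative_raw_clamped_to_zero(self):
        p = df.SegregationParameter.from_res(0.0)
        r = relative_death_rate(1e3, 8e3, 0.4, 0.1, p)  # 3 doublings, 2 generations
        assert r.d_raw < 0
        assert r.d == 0.0
        assert r.clamped

    @given(scale=st.floats(0.01, 100.0))
    def test_invariant_to_common_size_rescaling(self, scale):
        p = df.SegregationParameter.from_res(0.1)
        a = relative_death_rate(1e3, 3e3, 0.8, 0.2, p)
        b = relative_death_rate(1e3 * scale, 3e3 * scale, 0.8, 0.2, p)
        assert a.d == pytest.approx(b.d, rel=1e-9)


class TestProfileFromSegregation:
    def test_untreated_self_consistency(self):
        prof = df.GrowthProfile((0, 6), (1e3, 32e3), (0.0,))
        s = _series_from_profile(prof, 0.15)
        param = fit_segregation_parameter(s)
        rec, results = profile_from_segregation(s, param)
        assert rec.death_rates[0] == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_round_trip(self):
        # forward-simulate d = (0.3, 0.3, 1.5), invert, recover within 1e-6
        prof = df.GrowthProfile((0, 3, 6, 24), (1e3, 5e3, 2e4, 1.5e4), (0.3, 0.3, 1.5))
        s = _series_from_profile(prof, 0.2)
        param = df.SegregationParameter.from_res(0.2)
        rec, results = profile_from_segregation(s, param)
        assert np.allclose(rec.death_rates, prof.death_rates, atol=1e-6)
        assert not any(r.capped or r.clamped for r in results)

    def test_kanamycin_like_shape(self):
        fx = make_fixture("kanamycin_like", seed=0, noise=False)
        param = df.SegregationParameter.from_res(fx.true_res)
        rec, _ = profile_from_segregation(fx.series, param)
        assert rec.death_rates[0] > 1  # declining phase
        assert rec.death_rates[-1] < 1  # recovery phase

    @given(
        res=st.floats(0.0, 0.9),
        d1=st.floats(0.0, 0.9),
        d2=st.floats(1.1, 4.0),
    )
    def test_round_trip_property(self, res, d1, d2):
        # growth then decline, arbitrary res: exact inversion
        prof = df.GrowthProfile((0, 3, 6), (1e3, 8e3, 6e3), (d1, d2))
        s = _series_from_profile(prof, res)
        param = df.SegregationParameter.from_res(res)
        rec, _ = profile_from_segregation(s, param)
        assert np.allclose(rec.death_rates, prof.death_rates, atol=1e-6)

    def test_noisy_recovery_median_error(self, rng):
        # plate-count noise at ~300 colonies/plate, true d = 0.5
        from deathfluct.synth import _noisy_series

        errs = []
        for _ in range(100):
            fx = make_fixture("untreated", seed=int(rng.integers(2**31)), res=0.1)
            param = fit_segregation_parameter(fx.series)
            tprof = df.GrowthProfile((0, 24), (100, 1e4), (0.5,))
            tF = forward_segregation(tprof, 0.1)
            ts = _noisy_series(tprof, tF, np.random.default_rng(int(rng.integers(2**31))), 300)
            rec, _ = profile_from_segregation(ts, param)
            errs.append(abs(rec.death_rates[0] - 0.5))
        assert np.median(errs) < 0.25
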