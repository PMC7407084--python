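"""Population-level kinetics: rates, Gompertz fitting, fitness, shift."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osmofit import (
    DiauxicSimParams,
    GrowthCurve,
    GrowthSimParams,
    detect_shift,
    fit_gompertz,
    generations_per_cycle,
    instantaneous_growth_rate,
    max_growth_rate,
    mean_curve,
    preprocess,
    rate_vs_od,
    relative_fitness,
    replicate_stats,
    saturation_od,
    simulate_diauxic_curve,
    simulate_growth_curve,
)
from osmofit.errors import (
    AlignmentError,
    NoCrossingError,
    OutOfRangeError,
    ParameterError,
)
from osmofit.growth import GrowthRateSeries, gompertz_od


class TestPreprocess:
    def test_single_curve_zero_blank_unchanged(self, exponential_curve):
        (out,) = preprocess([exponential_curve], blank=0.0)
        np.testing.assert_array_equal(out.od, exponential_curve.od)

    def test_identical_replicates_have_zero_sem(self, gompertz_curve):
        _, _, sem = replicate_stats([gompertz_curve] * 4)
        np.testing.assert_array_equal(sem, 0.0)

    def test_two_replicate_mean_and_sem(self):
        t = np.array([0.0, 1.0, 2.0])
        a = GrowthCurve(time=t, od=np.array([0.1, 0.1, 0.1]))
        b = GrowthCurve(time=t, od=np.array([0.3, 0.3, 0.3]))
        _, mean, sem = replicate_stats([a, b])
        assert mean[0] == pytest.approx(0.2)
        assert sem[0] == pytest.approx(0.1)   # sd=0.1414, /sqrt(2)

    def test_disjoint_time_ranges_rejected(self):
        a = GrowthCurve(time=[0.0, 1.0, 2.0], od=[0.1, 0.2, 0.3])
        b = GrowthCurve(time=[5.0, 6.0, 7.0], od=[0.1, 0.2, 0.3])
        with pytest.raises(AlignmentError):
            replicate_stats([a, b])


class TestInstantaneousRate:
    @pytest.mark.parametrize("window", [3, 5, 9])
    def test_exact_exponential_gives_constant_rate(self, exponential_curve,
                                                   window):
        s = instantaneous_growth_rate(exponential_curve, window=window)
        np.testing.assert_allclose(s.rate, 0.5, rtol=0, atol=1e-9)

    def test_constant_od_gives_zero_rate(self):
        c = GrowthCurve(time=np.arange(10.0), od=np.full(10, 0.3))
        s = instantaneous_growth_rate(c)
        np.testing.assert_allclose(s.rate, 0.0, atol=1e-12)

    def test_rate_undefined_below_floor(self):
        od = np.array([0.001, 0.002, 0.004, 0.01, 0.02, 0.04, 0.08])
        c = GrowthCurve(time=np.arange(7.0), od=od)
        s = instantaneous_growth_rate(c, window=3)
        assert not np.isfinite(s.rate[0])
        assert np.isfinite(s.rate[-1])

    def test_even_or_oversized_window_rejected(self, exponential_curve):
        with pytest.raises(ParameterError):
            instantaneous_growth_rate(exponential_curve, window=4)
        with pytest.raises(ParameterError):
            instantaneous_growth_rate(exponential_curve, window=999)


class TestRateVsOD:
    def test_exponential_rate_constant_at_any_od(self, exponential_curve):
        rv = rate_vs_od(instantaneous_growth_rate(exponential_curve))
        for od_q in [0.02, 0.05, 0.1]:
            assert rv.rate_at_od(od_q) == pytest.approx(0.5, abs=1e-9)

    def test_od_strictly_increasing_for_monotone_curve(self, gompertz_curve):
        rv = rate_vs_od(instantaneous_growth_rate(gompertz_curve))
        assert np.all(np.diff(rv.od) > 0)

    def test_query_at_sampled_od_returns_series_value(self, gompertz_curve):
        s = instantaneous_growth_rate(gompertz_curve)
        rv = rate_vs_od(s)
        k = len(rv.od) // 2
        assert rv.rate_at_od(float(rv.od[k])) == pytest.approx(rv.rate[k])

    def test_out_of_range_query_rejected(self, exponential_curve):
        rv = rate_vs_od(instantaneous_growth_rate(exponential_curve))
        with pytest.raises(OutOfRangeError):
            rv.rate_at_od(50.0)


class TestMaxGrowthRate:
    def test_exponential(self, exponential_curve):
        rate, _ = max_growth_rate(instantaneous_growth_rate(exponential_curve))
        assert rate == pytest.approx(0.5, abs=1e-9)

    def test_planted_gompertz_max_rate(self, gompertz_curve):
        rate, _ = max_growth_rate(instantaneous_growth_rate(gompertz_curve))
        assert rate == pytest.approx(0.82, rel=0.02)

    def test_equals_brute_force_max_over_pairs(self, gompertz_curve):
        s = instantaneous_growth_rate(gompertz_curve)
        rv = rate_vs_od(s)
        rate, _ = max_growth_rate(s)
        assert rate == pytest.approx(max(r for _, r in rv.pairs()))


class TestGompertzFit:
    def test_recovers_planted_parameters(self, gompertz_curve):
        fit = fit_gompertz(gompertz_curve)
        assert fit.converged
        assert fit.A == pytest.approx(0.5, rel=1e-3)
        assert fit.mu_max == pytest.approx(0.82, rel=1e-3)
        assert fit.lag == pytest.approx(2.0, rel=0.01)

    @pytest.mark.parametrize("A,mu,lag", [(0.3, 0.4, 1.0), (0.6, 1.2, 4.0)])
    def test_recovery_across_parameter_space(self, A, mu, lag):
        c = simulate_growth_curve(GrowthSimParams(A=A, mu_max=mu, lag=lag,
                                                  noise_cv=0.0, t_end=30.0))
        fit = fit_gompertz(c)
        assert fit.A == pytest.approx(A, rel=1e-3)
        assert fit.mu_max == pytest.approx(mu, rel=1e-3)

    def test_flat_curve_reports_zero_rate_unconverged(self):
        c = GrowthCurve(time=np.arange(10.0), od=np.full(10, 0.2))
        fit = fit_gompertz(c)
        assert fit.mu_max == 0.0
        assert not fit.converged

    def test_fitted_mu_max_consistent_with_rate_estimator(self, gompertz_curve):
        # self-consistency: the fitted curve, densely evaluated and pushed
        # through the rate estimator, returns the fitted mu_max
        fit = fit_gompertz(gompertz_curve)
        t = np.linspace(0.0, 24.0, 2001)
        dense = GrowthCurve(time=t, od=fit.predict(t))
        rate, _ = max_growth_rate(instantaneous_growth_rate(dense))
        assert rate == pytest.approx(fit.mu_max, rel=0.01)


class TestSaturationOD:
    def test_non_saturating_returns_final_od(self):
        t = np.linspace(0.0, 5.0, 20)
        c = GrowthCurve(time=t, od=0.05 + 0.1 * t)
        assert saturation_od(c) == pytest.approx(c.od[-1])

    def test_long_gompertz_returns_carrying_capacity(self):
        c = simulate_growth_curve(GrowthSimParams(A=0.5, mu_max=0.8, lag=2.0,
                                                  t_end=48.0, noise_cv=0.0))
        assert saturation_od(c) == pytest.approx(0.5, rel=0.01)

    def test_post_peak_decline_returns_maximum(self):
        t = np.linspace(0.0, 20.0, 81)
        od = 0.5 / (1 + np.exp(-(t - 5.0))) - 0.002 * np.maximum(t - 10, 0)
        c = GrowthCurve(time=t, od=od)
        assert saturation_od(c) == pytest.approx(float(od.max()))

    def test_never_exceeds_curve_maximum(self, gompertz_curve):
        assert saturation_od(gompertz_curve) <= gompertz_curve.od.max()


class TestRelativeFitness:
    def test_identity_gives_unit_fitness(self, gompertz_curve):
        res = relative_fitness(gompertz_curve, gompertz_curve)
        assert res.fitness == pytest.approx(1.0, abs=1e-12)

    def test_joint_scale_invariance(self, gompertz_curve):
        evolved = simulate_growth_curve(
            GrowthSimParams(A=0.6, mu_max=0.6, lag=2.0, noise_cv=0.0))
        base = relative_fitness(evolved, gompertz_curve)
        c = 3.7
        scaled = relative_fitness(
            GrowthCurve(time=evolved.time, od=c * evolved.od),
            GrowthCurve(time=gompertz_curve.time, od=c * gompertz_curve.od))
        assert scaled.fitness == pytest.approx(base.fitness, rel=1e-12)

    def test_matches_dense_grid_oracle(self):
        pe = GrowthSimParams(A=0.6, mu_max=0.6, lag=2.0, t_end=24.0,
                             noise_cv=0.0)
        pa = GrowthSimParams(A=0.45, mu_max=0.43, lag=3.0, t_end=24.0,
                             noise_cv=0.0)
        res = relative_fitness(simulate_growth_curve(pe),
                               simulate_growth_curve(pa))
        # brute force on a 1000x denser analytic resampling
        t = np.linspace(0.0, 24.0, 96 * 1000 + 1)
        ode = gompertz_od(t, pe.A, pe.mu_max, pe.lag, pe.inoculum)
        oda = gompertz_od(t, pa.A, pa.mu_max, pa.lag, pa.inoculum)
        od_max = ode.max()
        i = int(np.argmax(ode >= od_max / 2))
        fitness_oracle = (od_max / 2) / oda[i]
        assert res.fitness == pytest.approx(fitness_oracle, rel=5e-3)

    def test_unreached_level_raises_no_crossing(self):
        from osmofit.growth import _first_upward_crossing
        t = np.linspace(0.0, 10.0, 30)
        with pytest.raises(NoCrossingError):
            _first_upward_crossing(t, 0.1 + 0.01 * t, level=5.0)

    def test_ancestor_at_noise_floor_raises_division_guard(self, gompertz_curve):
        from osmofit.errors import DivisionGuardError
        anc = GrowthCurve(time=gompertz_curve.time,
                          od=np.full(len(gompertz_curve), 0.004))
        with pytest.raises(DivisionGuardError):
            relative_fitness(gompertz_curve, anc)

    @given(st.floats(min_value=0.1, max_value=10.0),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_self_fitness_is_one_for_random_monotone_curves(self, scale, seed):
        rng = np.random.default_rng(seed)
        od = 0.01 + np.cumsum(rng.uniform(0.001, 0.05, 30)) * scale
        c = GrowthCurve(time=np.arange(30.0) * 0.5, od=od)
        assert relative_fitness(c, c).fitness == pytest.approx(1.0, abs=1e-9)


class TestDetectShift:
    def test_monotone_rate_curve_yields_no_shift(self, exponential_curve):
        s = instantaneous_growth_rate(exponential_curve)
        assert not detect_shift(s).shifted

    def test_recovers_planted_post_shift_rate(self):
        d = DiauxicSimParams(
            phase1=GrowthSimParams(A=0.05, mu_max=0.8, lag=2.0, t_end=10.0,
                                   od0=0.005, noise_cv=0.0),
            phase2=GrowthSimParams(A=0.5, mu_max=0.5, lag=1.0, t_end=14.0,
                                   noise_cv=0.0),
            shift_pause=1.0)
        curve = simulate_diauxic_curve(d)
        res = detect_shift(instantaneous_growth_rate(curve))
        assert res.shifted
        assert res.post_max_rate == pytest.approx(0.5, rel=0.02)
        assert res.pre_max_rate >= res.rate_at_shift
        assert res.post_max_rate >= res.rate_at_shift
        # the dip sits at the constructed pause midpoint
        assert abs(res.t_shift - curve.meta["pause_mid"]) <= d.phase1.dt

    def test_matches_exhaustive_scan_oracle(self):
        t = np.linspace(0.0, 20.0, 101)
        rate = (0.6 * np.exp(-((t - 4) / 2.0) ** 2)
                + 0.5 * np.exp(-((t - 14) / 2.5) ** 2) + 0.01 * np.sin(3 * t))
        s = GrowthRateSeries(time=t, od=np.full_like(t, 0.2), rate=rate)
        res = detect_shift(s)
        prom = 0.10 * rate.max()
        best, best_r = None, np.inf
        for i in range(1, len(rate) - 1):
            if rate[i] <= rate[i - 1] and rate[i] <= rate[i + 1]:
                if (rate[:i].max() >= rate[i] + prom
                        and rate[i + 1:].max() >= rate[i] + prom
                        and rate[i] < best_r):
                    best, best_r = i, rate[i]
        assert res.shifted
        assert res.t_shift == pytest.approx(t[best])


class TestGenerations:
    def test_twofold_dilution_is_one_generation(self):
        assert generations_per_cycle(2.0) == pytest.approx(1.0)

    def test_hundredfold_dilution_rounds_to_6_6(self):
        assert round(generations_per_cycle(100.0), 1) == 6.6

    def test_38_cycles_approximate_250_generations(self):
        total = 38 * generations_per_cycle(100.0)
        assert total == pytest.approx(252.5, abs=0.1)

    def test_dilution_at_or_below_one_rejected(self):
        with pytest.raises(ParameterError):
            generations_per_cycle(1.0)
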