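"""Censoring correction, distribution estimation, and Euler-Lotka inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmgrowth import (
    DivisionEvent,
    ExperimentStatus,
    GenerationTimeDistribution,
    ObservationWindow,
    analyze_experiment,
    correction_factor,
    estimate_distribution,
    heterogeneity_stats,
    solve_growth_rate,
)
from mmgrowth.events import ExperimentRecord

from conftest import make_events


def grid_search_mu(tau, p, mu_max=10.0, step=1e-6):
    """Independent brute-force root of 1 = 2 sum f exp(-mu tau)."""
    mus = np.arange(step, mu_max, step)
    g = 2.0 * (p[None, :] * np.exp(-np.outer(mus, tau))).sum(axis=1) - 1.0
    return mus[np.argmin(np.abs(g))]


class TestCorrectionFactor:
    def test_vanishing_tau_limit(self, window25):
        assert correction_factor(1e-9, window25) == pytest.approx(1.0)

    def test_hand_value(self, window25):
        # observable span for tau = 5 h in a 25 h window is 20 h
        assert correction_factor(5.0, window25) == pytest.approx(25.0 / 20.0)

    def test_domain_error_at_window_length(self, window25):
        with pytest.raises(ValueError):
            correction_factor(25.0, window25)

    def test_nonpositive_tau_rejected(self, window25):
        with pytest.raises(ValueError):
            correction_factor(0.0, window25)

    @given(st.floats(0.01, 24.9), st.floats(0.01, 24.9))
    def test_strictly_increasing(self, a, b):
        w = ObservationWindow(0.0, 25.0)
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert correction_factor(lo, w) < correction_factor(hi, w)


class TestEstimateDistribution:
    def test_point_mass(self, window25):
        dist = estimate_distribution(make_events([2.0] * 8), window25)
        assert dist.tau_values.tolist() == [2.0]
        assert dist.probabilities.tolist() == [1.0]

    def test_correction_favors_long_tau(self, window25):
        dist = estimate_distribution(
            make_events([2.0] * 10 + [10.0] * 10), window25
        )
        p = dict(zip(dist.tau_values, dist.probabilities))
        assert p[10.0] > p[2.0]

    def test_hand_computed_weights(self, window25):
        # weights 25/20 = 1.25 and 25/10 = 2.5 -> 12.5 : 25 -> 1/3 : 2/3
        dist = estimate_distribution(
            make_events([5.0] * 10 + [15.0] * 10), window25
        )
        assert dist.probabilities == pytest.approx([1.0 / 3.0, 2.0 / 3.0])

    def test_empty_input_instructs_classification(self, window25):
        with pytest.raises(ValueError, match="classify"):
            estimate_distribution([], window25)

    def test_normalization_exact(self, window25, rng):
        taus = (rng.integers(1, 200, size=500) * window25.delta_tau).tolist()
        dist = estimate_distribution(make_events(taus), window25)
        assert abs(dist.probabilities.sum() - 1.0) <= 1e-12

    def test_prefactor_invariance(self, window25):
        # any tau-independent prefactor on the weights cancels on
        # normalization: recompute f with weights 1/(L - tau) directly
        taus = [2.0] * 5 + [7.0] * 3 + [12.0] * 2
        dist = estimate_distribution(make_events(taus), window25)
        L = window25.length
        raw = np.array([5 / (L - 2.0), 3 / (L - 7.0), 2 / (L - 12.0)])
        assert dist.probabilities == pytest.approx(raw / raw.sum(), abs=1e-14)

    def test_rebinning(self, window25):
        dist = estimate_distribution(
            make_events([1.0, 1.25, 2.0, 2.25]), window25, rebin_width=1.0
        )
        assert dist.tau_values.tolist() == [1.0, 2.0]


class TestSolveGrowthRate:
    def test_point_mass_doubling(self, window25):
        d = GenerationTimeDistribution(np.array([1.0]), np.array([1.0]), window25)
        assert solve_growth_rate(d) == pytest.approx(math.log(2.0), abs=1e-9)

    def test_point_mass_two_hours(self, window25):
        d = GenerationTimeDistribution(np.array([2.0]), np.array([1.0]), window25)
        assert solve_growth_rate(d) == pytest.approx(math.log(2.0) / 2.0, abs=1e-9)

    def test_two_point_closed_form(self, window25):
        # 1 = e^{-mu} + e^{-2mu}  =>  x^2 + x - 1 = 0 with x = e^{-mu}
        d = GenerationTimeDistribution(
            np.array([1.0, 2.0]), np.array([0.5, 0.5]), window25
        )
        expected = -math.log((math.sqrt(5.0) - 1.0) / 2.0)
        assert solve_growth_rate(d) == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_grid_search_oracle(self, seed, window25):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        tau = np.sort(rng.uniform(0.5, 8.0, size=k))
        tau += np.arange(k) * 1e-3  # ensure strictly increasing
        p = rng.dirichlet(np.ones(k))
        d = GenerationTimeDistribution(tau, p / p.sum(), window25)
        mu = solve_growth_rate(d)
        assert mu == pytest.approx(grid_search_mu(tau, p / p.sum()), abs=1e-5)
        # residual at the solution is zero to solver precision
        resid = 2.0 * np.sum(p / p.sum() * np.exp(-mu * tau)) - 1.0
        assert abs(resid) < 1e-10

    def test_degenerate_distribution_rejected(self, window25):
        with pytest.raises(ValueError):
            GenerationTimeDistribution(
                np.array([1.0, 2.0]), np.array([0.7, 0.7]), window25
            )


class TestHeterogeneityStats:
    def test_point_mass(self, window25):
        d = GenerationTimeDistribution(np.array([3.0]), np.array([1.0]), window25)
        mean, var, cv = heterogeneity_stats(d)
        assert (mean, var, cv) == (3.0, 0.0, 0.0)

    def test_two_point_moments(self, window25):
        d = GenerationTimeDistribution(
            np.array([1.0, 3.0]), np.array([0.5, 0.5]), window25
        )
        mean, var, cv = heterogeneity_stats(d)
        assert mean == pytest.approx(2.0)
        assert var == pytest.approx(1.0)
        assert cv == pytest.approx(0.5)


class TestAnalyzeExperiment:
    def test_few_events_marked_zero_growth(self, default_window):
        rec = ExperimentRecord("E", 100.0, make_events([2.0] * 4, birth=16.0))
        res = analyze_experiment(rec, default_window)
        assert res.status is ExperimentStatus.ZERO_GROWTH
        assert res.mu == 0.0

    def test_intermediate_count_excluded_without_mu(self, default_window):
        rec = ExperimentRecord("E", 20.0, make_events([2.0] * 30, birth=16.0))
        res = analyze_experiment(rec, default_window)
        assert res.status is ExperimentStatus.EXCLUDED
        assert res.mu is None

    def test_composition_point_mass(self, default_window):
        rec = ExperimentRecord("E", 6.0, make_events([1.0] * 200, birth=16.0))
        res = analyze_experiment(rec, default_window)
        assert res.status is ExperimentStatus.ANALYZED
        assert res.mu == pytest.approx(math.log(2.0), abs=1e-9)
        assert res.mean_tau == pytest.approx(1.0)
        assert res.var_tau == 0.0

    def test_filter_applied_before_classification(self, default_window):
        # 60 events but all born before t_start -> zero growth
        rec = ExperimentRecord("E", 6.0, make_events([2.0] * 60, birth=5.0))
        res = analyze_experiment(rec, default_window)
        assert res.status is ExperimentStatus.ZERO_GROWTH
        assert res.n_events == 0


class TestJensenBound:
    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_mu_times_mean_tau_at_least_ln2(self, seed):
        rng = np.random.default_rng(seed)
        window = ObservationWindow(0.0, 25.0)
        k = int(rng.integers(1, 6))
        tau = np.sort(rng.uniform(0.5, 10.0, size=k)) + np.arange(k) * 1e-3
        p = rng.dirichlet(np.ones(k))
        d = GenerationTimeDistribution(tau, p / p.sum(), window)
        mu = solve_growth_rate(d)
        mean, var, _ = heterogeneity_stats(d)
        assert mu * mean >= math.log(2.0) - 1e-9
        if var < 1e-12:
            assert mu * mean == pytest.approx(math.log(2.0), abs=1e-9)
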