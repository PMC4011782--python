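"""Synthetic register generator: determinism, coverage, distributional checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, poisson

from hiddenpop import (
    ParameterError,
    SimulationConfig,
    capture_histogram,
    coverage_to_p,
    epoch_counts,
    load_events,
    simulate_registry,
    simulate_sufficient_stats,
)
from hiddenpop.simulate import stats_to_epoch_counts, stats_to_histogram


class TestCoverageToP:
    def test_yearly_exemplar(self):
        # 30% yearly coverage under daily observation: p ~ 0.001, lambda ~ 0.36
        p = coverage_to_p(0.3, 365)
        assert round(p, 3) == 0.001
        assert 365 * p == pytest.approx(0.36, abs=0.005)

    def test_single_step_identity(self):
        assert coverage_to_p(0.4, 1) == pytest.approx(0.4)

    @pytest.mark.parametrize("c", [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
    def test_round_trip(self, c):
        p = coverage_to_p(c, 512)
        assert 1 - (1 - p) ** 512 == pytest.approx(c, abs=1e-12)

    @pytest.mark.parametrize("c", [0.0, 1.0, -0.1])
    def test_boundary_rejected(self, c):
        with pytest.raises(ParameterError):
            coverage_to_p(c, 100)


class TestConfig:
    def test_p1_and_coverage_mutually_exclusive(self):
        with pytest.raises(ParameterError):
            SimulationConfig(N=10, p1=0.1, target_coverage=0.5)
        with pytest.raises(ParameterError):
            SimulationConfig(N=10)

    def test_coverage_resolves_p1(self):
        config = SimulationConfig(N=10, T=365, target_coverage=0.3)
        assert config.p1_resolved == pytest.approx(coverage_to_p(0.3, 365))


class TestSimulateRegistry:
    def test_zero_probability_gives_empty_register(self):
        table = simulate_registry(SimulationConfig(N=100, T=50, p1=0.0, seed=1))
        assert table.n_events == 0 and table.T == 50

    def test_seed_determinism(self):
        config = SimulationConfig(N=200, T=64, p1=0.02, seed=99)
        a = simulate_registry(config).events
        b = simulate_registry(config).events
        pd.testing.assert_frame_equal(a, b)

    def test_coverage_matches_target(self):
        N = 10_000
        config = SimulationConfig(N=N, T=512, target_coverage=0.5, seed=4)
        frac = simulate_registry(config).n_persons / N
        se = np.sqrt(0.5 * 0.5 / N)
        assert abs(frac - 0.5) < 3 * se

    def test_event_counts_fit_poisson_approximation(self):
        # memoryless regime: per-person counts ~ Binomial(T, p1) ~ Poisson(0.36)
        lam = 0.36
        N = 10_000
        config = SimulationConfig(N=N, T=512, p1=lam / 512, seed=8)
        hist = capture_histogram(simulate_registry(config))
        observed = np.array([N - hist.observed_total, hist[1], hist[2],
                             sum(c for j, c in hist.h.items() if j >= 3)])
        probs = [poisson.pmf(0, lam), poisson.pmf(1, lam), poisson.pmf(2, lam),
                 poisson.sf(2, lam)]
        stat, pval = chisquare(observed, N * np.array(probs))
        assert pval > 0.01

    def test_exchangeability_of_person_labels(self):
        config = SimulationConfig(N=300, T=64, p1=0.02, seed=12)
        table = simulate_registry(config)
        shuffled = table.events.copy()
        rng = np.random.default_rng(0)
        mapping = dict(
            zip(
                shuffled["person_id"].unique(),
                rng.permutation(shuffled["person_id"].unique()),
            )
        )
        shuffled["person_id"] = shuffled["person_id"].map(mapping)
        relabeled = type(table)(events=shuffled.sort_values(
            ["person_id", "time"], ignore_index=True), T=table.T)
        assert epoch_counts(relabeled, M=4).counts == epoch_counts(table, M=4).counts
        assert capture_histogram(relabeled).h == capture_histogram(table).h

    def test_first_epoch_count_matches_binomial_moments(self):
        # homogeneous memoryless case: n_1 ~ Binomial(N, 1-(1-p1)^d)
        N, T, M, p1 = 500, 64, 4, 0.02
        d = T // M
        p_epoch = 1 - (1 - p1) ** d
        n1 = []
        for seed in range(300):
            table = simulate_registry(SimulationConfig(N=N, T=T, p1=p1, seed=seed))
            n1.append(epoch_counts(table, M=M).counts[0])
        n1 = np.array(n1)
        mean, var = N * p_epoch, N * p_epoch * (1 - p_epoch)
        assert n1.mean() == pytest.approx(mean, abs=3 * np.sqrt(var / len(n1)))
        assert n1.var(ddof=1) == pytest.approx(var, rel=0.35)

    def test_round_trip_through_csv(self, tmp_path, small_registry):
        path = tmp_path / "sim.csv"
        small_registry.to_csv(path)
        back = load_events(path, T=small_registry.T)
        pd.testing.assert_frame_equal(back.events, small_registry.events)

    def test_heterogeneity_draws_are_clipped(self):
        # sd much larger than mean: some individuals get p=0 yet nothing crashes
        config = SimulationConfig(
            N=2000, T=32, p1=0.01, heterogeneity_sd=0.05, seed=2
        )
        table = simulate_registry(config)
        assert table.n_persons < 2000  # clipped-to-zero individuals are unobservable


class TestSufficientStatsPath:
    def test_matches_full_simulator_distribution(self):
        """The O(N) path and the event-table path share the same law."""
        config = SimulationConfig(N=400, T=64, p1=0.02, p2_factor=0.5)
        full_n1, fast_n1, full_events, fast_events = [], [], [], []
        for seed in range(200):
            table = simulate_registry(config.with_seed(seed))
            full_n1.append(epoch_counts(table, M=4).counts[0])
            full_events.append(table.n_events)
            first, counts = simulate_sufficient_stats(config.with_seed(10_000 + seed))
            fast_n1.append(stats_to_epoch_counts(first, 64, 4).counts[0])
            fast_events.append(counts.sum())
        # means agree within Monte Carlo error on both statistics
        for a, b in [(full_n1, fast_n1), (full_events, fast_events)]:
            a, b = np.array(a, float), np.array(b, float)
            se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
            assert abs(a.mean() - b.mean()) < 4 * se

    def test_histogram_mass(self):
        first, counts = simulate_sufficient_stats(
            SimulationConfig(N=500, T=64, p1=0.03, seed=3)
        )
        hist = stats_to_histogram(counts)
        assert hist.observed_total == len(first)
        assert hist.n_events == counts.sum()
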