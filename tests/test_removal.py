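"""Removal maximum-likelihood estimator: worked examples, oracle, properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from hiddenpop import (
    EpochCounts,
    ParameterError,
    RemovalModel,
    closed_form_m2,
    existence_check,
    maximize_removal,
    removal_loglik,
)


def stirling_loglik_grid(counts, N_grid, p_grid):
    """Independent brute-force evaluation of the removal log-likelihood.

    Evaluates s*log(p) + N*log(N) + A*log(1-p) - (N-s)*log(N-s), with A
    the total (1-p) exponent of the conditional binomial chain, on the
    outer grid N_grid x p_grid, directly from the formula.
    """
    n = np.asarray(counts, dtype=float)
    M, s = len(n), n.sum()
    cum = np.cumsum(n)
    N = np.asarray(N_grid, dtype=float)[:, None]
    p = np.asarray(p_grid, dtype=float)[None, :]
    A = M * N - cum.sum()
    rem = N - s
    with np.errstate(divide="ignore", invalid="ignore"):
        rlogr = np.where(rem > 0, rem * np.log(np.where(rem > 0, rem, 1.0)), 0.0)
        return s * np.log(p) + N * np.log(N) + A * np.log1p(-p) - rlogr


class TestWorkedExamples:
    def test_raster_figure_counts_give_49(self, fig1_counts):
        res = maximize_removal(fig1_counts)
        assert res.valid
        assert res.N_hat_rounded == 49
        assert 0 < res.nuisance < 1

    def test_m2_closed_form_value(self):
        res = closed_form_m2(19, 10)
        assert res.N_hat == pytest.approx(361 / 9)
        assert res.nuisance == pytest.approx(9 / 19)

    def test_m2_all_caught_first_epoch(self):
        res = closed_form_m2(40, 0)
        assert res.N_hat == 40 and res.nuisance == 1.0

    def test_m2_near_flat_catch_explodes(self):
        assert closed_form_m2(100, 99).N_hat == pytest.approx(10_000)

    def test_equal_counts_invalid(self):
        res = maximize_removal(EpochCounts((10, 10)))
        assert not res.valid
        assert res.N_hat_rounded is None
        assert "X/s" in res.message


class TestExistence:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((19, 10, 8), True),   # X/s = 26/37 < 1
            ((10, 10), False),     # boundary: X/s = 1/2 = (M-1)/2
            ((8, 10, 19), False),  # increasing catches, X/s = 48/37 > 1
            ((5, 0), True),
        ],
    )
    def test_solvability_condition(self, counts, expected):
        ok, reason = existence_check(EpochCounts(counts))
        assert ok is expected
        assert ok or reason

    def test_no_observations(self):
        ok, reason = existence_check(EpochCounts((0, 0, 0)))
        assert not ok and reason == "no observations"


class TestLoglik:
    def test_exact_form_reduces_to_binomial_at_m1(self):
        # one epoch: the chain is a single Binomial(N, p) pmf
        model = RemovalModel(EpochCounts((7,)))
        for N, p in [(20, 0.3), (55, 0.12)]:
            assert model.loglike(N, p, form="exact") == pytest.approx(
                binom.logpmf(7, N, p)
            )

    def test_unimodal_in_N_for_fixed_p(self, fig1_counts):
        s = fig1_counts.s
        N_grid = np.linspace(s, 10 * s, 2000)
        L = np.array([removal_loglik(N, 0.37, fig1_counts) for N in N_grid])
        signs = np.sign(np.diff(L))
        # increasing then decreasing: exactly one sign change
        assert (np.diff(signs[signs != 0]) != 0).sum() == 1

    def test_domain_errors(self, fig1_counts):
        with pytest.raises(ParameterError):
            removal_loglik(10, 0.5, fig1_counts)  # N < s
        with pytest.raises(ParameterError):
            removal_loglik(50, 1.5, fig1_counts)


class TestOptimizerAgainstOracle:
    def test_grid_oracle_on_raster_counts(self, fig1_counts):
        res = maximize_removal(fig1_counts)
        s = fig1_counts.s
        N_grid = np.linspace(s + 1e-9, 20 * s, 600)
        p_grid = np.linspace(0.005, 0.995, 300)
        grid_max = stirling_loglik_grid(fig1_counts.counts, N_grid, p_grid).max()
        fitted = removal_loglik(res.N_hat, res.nuisance, fig1_counts, form="stirling")
        assert fitted >= grid_max - 1e-9

    def test_optimizer_dominates_grid_on_random_counts(self):
        rng = np.random.default_rng(42)
        tried = 0
        while tried < 50:
            M = int(rng.integers(2, 7))
            counts = EpochCounts(tuple(int(x) for x in rng.integers(0, 40, M)))
            if counts.s == 0 or counts.s > 200 or not existence_check(counts)[0]:
                continue
            tried += 1
            res = maximize_removal(counts)
            assert res.valid
            N_grid = np.linspace(counts.s + 1e-9, 20 * counts.s, 300)
            p_grid = np.linspace(0.005, 0.995, 200)
            grid_max = stirling_loglik_grid(counts.counts, N_grid, p_grid).max()
            fitted = removal_loglik(res.N_hat, res.nuisance, counts, form="stirling")
            assert fitted >= grid_max - 1e-9, counts.counts

    def test_score_identity(self):
        # stationarity in N: N_hat * (1 - (1-p_hat)^M) = s
        for counts in [(19, 10, 8), (30, 22, 15, 9), (100, 40)]:
            res = maximize_removal(EpochCounts(counts))
            s = sum(counts)
            M = len(counts)
            assert res.N_hat * (1 - (1 - res.nuisance) ** M) == pytest.approx(
                s, rel=1e-9
            )


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    n1=st.integers(min_value=1, max_value=10_000),
    frac=st.floats(min_value=0.0, max_value=0.999),
)
def test_m2_profile_matches_closed_form(n1, frac):
    """For M=2 the profile root-find reproduces n1^2/(n1-n2) exactly."""
    n2 = int(frac * n1)
    assert n2 < n1
    numeric = maximize_removal(EpochCounts((n1, n2)))
    closed = closed_form_m2(n1, n2)
    assert numeric.valid and closed.valid
    assert numeric.N_hat == pytest.approx(closed.N_hat, rel=1e-6)
    assert numeric.nuisance == pytest.approx(closed.nuisance, rel=1e-6)


def test_estimate_never_below_observed():
    rng = np.random.default_rng(7)
    for _ in range(100):
        M = int(rng.integers(2, 9))
        counts = EpochCounts(tuple(int(x) for x in rng.integers(0, 30, M)))
        if counts.s == 0:
            continue
        res = maximize_removal(counts)
        if res.valid:
            assert res.N_hat >= counts.s - 1e-9
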