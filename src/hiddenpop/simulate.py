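"""Synthetic register generator.

Emulates the data-generating process the estimators assume, plus the two
violations whose effect the evaluation harness quantifies:

* a closed population of ``N`` individuals observed over ``T`` discrete
  time-steps (default 512, e.g. days over ~1.4 years);
* each individual i carries a per-step first-registration probability
  ``p_i``, either the common value ``p1`` or, with ``heterogeneity_sd``
  > 0, drawn once per individual from Normal(p1, sd) clipped to [0, 1]
  (so strongly heterogeneous populations may contain unobservable,
  zero-probability individuals);
* before first registration the individual is registered at each step
  with probability ``p_i``; afterwards with ``p2_factor * p_i`` (clipped).
  ``p2_factor = 1`` is the memoryless Poisson-like regime;
  ``p2_factor = 1/k`` reproduces the "registration discourages
  re-registration" regime, ``p2_factor > 1`` the opposite.

What the generator deliberately omits: open-population turnover
(entries/exits), reporting delays, and same-day duplicate administrative
rows -- real registers have all three.

The per-step Bernoulli process is sampled exactly but in a vectorized
two-phase form: the first-registration time is the number of failures of
a geometric trial (inverse-CDF from one uniform per individual), and the
subsequent steps are i.i.d. Bernoulli(p2_i).  For evaluation at scale,
:func:`simulate_sufficient_stats` draws only the first-registration time
and a Binomial count of re-registrations -- the same joint law restricted
to the statistics the estimators use -- without materializing event rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .registry import CaptureHistogram, EpochCounts, EventTable

__all__ = [
    "SimulationConfig",
    "coverage_to_p",
    "simulate_registry",
    "simulate_sufficient_stats",
    "expected_capture_frequencies",
]


def coverage_to_p(coverage: float, T: int) -> float:
    """Per-step probability giving a target whole-window coverage.

    Solves ``1 - (1 - p)^T = coverage`` for p, i.e. the fraction of the
    population registered at least once over T steps equals ``coverage``
    in expectation.  E.g. coverage 0.3 over a year of daily observation
    (T=365) gives p ~ 0.001 and a Poisson rate lambda = T*p ~ 0.36.
    """
    if not (0.0 < coverage < 1.0):
        raise ParameterError(f"coverage must be in (0, 1), got {coverage}")
    if T < 1:
        raise ParameterError(f"T must be >= 1, got {T}")
    return -np.expm1(np.log1p(-coverage) / T)


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario description for the synthetic register.

    Exactly one of ``p1`` and ``target_coverage`` must be given; with
    ``target_coverage`` the per-step probability is derived via
    :func:`coverage_to_p`.
    """

    N: int
    T: int = 512
    p1: float | None = None
    target_coverage: float | None = None
    heterogeneity_sd: float = 0.0
    p2_factor: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ParameterError(f"N must be non-negative, got {self.N}")
        if self.T < 1:
            raise ParameterError(f"T must be >= 1, got {self.T}")
        if (self.p1 is None) == (self.target_coverage is None):
            raise ParameterError("give exactly one of p1 and target_coverage")
        if self.p1 is not None and not (0.0 <= self.p1 <= 1.0):
            raise ParameterError(f"p1 must be in [0, 1], got {self.p1}")
        if self.heterogeneity_sd < 0:
            raise ParameterError("heterogeneity_sd must be non-negative")
        if self.p2_factor < 0:
            raise ParameterError("p2_factor must be non-negative")
        if self.N * self.T > 5e9:
            raise ParameterError(
                f"N*T = {self.N * self.T:.2g} exceeds the simulator guard"
            )

    @property
    def p1_resolved(self) -> float:
        if self.p1 is not None:
            return float(self.p1)
        return float(coverage_to_p(self.target_coverage, self.T))

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "T": self.T,
            "p1": self.p1_resolved,
            "target_coverage": self.target_coverage,
            "heterogeneity_sd": self.heterogeneity_sd,
            "p2_factor": self.p2_factor,
            "seed": self.seed,
        }


def _per_individual_probs(config: SimulationConfig, rng: np.random.Generator):
    """Draw (p_first, p_after) per individual, clipped to [0, 1]."""
    p1 = config.p1_resolved
    if config.heterogeneity_sd > 0:
        p_first = np.clip(
            rng.normal(p1, config.heterogeneity_sd, size=config.N), 0.0, 1.0
        )
    else:
        p_first = np.full(config.N, p1)
    p_after = np.clip(p_first * config.p2_factor, 0.0, 1.0)
    return p_first, p_after


def _first_times(p_first: np.ndarray, T: int, rng: np.random.Generator):
    """Inverse-CDF geometric first-registration step; T means 'never'."""
    u = rng.random(p_first.shape)
    t = np.full(p_first.shape, T, dtype=np.int64)
    pos = p_first > 0
    with np.errstate(divide="ignore"):
        # number of failures before first success
        fails = np.floor(np.log(u[pos]) / np.log1p(-np.minimum(p_first[pos], 1 - 1e-16)))
    t[pos] = np.minimum(fails.astype(np.int64), T)
    t[p_first >= 1.0] = 0
    return t


def simulate_registry(config: SimulationConfig) -> EventTable:
    """Generate a full synthetic register as an :class:`EventTable`.

    All registration events are emitted (first and subsequent), one row
    per (person, time-step).  Identical config and seed give identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    N, T = config.N, config.T
    p_first, p_after = _per_individual_probs(config, rng)
    t_first = _first_times(p_first, T, rng)
    reg = np.flatnonzero(t_first < T)

    persons: list[str] = []
    times: list[int] = []
    width = max(6, len(str(max(N - 1, 0))))
    ids = np.array([f"p{i:0{width}d}" for i in range(N)])
    # phase 2: i.i.d. Bernoulli(p_after) on the steps after first registration,
    # drawn as one uniform block over the registered sub-population
    if reg.size:
        u = rng.random((reg.size, T))
        step = np.arange(T)
        hits = (u < p_after[reg, None]) & (step[None, :] > t_first[reg, None])
        rows, cols = np.nonzero(hits)
        persons.extend(ids[reg].tolist())
        times.extend(t_first[reg].tolist())
        persons.extend(ids[reg[rows]].tolist())
        times.extend(cols.tolist())
    events = pd.DataFrame({"person_id": persons, "time": pd.array(times, dtype=int)})
    events = events.sort_values(["person_id", "time"], ignore_index=True)
    return EventTable(events=events, T=T)


def simulate_sufficient_stats(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw only the statistics the estimators use, at O(N) cost.

    Returns
    -------
    first_times : ndarray of int
        First-registration step of each *registered* individual (sorted
        by individual index), each in ``[0, T)``.
    total_counts : ndarray of int
        Total number of registrations (>= 1) of the same individuals; the
        re-registration count is Binomial(T - 1 - t_first, p_after), the
        exact law of the per-step Bernoulli phase-2 process.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T = config.T
    p_first, p_after = _per_individual_probs(config, rng)
    t_first = _first_times(p_first, T, rng)
    reg = t_first < T
    t = t_first[reg]
    extra = rng.binomial(T - 1 - t, p_after[reg])
    return t, 1 + extra


def stats_to_epoch_counts(first_times: np.ndarray, T: int, M: int) -> EpochCounts:
    """Bin first-registration times into M equal epochs (no burn-in)."""
    if M < 2:
        raise ParameterError(f"need M >= 2, got {M}")
    if T < M:
        raise ParameterError(f"T={T} cannot hold {M} epochs")
    d = T // M
    kept = first_times[first_times < M * d]
    counts = np.bincount(kept // d, minlength=M)
    return EpochCounts(counts=tuple(int(c) for c in counts), d=d)


def stats_to_histogram(total_counts: np.ndarray) -> CaptureHistogram:
    """Capture-frequency histogram from per-person registration counts."""
    if total_counts.size == 0:
        return CaptureHistogram(h={})
    j, c = np.unique(total_counts, return_counts=True)
    return CaptureHistogram(h=dict(zip(j.tolist(), c.tolist())))


def expected_capture_frequencies(
    N: int, T: int, p1: float, p2: float, j_max: int = 10
) -> dict[int, float]:
    """Exact expected frequencies E(h_j) under the two-phase process.

    Conditioning on the first-registration step t (geometric in p1,
    truncated at T), the re-registration count is Binomial(T-1-t, p2), so

        E(h_j) = N * sum_t (1-p1)^t p1 * P(Bin(T-1-t, p2) = j-1),   j >= 1
        E(h_0) = N * (1-p1)^T.

    Used as the brute-force oracle for the systematic bias of the
    truncated-Poisson estimators when p2 != p1 (in the small-p1 limit
    with p2 = p1/k, E(h_1)^2 / (2 E(h_2)) -> k*N).
    """
    from scipy.stats import binom

    t = np.arange(T)
    w = (1.0 - p1) ** t * p1  # P(first registration at step t)
    out = {0: float(N * (1.0 - p1) ** T)}
    for j in range(1, j_max + 1):
        pmf = binom.pmf(j - 1, T - 1 - t, p2)
        out[j] = float(N * np.sum(w * pmf))
    return out
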