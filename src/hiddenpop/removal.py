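"""Removal (capture-and-remove) maximum-likelihood estimation of N.

The observation window is divided into M equal epochs and ``n_j`` counts
the previously unregistered persons first appearing in epoch j.  Under a
closed population of size N in which every not-yet-registered person is
registered within an epoch with probability p, the counts form a
conditional binomial chain::

    n_j | n_1..n_{j-1}  ~  Binomial(N - sum_{i<j} n_i,  p)

Maximizing the joint likelihood in (N, p) is the classical removal
(Zippin) estimator.  Writing q = 1 - p, s = sum n_j and
X = sum (j-1) n_j, the two score equations reduce to a single profile
equation in q,

    q/(1-q) - M q^M / (1 - q^M)  =  X / s,

whose left side increases from 0 at q=0 to (M-1)/2 at q=1.  A root --
and hence the ML estimate -- exists iff X/s < (M-1)/2 (for M=2 this is
the familiar condition n_1 > n_2), and then

    N_hat = s / (1 - q^M),        p_hat = 1 - q.

The profile equation is solved by safeguarded bracketing on [0, 1] using
a cancellation-free polynomial form of the left side, so the solver
cannot diverge regardless of starting point.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .errors import EstimationError, ParameterError
from .registry import EpochCounts
from .results import EstimateResult

__all__ = [
    "RemovalModel",
    "RemovalResults",
    "removal_loglik",
    "maximize_removal",
    "closed_form_m2",
    "existence_check",
]


def _profile_lhs(q: float, M: int) -> float:
    """Left side of the profile score equation, evaluated stably on [0, 1].

    Uses the identity
        q/(1-q) - M q^M/(1-q^M)
            = (sum_{i=1}^{M-1} q^i S_{M-i}) / S_M,
    with S_k = 1 + q + ... + q^{k-1}, which involves no subtraction and is
    exact at both endpoints (0 at q=0, (M-1)/2 at q=1).
    """
    powers = q ** np.arange(M, dtype=float)
    S = np.cumsum(powers)  # S[k-1] = S_k
    num = 0.0
    for i in range(1, M):
        num += powers[i] * S[M - i - 1]
    return num / S[M - 1]


def _geom_sum(q: float, M: int) -> float:
    """1 + q + ... + q^{M-1}  (= (1-q^M)/(1-q), stable near q=1)."""
    return float(np.sum(q ** np.arange(M, dtype=float)))


class RemovalModel:
    """Removal-sampling model for epoch first-registration counts.

    Parameters
    ----------
    counts : EpochCounts
        The sufficient statistic ``n_1..n_M`` (M >= 2).

    Examples
    --------
    >>> from hiddenpop import EpochCounts, RemovalModel
    >>> res = RemovalModel(EpochCounts((19, 10, 8))).fit()
    >>> res.N_hat_rounded
    49
    """

    def __init__(self, counts: EpochCounts):
        # M=1 is allowed for likelihood evaluation (a single binomial);
        # estimation itself requires M >= 2 and is guarded in fit().
        self.counts = counts

    @classmethod
    def from_events(cls, events, M: int, burn_in: int = 0) -> "RemovalModel":
        """Build the model directly from an :class:`EventTable`."""
        from .registry import epoch_counts

        return cls(epoch_counts(events, M=M, burn_in=burn_in))

    # -- likelihood ---------------------------------------------------

    def loglike(self, N: float, p: float, form: str = "exact") -> float:
        """Log-likelihood of (N, p) given the epoch counts.

        ``form="exact"`` evaluates the product-binomial chain exactly via
        log-gamma functions (valid for real N >= s).  ``form="stirling"``
        uses the n! ~ n log n - n approximation, i.e. the objective whose
        stationary point the profile score equation solves exactly; both
        forms differ only by O(1/N) in the location of the maximum.
        """
        c = self.counts
        n = np.asarray(c.counts, dtype=float)
        s, M = c.s, c.M
        if N < s:
            raise ParameterError(f"N={N} below observed total s={s}")
        if not (0.0 < p <= 1.0):
            raise ParameterError(f"p={p} outside (0, 1]")
        cum = np.cumsum(n)
        # A = sum_i (N - cum_i): total exponent of (1 - p).  p = 1 is the
        # boundary optimum when everyone is caught in the first epoch; it
        # has finite likelihood only when A = 0.
        A = M * N - cum.sum()
        if p == 1.0:
            tail = 0.0 if A == 0 else -math.inf
        else:
            tail = A * math.log1p(-p)
        if form == "exact":
            return float(
                gammaln(N + 1.0)
                - gammaln(N - s + 1.0)
                - gammaln(n + 1.0).sum()
                + s * math.log(p)
                + tail
            )
        if form == "stirling":
            nlogn = N * math.log(N) if N > 0 else 0.0
            rem = N - s
            rlogr = rem * math.log(rem) if rem > 0 else 0.0
            return float(s * math.log(p) + nlogn + tail - rlogr)
        raise ParameterError(f"unknown likelihood form {form!r}")

    # -- existence ----------------------------------------------------

    def existence_check(self) -> tuple[bool, str]:
        """Whether the ML estimate exists for these counts.

        The profile score has a root iff ``X/s < (M-1)/2`` where
        ``X = sum (j-1) n_j``; equality (e.g. n_1 = n_2 at M=2) is the
        degenerate boundary and counts as nonexistence.
        """
        c = self.counts
        if c.s == 0:
            return False, "no observations"
        X = c.removals_weighted
        bound = (c.M - 1) / 2.0
        ratio = X / c.s
        if ratio < bound:
            return True, ""
        return False, (
            f"removal condition violated: X/s = {X}/{c.s} = {ratio:.4f} "
            f">= (M-1)/2 = {bound:.4f}; epoch counts do not decline enough"
        )

    # -- fitting ------------------------------------------------------

    def fit(self, xtol: float = 1e-12) -> "RemovalResults":
        """Maximize the removal likelihood by profile root finding.

        Solves the profile score equation in q = 1 - p by Brent bracketing
        on [0, 1] (monotone left side, so the bracket is guaranteed), then
        recovers ``N_hat = s / (1 - q^M)``.
        """
        c = self.counts
        if c.M < 2:
            raise ParameterError("removal estimation requires M >= 2 epochs")
        ok, reason = self.existence_check()
        if not ok:
            return RemovalResults(
                model=self, method="removal-ml", valid=False, message=reason
            )
        s, M, X = c.s, c.M, c.removals_weighted
        if X == 0:
            # every person caught in the first epoch: q=0, p=1, N=s
            return RemovalResults(
                model=self,
                method="removal-ml",
                N_hat=float(s),
                nuisance=1.0,
                diagnostics={"q_hat": 0.0, "score_residual": 0.0, "iterations": 0},
            )
        R = X / s
        g = lambda q: _profile_lhs(q, M) - R
        try:
            q_hat, info = brentq(g, 0.0, 1.0, xtol=xtol, full_output=True)
        except (ValueError, RuntimeError) as exc:  # pragma: no cover - safeguarded
            raise EstimationError(
                f"profile root finder failed on [0,1] for counts {c.counts}: {exc}"
            ) from exc
        if not info.converged:  # pragma: no cover
            raise EstimationError(
                f"profile root finder did not converge: {info.flag}"
            )
        one_minus_qM = (1.0 - q_hat) * _geom_sum(q_hat, M)
        N_hat = s / one_minus_qM
        return RemovalResults(
            model=self,
            method="removal-ml",
            N_hat=float(N_hat),
            nuisance=float(1.0 - q_hat),
            diagnostics={
                "q_hat": float(q_hat),
                "score_residual": float(g(q_hat)),
                "iterations": int(info.iterations),
            },
        )


class RemovalResults(EstimateResult):
    """Fit results of :class:`RemovalModel`.

    Inherits the :class:`~hiddenpop.results.EstimateResult` fields;
    ``nuisance`` is the per-epoch registration probability ``p_hat``.
    """

    def __init__(self, model: RemovalModel, **kwargs):
        super().__init__(**kwargs)
        self.model = model

    @property
    def p_hat(self) -> float | None:
        return self.nuisance

    def loglike_at_optimum(self, form: str = "exact") -> float:
        if not self.valid:
            raise EstimationError("no optimum: estimator invalid for these data")
        return self.model.loglike(self.N_hat, self.nuisance, form=form)

    def summary(self) -> str:
        c = self.model.counts
        head = [
            "Removal maximum-likelihood population size",
            "=" * 44,
            f"  epochs M        {c.M:>12}",
            f"  counts n_j      {c.counts!s:>12}",
            f"  observed s_M    {c.s:>12}",
        ]
        return "\n".join(head) + "\n" + super().summary()


# ---------------------------------------------------------------------
# operation-style wrappers


def removal_loglik(N: float, p: float, counts: EpochCounts, form: str = "exact") -> float:
    """Removal log-likelihood of (N, p) for the given epoch counts."""
    return RemovalModel(counts).loglike(N, p, form=form)


def maximize_removal(counts: EpochCounts) -> RemovalResults:
    """Fit the removal ML estimator; see :meth:`RemovalModel.fit`."""
    return RemovalModel(counts).fit()


def existence_check(counts: EpochCounts) -> tuple[bool, str]:
    """Solvability condition ``X/s < (M-1)/2`` for the removal estimator."""
    return RemovalModel(counts).existence_check()


def closed_form_m2(n1: int, n2: int) -> EstimateResult:
    """Two-epoch removal estimate in closed form.

    For M=2 the likelihood maximum is ``N_hat = n1^2 / (n1 - n2)`` with
    ``p_hat = (n1 - n2)/n1``; it exists iff ``n1 > n2``.
    """
    if n1 < 0 or n2 < 0:
        raise ParameterError("epoch counts must be non-negative")
    if n1 <= n2:
        return EstimateResult(
            method="removal-ml-m2",
            valid=False,
            message=f"n1={n1} <= n2={n2}: removal estimator does not exist",
        )
    return EstimateResult(
        method="removal-ml-m2",
        N_hat=n1 * n1 / (n1 - n2),
        nuisance=(n1 - n2) / n1,
    )
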