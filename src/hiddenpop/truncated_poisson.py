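"""Truncated-Poisson population-size estimators (Chao, Zelterman).

If each person's registration count over the window is (approximately)
Poisson(lambda), only persons with count >= 1 are observed and the
expected frequency of count-j persons is ``E(h_j) = N lambda^j e^-lambda / j!``.
Eliminating lambda from the first three moments gives

    E(h_0) = E(h_1)^2 / (2 E(h_2)),

so the hidden zero class can be estimated from the two lowest observed
frequency classes:

* Chao:       ``N_C = sum_j h_j + h_1^2 / (2 h_2)``
* Zelterman:  ``lambda_e = 2 h_2 / h_1``,
              ``N_Z = sum_j h_j / (1 - exp(-lambda_e))``

Both hinge on registrations being memoryless: if being registered once
changes the future registration probability, the count distribution is
no longer Poisson and these estimators can be badly biased (see
:mod:`hiddenpop.evaluation` for the quantitative study).  The ratio
diagnostic ``h_1/(2 h_2)``, which should equal ``h_0/h_1`` under the
Poisson model, flags such violations when an external census of N is
available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterError
from .registry import CaptureHistogram
from .results import EstimateResult

__all__ = [
    "TruncatedPoissonModel",
    "RatioDiagnostic",
    "chao",
    "zelterman",
    "poisson_ratio_diagnostic",
]


@dataclass(frozen=True)
class RatioDiagnostic:
    """Poisson consistency ratios.

    ``r12 = h_1 / (2 h_2)`` is always computable; ``r01 = h_0 / h_1``
    requires an external census of N (then ``h_0 = N - observed``).
    Under an exact Poisson count model the two are equal; ``r12 << r01``
    indicates that registration begets re-registration.
    """

    r12: float
    r01: float | None = None

    @property
    def poisson_consistent(self) -> bool | None:
        if self.r01 is None:
            return None
        return math.isclose(self.r12, self.r01, rel_tol=0.1)


class TruncatedPoissonModel:
    """Zero-truncated Poisson model for a capture-frequency histogram.

    Parameters
    ----------
    hist : CaptureHistogram
        Counts ``h_j`` of persons registered exactly j times.

    Examples
    --------
    >>> from hiddenpop import CaptureHistogram, TruncatedPoissonModel
    >>> m = TruncatedPoissonModel(CaptureHistogram({1: 75, 2: 55}, observed_total=262))
    >>> m.fit(method="chao").N_hat_rounded
    313
    """

    def __init__(self, hist: CaptureHistogram):
        self.hist = hist

    @classmethod
    def from_events(cls, events, burn_in: int = 0) -> "TruncatedPoissonModel":
        from .registry import capture_histogram

        return cls(capture_histogram(events, burn_in=burn_in))

    def fit(self, method: str = "chao") -> EstimateResult:
        if method == "chao":
            return self._fit_chao()
        if method == "zelterman":
            return self._fit_zelterman()
        raise ParameterError(f"unknown truncated-Poisson method {method!r}")

    def _fit_chao(self) -> EstimateResult:
        h1, h2 = self.hist[1], self.hist[2]
        obs = self.hist.observed_total
        if h2 == 0:
            return EstimateResult(
                method="chao",
                valid=False,
                message="h_2 = 0: Chao's estimator h_1^2/(2 h_2) is undefined",
            )
        return EstimateResult(method="chao", N_hat=obs + h1 * h1 / (2.0 * h2))

    def _fit_zelterman(self) -> EstimateResult:
        h1, h2 = self.hist[1], self.hist[2]
        obs = self.hist.observed_total
        if h1 == 0 or h2 == 0:
            return EstimateResult(
                method="zelterman",
                valid=False,
                message=f"h_1={h1}, h_2={h2}: rate estimate 2 h_2/h_1 undefined",
            )
        lam = 2.0 * h2 / h1
        return EstimateResult(
            method="zelterman",
            N_hat=obs / (-math.expm1(-lam)),
            nuisance=lam,
        )

    def ratio_diagnostic(self, external_N: int | None = None) -> RatioDiagnostic:
        h1, h2 = self.hist[1], self.hist[2]
        obs = self.hist.observed_total
        if h1 == 0 or h2 == 0:
            raise ParameterError("ratio diagnostic requires h_1 > 0 and h_2 > 0")
        r12 = h1 / (2.0 * h2)
        if external_N is None:
            return RatioDiagnostic(r12=r12)
        if external_N < obs:
            raise ParameterError(
                f"external N={external_N} below observed total {obs}"
            )
        return RatioDiagnostic(r12=r12, r01=(external_N - obs) / h1)


def chao(hist: CaptureHistogram) -> EstimateResult:
    """Chao's lower-bound style estimator ``N_C = sum h_j + h_1^2/(2 h_2)``."""
    return TruncatedPoissonModel(hist).fit(method="chao")


def zelterman(hist: CaptureHistogram) -> EstimateResult:
    """Zelterman's estimator ``N_Z = sum h_j / (1 - e^{-2 h_2/h_1})``."""
    return TruncatedPoissonModel(hist).fit(method="zelterman")


def poisson_ratio_diagnostic(
    hist: CaptureHistogram, external_N: int | None = None
) -> RatioDiagnostic:
    """Poisson consistency check ``h_1/(2 h_2)`` (vs ``h_0/h_1`` given N)."""
    return TruncatedPoissonModel(hist).ratio_diagnostic(external_N=external_N)
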