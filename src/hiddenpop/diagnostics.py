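"""Applied-data diagnostics for the population-size estimators.

None of the estimators comes with a finite-sample guarantee on real
registers, so the practical workflow is to stress the estimate:

* :func:`m_sensitivity` -- refit the removal ML estimator for a range of
  epoch numbers M.  A strong dependence on M signals that too small a
  fraction of the population has been observed and the estimate should
  not be trusted.
* :func:`chao_stability` -- compare Chao's estimate on the first part of
  the window with the full-window estimate.  Under the Poisson
  assumption the two agree up to sampling error; a systematic drift
  indicates state-dependent registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import EventTable, capture_histogram, epoch_counts, split_window
from .removal import RemovalModel
from .truncated_poisson import TruncatedPoissonModel
from .errors import HiddenPopError

__all__ = ["MSensitivityResult", "m_sensitivity", "chao_stability"]


@dataclass(frozen=True)
class MSensitivityResult:
    """Removal ML estimates across epoch numbers M.

    ``table`` has one row per M (N_hat, p_hat, valid, message);
    ``relative_spread`` is (max - min)/mean of the valid estimates, NaN
    when fewer than two are valid.
    """

    table: pd.DataFrame
    relative_spread: float

    def summary(self) -> str:
        lines = ["Removal ML sensitivity to the number of epochs M",
                 "=" * 50,
                 self.table.to_string(index=False),
                 f"relative spread of valid estimates: {self.relative_spread:.4f}"]
        return "\n".join(lines)


def m_sensitivity(events: EventTable, Ms, burn_in: int = 0) -> MSensitivityResult:
    """Refit the removal estimator for each M and report the spread."""
    rows = []
    for M in Ms:
        try:
            res = RemovalModel(epoch_counts(events, M=int(M), burn_in=burn_in)).fit()
            rows.append(
                {
                    "M": int(M),
                    "N_hat": res.N_hat,
                    "N_hat_rounded": res.N_hat_rounded,
                    "p_hat": res.nuisance,
                    "valid": res.valid,
                    "message": res.message,
                }
            )
        except HiddenPopError as exc:
            rows.append(
                {
                    "M": int(M),
                    "N_hat": np.nan,
                    "N_hat_rounded": None,
                    "p_hat": np.nan,
                    "valid": False,
                    "message": str(exc),
                }
            )
    table = pd.DataFrame(rows)
    valid = table.loc[table["valid"], "N_hat"].to_numpy(dtype=float)
    if valid.size >= 2:
        spread = float((valid.max() - valid.min()) / valid.mean())
    else:
        spread = float("nan")
    return MSensitivityResult(table=table, relative_spread=spread)


def chao_stability(events: EventTable, fraction: float = 0.5) -> pd.DataFrame:
    """Chao's estimate on the head window vs the full window.

    Returns one row per window with the estimate and its validity; large
    disagreement between the rows questions the Poisson assumption.
    """
    head, full = split_window(events, fraction)
    rows = []
    for label, tab in (("head", head), ("full", full)):
        res = TruncatedPoissonModel(capture_histogram(tab)).fit(method="chao")
        rows.append(
            {
                "window": label,
                "T": tab.T,
                "observed": capture_histogram(tab).observed_total,
                "N_hat": res.N_hat,
                "valid": res.valid,
                "message": res.message,
            }
        )
    return pd.DataFrame(rows)
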