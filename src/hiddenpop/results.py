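"""Result containers shared by all population-size estimators."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["EstimateResult"]


@dataclass
class EstimateResult:
    """A population-size estimate together with its nuisance parameter.

    Attributes
    ----------
    method : str
        Estimator label: ``"removal-ml"``, ``"chao"`` or ``"zelterman"``.
    N_hat : float
        Estimated population size (NaN when ``valid`` is False).
    nuisance : float or None
        The estimated nuisance parameter: per-epoch registration
        probability ``p`` for the removal ML estimator, Poisson rate
        ``lambda`` for the truncated-Poisson estimators.
    valid : bool
        Whether the estimator exists for these data (e.g. the removal
        estimator requires declining epoch counts; Chao requires h_2 > 0).
    message : str
        Human-readable reason when ``valid`` is False.
    diagnostics : dict
        Free-form numerical diagnostics (score residual, iterations, ...).
    """

    method: str
    N_hat: float = math.nan
    nuisance: float | None = None
    valid: bool = True
    message: str = ""
    diagnostics: dict = field(default_factory=dict)

    @property
    def N_hat_rounded(self) -> int | None:
        """Estimate rounded to the nearest whole person."""
        if not self.valid or math.isnan(self.N_hat):
            return None
        return int(round(self.N_hat))

    def to_frame(self) -> pd.DataFrame:
        """One-row data frame in the audit CSV schema."""
        rounded = self.N_hat_rounded
        return pd.DataFrame(
            {
                "method": [self.method],
                "N_hat": [float(self.N_hat)],
                "N_hat_rounded": [math.nan if rounded is None else float(rounded)],
                "nuisance": [math.nan if self.nuisance is None else float(self.nuisance)],
                "valid": [self.valid],
                "message": [self.message],
            }
        )

    def summary(self) -> str:
        lines = [
            f"Population size estimate ({self.method})",
            "-" * 44,
            f"  N_hat           {self.N_hat:12.4f}",
            f"  N_hat (rounded) {self.N_hat_rounded!s:>12}",
        ]
        if self.nuisance is not None:
            lines.append(f"  nuisance        {self.nuisance:12.6f}")
        lines.append(f"  valid           {self.valid!s:>12}")
        if self.message:
            lines.append(f"  note: {self.message}")
        for k, v in self.diagnostics.items():
            lines.append(f"  {k:<16}{v}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.valid:
            return (
                f"<EstimateResult {self.method}: N_hat={self.N_hat:.2f} "
                f"nuisance={self.nuisance}>"
            )
        return f"<EstimateResult {self.method}: invalid ({self.message})>"
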