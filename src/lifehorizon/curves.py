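"""Monthly-grid survival curves shared by every stage of the pipeline.

All survival functions in the package — the Kaplan–Meier estimate of the
index cohort, the Monte-Carlo referent curve, and the extrapolated lifetime
curve — live on the same integer monthly grid ``0, 1, 2, ...`` measured from
the index date.  ``S(m)`` is the probability of surviving *beyond* month m:
a death recorded at month ``t`` drops the curve at grid point ``t``.  One
month is DAYS_PER_MONTH = 30.4375 days (365.25 / 12); years = months / 12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 30.4375

#: survival mass below which a curve counts as exhausted (horizon reached)
SURVIVAL_EPS = 1e-6


def days_to_months(days) -> np.ndarray:
    """Snap day-scale follow-up to the monthly grid by interval membership.

    A duration of ``d`` days belongs to the month whose grid point is
    nearest (deaths on day 0 land in month 0).
    """
    return np.rint(np.asarray(days, dtype=float) / DAYS_PER_MONTH).astype(int)


@dataclass
class SurvivalCurve:
    """Survival probabilities on the monthly grid with at-risk counts.

    ``provenance`` records how the curve was obtained: ``"index-KM"``
    (product-limit on the index cohort), ``"referent-MC"`` (Monte-Carlo
    life-table referents), or ``"extrapolated"``.
    """

    months: np.ndarray
    surv: np.ndarray
    n_at_risk: np.ndarray | None = None
    provenance: str = "index-KM"

    def __post_init__(self) -> None:
        self.months = np.asarray(self.months, dtype=int)
        self.surv = np.asarray(self.surv, dtype=float)
        if self.n_at_risk is not None:
            self.n_at_risk = np.asarray(self.n_at_risk, dtype=float)
            if self.n_at_risk.shape != self.months.shape:
                raise ValueError("n_at_risk must match the grid")
        if self.months.ndim != 1 or self.months.size == 0:
            raise ValueError("curve needs a non-empty 1-d monthly grid")
        if not np.array_equal(self.months, np.arange(self.months[0], self.months[-1] + 1)):
            raise ValueError("monthly grid must be consecutive integers")
        if self.months[0] != 0:
            raise ValueError("grid must start at month 0 (the index date)")
        if np.any(self.surv < -1e-12) or np.any(self.surv > 1 + 1e-12):
            raise ValueError("survival probabilities outside [0, 1]")
        if np.any(np.diff(self.surv) > 1e-12):
            raise ValueError("survival curve must be non-increasing")
        self.surv = np.clip(self.surv, 0.0, 1.0)

    @property
    def horizon(self) -> int:
        return int(self.months[-1])

    def at(self, month: int) -> float:
        if month < 0 or month > self.horizon:
            raise IndexError(f"month {month} outside grid [0, {self.horizon}]")
        return float(self.surv[month])

    def restricted_mean(self, horizon_months: int) -> float:
        """Trapezoidal integral of S from 0 to ``horizon_months``, in years."""
        if horizon_months > self.horizon:
            raise ValueError(
                f"horizon {horizon_months} beyond grid end {self.horizon}"
            )
        if horizon_months < 0:
            raise ValueError("horizon must be non-negative")
        s = self.surv[: horizon_months + 1]
        return float(np.trapezoid(s, dx=1.0) / 12.0)

    def mean_survival(self) -> float:
        """Life expectancy in years; requires the curve to be exhausted."""
        if self.surv[-1] > SURVIVAL_EPS:
            raise ValueError(
                f"curve still has survival mass {self.surv[-1]:.3g} at its end; "
                "integral would be silently truncated"
            )
        return self.restricted_mean(self.horizon)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "month": self.months,
            "S": self.surv,
            "n_at_risk": 0.0 if self.n_at_risk is None else self.n_at_risk,
            "provenance": self.provenance,
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "SurvivalCurve":
        df = pd.read_csv(path)
        return cls(
            months=df["month"].to_numpy(),
            surv=df["S"].to_numpy(),
            n_at_risk=df["n_at_risk"].to_numpy() if "n_at_risk" in df else None,
            provenance=str(df["provenance"].iloc[0]) if "provenance" in df else "index-KM",
        )


def require_shared_grid(a: SurvivalCurve, b: SurvivalCurve, through: int) -> None:
    """Raise if two curves do not share the monthly grid up to ``through``."""
    if a.horizon < through or b.horizon < through:
        raise ValueError(
            f"curves do not both reach month {through} "
            f"(horizons {a.horizon}, {b.horizon})"
        )
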