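"""Survival-weighted discounted lifetime medical costs.

Monthly mean costs among patients still under observation (alive and
uncensored) are extrapolated beyond follow-up with the same rolling-over
OLS used for survival — applied on the log(1 + cost) scale, which keeps the
extrapolated costs positive and lets the trend capture the characteristic
rise of medical spending near the end of life.  The lifetime cost is then

    sum_m  S(m) * mean_cost(m) * (1 + r)^(-m/12)

per stream (insurer-paid and patient copayment), where S is the lifetime
survival curve and r the annual discount rate (3% base case; 0% and 5%
sensitivity).  Averaging among survivors and re-weighting by S(m) at
aggregation time is what makes the sum an expected *per-case* lifetime
cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import SurvivalCurve

STREAMS = ("insurer", "copay")


@dataclass
class CostProfile:
    """Mean monthly costs per stream with contribution counts."""

    months: np.ndarray
    mean_cost: dict                      # stream -> array aligned to months
    n_contributing: np.ndarray
    provenance: np.ndarray = None        # "observed" / "extrapolated" per month

    def __post_init__(self):
        self.months = np.asarray(self.months, dtype=int)
        self.n_contributing = np.asarray(self.n_contributing, dtype=float)
        if self.provenance is None:
            self.provenance = np.array(["observed"] * self.months.size)
        self.provenance = np.asarray(self.provenance)
        for s in STREAMS:
            arr = np.asarray(self.mean_cost[s], dtype=float)
            if arr.shape != self.months.shape:
                raise ValueError(f"stream {s!r} misaligned with months")
            if np.any(arr < 0):
                raise ValueError("mean costs must be >= 0")
            self.mean_cost[s] = arr
        if np.any(self.n_contributing < 0):
            raise ValueError("n_contributing must be >= 0")
        obs = self.provenance == "observed"
        if obs.any() and not obs[: int(np.flatnonzero(obs)[-1]) + 1].all():
            raise ValueError("observed months must precede extrapolated months")

    @property
    def horizon(self) -> int:
        return int(self.months[-1])


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate compounded monthly: factor (1+r)^(-m/12)."""

    annual_rate: float = 0.03

    def __post_init__(self):
        if self.annual_rate < 0:
            raise ValueError("annual_rate must be >= 0")

    def factor(self, months: np.ndarray) -> np.ndarray:
        return np.power(1.0 + self.annual_rate, -np.asarray(months) / 12.0)


def monthly_mean_costs(patients: pd.DataFrame,
                       costs_long: pd.DataFrame) -> CostProfile:
    """Observed monthly average cost per case after diagnosis.

    For month m the mean runs over patients still under observation at m —
    i.e. with ``followup_months > m`` — counting patients without a claim
    that month as zero.  Months with nobody under observation are absent.
    """
    if (costs_long[["insurer", "copay"]] < 0).any().any():
        raise ValueError("negative costs")
    fup = patients.set_index("patient_id")["followup_months"]
    max_m = int(fup.max()) - 1
    if max_m < 0:
        raise ValueError("no patient contributes any full month of observation")
    months = np.arange(max_m + 1)
    n_contrib = np.array([(fup > m).sum() for m in months], dtype=float)

    cl = costs_long[costs_long["patient_id"].isin(fup.index)].merge(
        fup.rename("fup"), left_on="patient_id", right_index=True)
    cl = cl[cl["month"] < cl["fup"]]
    sums = cl.groupby("month")[["insurer", "copay"]].sum()
    sums = sums.reindex(months, fill_value=0.0)
    mean = {s: sums[s].to_numpy() / np.maximum(n_contrib, 1) for s in STREAMS}
    keep = n_contrib > 0
    last = int(np.flatnonzero(keep)[-1])
    return CostProfile(months=months[: last + 1],
                       mean_cost={s: mean[s][: last + 1] for s in STREAMS},
                       n_contributing=n_contrib[: last + 1])


def extrapolate_costs(profile: CostProfile, lifetime: SurvivalCurve,
                      window: int = 24) -> CostProfile:
    """Extend the mean-cost profile to the survival horizon.

    Rolling-over OLS on log(1 + mean_cost) over the trailing ``window``
    months (observed plus previously extrapolated), exponentiated back and
    floored at 0; extrapolated months are marked as such.
    """
    if window < 2:
        raise ValueError("rolling window must span at least 2 months")
    horizon = lifetime.horizon
    if profile.horizon >= horizon:
        return profile
    months = np.arange(horizon + 1)
    n_obs = profile.months.size
    window = min(window, n_obs)
    out = {}
    for s in STREAMS:
        y = np.log1p(profile.mean_cost[s]).tolist()
        x = profile.months.astype(float).tolist()
        for m in range(profile.horizon + 1, horizon + 1):
            xx = np.asarray(x[-window:])
            yy = np.asarray(y[-window:])
            slope, intercept = np.polyfit(xx, yy, 1)
            y_hat = intercept + slope * m
            x.append(float(m))
            y.append(float(y_hat))
        out[s] = np.maximum(np.expm1(np.asarray(y)), 0.0)
    n_contrib = np.zeros(horizon + 1)
    n_contrib[: n_obs] = profile.n_contributing
    provenance = np.where(months <= profile.horizon, "observed", "extrapolated")
    return CostProfile(months=months, mean_cost=out,
                       n_contributing=n_contrib, provenance=provenance)


def lifetime_cost(profile: CostProfile, lifetime: SurvivalCurve,
                  discount: DiscountSpec | None = None) -> dict:
    """Survival-weighted discounted lifetime cost per stream.

    The profile and curve must share the monthly grid out to the curve's
    horizon.  Returns insurer, copay and total amounts plus the copayment
    share copay / (copay + insurer).
    """
    discount = discount or DiscountSpec()
    if profile.horizon < lifetime.horizon:
        raise ValueError(
            f"cost profile ends at month {profile.horizon}, before the "
            f"survival horizon {lifetime.horizon}; extrapolate costs first")
    m = lifetime.months
    disc = discount.factor(m)
    out = {}
    for s in STREAMS:
        out[s] = float(np.sum(lifetime.surv * profile.mean_cost[s][: m.size] * disc))
    out["total"] = out["insurer"] + out["copay"]
    out["copay_share"] = out["copay"] / out["total"] if out["total"] > 0 else 0.0
    return out


def convert_currency(amount_krw, krw_per_usd: float = 1131.2):
    """KRW to USD at a fixed exchange rate (2015 average: 1131.2 KRW/US$)."""
    if krw_per_usd <= 0:
        raise ValueError("exchange rate must be positive")
    return amount_krw / krw_per_usd
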