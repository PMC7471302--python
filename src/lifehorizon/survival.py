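"""Kaplan-Meier estimation of index-cohort survival on the monthly grid."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .curves import SurvivalCurve


@dataclass(frozen=True)
class FollowupSpec:
    """Administrative follow-up limits applied before estimation."""

    max_followup_months: int

    def __post_init__(self):
        if self.max_followup_months <= 0:
            raise ValueError("max_followup_months must be positive")


def kaplan_meier(patients: pd.DataFrame,
                 spec: FollowupSpec | None = None) -> SurvivalCurve:
    """Product-limit survival estimate evaluated on the monthly grid.

    ``patients`` must carry integer ``followup_months`` and ``event``
    (1 = died, 0 = censored).  Follow-up is snapped to whole months before
    estimation, so ties within a month are resolved the standard way
    (deaths precede censorings at the same time).  When ``spec`` caps the
    follow-up, durations and events are administratively truncated first.
    """
    if len(patients) == 0:
        raise ValueError("cannot estimate survival for an empty cohort")
    dur = patients["followup_months"].to_numpy(dtype=float)
    ev = patients["event"].to_numpy(dtype=int)
    if np.any(dur < 0):
        raise ValueError("negative follow-up durations")
    if spec is not None:
        cap = spec.max_followup_months
        ev = np.where(dur <= cap, ev, 0)
        dur = np.minimum(dur, cap)
    if dur.max() == 0 and ev.sum() == 0:
        raise ValueError("all patients censored at time 0; no information")

    kmf = KaplanMeierFitter()
    kmf.fit(dur, event_observed=ev)
    grid = np.arange(int(dur.max()) + 1)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    # at risk just before each grid month (censorings at m still at risk at m)
    n_at_risk = np.array([(dur >= m).sum() for m in grid], dtype=float)
    return SurvivalCurve(months=grid, surv=surv, n_at_risk=n_at_risk,
                         provenance="index-KM")


def restricted_mean(curve: SurvivalCurve, horizon_months: int) -> float:
    """Restricted mean survival time in years: the trapezoidal integral of
    S from month 0 to ``horizon_months``."""
    return curve.restricted_mean(horizon_months)
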