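"""Matched reference population survival via Monte-Carlo life-table sampling.

For every patient in the index cohort, referent lifetimes are simulated by
walking the national life table forward from the patient's sex, completed
age and calendar year at index, age and calendar year advancing together on
the monthly grid (monthly hazard ``-ln(1-q)/12``; within-year death months
follow the constant-hazard monthly discretization).  The pooled empirical
survival of these referents is what the patient cohort's survival *would
have been* absent the disease; its integral is the referents' life
expectancy, and the EYLL is measured against it.

The referent curve uses only (sex, age, index year) — never the patients'
event or censoring data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .curves import SURVIVAL_EPS, SurvivalCurve
from .lifetable import LifeTable

#: referents are never simulated past this age
AGE_CAP = 110


def monte_carlo_reference(patients: pd.DataFrame, life_table: LifeTable,
                          n_replicates: int = 100, seed: int = 0,
                          eps: float = SURVIVAL_EPS) -> SurvivalCurve:
    """Pooled referent survival curve for a cohort.

    ``patients`` must carry ``sex``, ``age_at_index`` and ``index_date``
    (or ``index_year``).  Each patient contributes ``n_replicates``
    simulated referent lifetimes; the pooled curve ends at the first month
    where survival falls below ``eps`` (the life table's closing age
    guarantees this happens).  Deterministic given ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if len(patients) == 0:
        raise ValueError("cannot build a referent curve for an empty cohort")
    rng = np.random.default_rng(seed)

    if "index_year" in patients.columns:
        year = patients["index_year"].astype(int)
    else:
        year = pd.to_datetime(patients["index_date"]).dt.year
    prof = pd.DataFrame({
        "sex": patients["sex"].to_numpy(),
        "age": patients["age_at_index"].astype(int).to_numpy(),
        "year": year.to_numpy(),
    })
    groups = prof.value_counts().reset_index(name="count")
    max_age_cap = min(life_table.max_age, AGE_CAP)
    n_months = (max_age_cap - int(groups["age"].min())) * 12 + 12

    total = int(groups["count"].sum()) * n_replicates
    death_hist = np.zeros(n_months + 2)
    for row in groups.itertuples(index=False):
        p = life_table.monthly_death_prob_path(row.sex, row.age, row.year, n_months)
        p[(row.age + np.arange(n_months) // 12) >= max_age_cap] = 1.0
        S = np.empty(n_months + 1)
        S[0] = 1.0
        np.cumprod(1.0 - p, out=S[1:])
        u = rng.random(row.count * n_replicates)
        T = np.searchsorted(-S, -u, side="right")
        np.add.at(death_hist, np.minimum(T, n_months), 1)

    alive = total - np.cumsum(death_hist[: n_months + 1])
    surv = alive / total
    # horizon: first month at/under eps (certain to exist: the table closes)
    below = np.flatnonzero(surv <= eps)
    end = int(below[0]) if below.size else n_months
    return SurvivalCurve(months=np.arange(end + 1), surv=surv[: end + 1],
                         n_at_risk=alive[: end + 1], provenance="referent-MC")


def reference_life_expectancy(ref: SurvivalCurve) -> float:
    """Life expectancy of the referents, in years (trapezoidal integral of
    the pooled curve; raises if the curve still has survival mass)."""
    return ref.mean_survival()
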