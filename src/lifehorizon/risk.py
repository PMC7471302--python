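"""Lifetime risk of disease via the cumulative incidence rate, CIR_18-84.

Age- and sex-specific incidence rates IR_i are computed per two-year
period from sample case counts (scaled up by the sampling fraction of the
source cohort) and census denominators.  The lifetime risk between ages 18
and 84 is then

    CIR_18-84 = 1 - exp( - sum_i IR_i * w_i )

where w_i is the width of the i-th age band: 7 years for 18-24, then
5-year bands through 80-84.  Ages 85+ are excluded because their small
denominators would be over-represented by the equal-weight construction.
The CIR does not adjust for competing mortality; a prevalence-adjusted
variant subtracts prevalent cases from the denominators only, which yields
an upper bound on the risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: (low, high) inclusive age bands for CIR_18-84
AGE_BANDS = tuple([(18, 24)] + [(lo, lo + 4) for lo in range(25, 85, 5)])


def band_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


BAND_LABELS = tuple(band_label(lo, hi) for lo, hi in AGE_BANDS)
BAND_WIDTHS = {band_label(lo, hi): hi - lo + 1 for lo, hi in AGE_BANDS}


def age_to_band(age) -> pd.Series:
    """Map single ages to CIR band labels (NaN outside 18-84)."""
    age = pd.Series(age)
    bins = [17] + [hi for _, hi in AGE_BANDS]
    return pd.cut(age, bins=bins, labels=BAND_LABELS)


@dataclass(frozen=True)
class SamplingFraction:
    """Proportion of the national population present in the sample cohort,
    per calendar year (e.g. ~0.02 for a 2% national sample)."""

    by_year: dict

    def __post_init__(self):
        for year, f in self.by_year.items():
            if not 0 < f <= 1:
                raise ValueError(f"sampling fraction {f} for {year} outside (0, 1]")

    def at(self, year: int) -> float:
        if year not in self.by_year:
            raise KeyError(f"no sampling fraction for year {year}")
        return float(self.by_year[year])


def incidence_rates(new_cases: pd.DataFrame, census: pd.DataFrame,
                    sampling: SamplingFraction,
                    periods: list | None = None) -> pd.DataFrame:
    """Annualized age-/sex-specific incidence per two-year period.

    Parameters
    ----------
    new_cases : DataFrame with columns (sex, age_group, year, cases) —
        sample counts of first-ever events per calendar year.
    census : DataFrame with columns (sex, age_group, period, population) —
        national person counts per stratum and two-year period.
    sampling : per-year sampling fractions used to scale sample counts to
        national counts.
    periods : optional list of (start_year, end_year); inferred from the
        census period labels when omitted.

    Returns an IncidenceTable DataFrame with columns
    (sex, age_group, period, cases_scaled, population, person_years, IR,
    width).  IR = scaled cases / (population x period length in years).
    """
    if periods is None:
        periods = [tuple(int(y) for y in p.split("-"))
                   for p in sorted(census["period"].unique())]
    year_to_period = {}
    for (y0, y1) in periods:
        for y in range(y0, y1 + 1):
            year_to_period[y] = f"{y0}-{y1}"
    period_years = {f"{y0}-{y1}": y1 - y0 + 1 for y0, y1 in periods}

    cases = new_cases.copy()
    unknown = set(cases["year"].unique()) - set(year_to_period)
    if unknown:
        raise ValueError(f"case years {sorted(unknown)} outside the census periods")
    if len(cases):
        cases["period"] = cases["year"].map(year_to_period)
        cases["cases_scaled"] = [c / sampling.at(int(y))
                                 for c, y in zip(cases["cases"], cases["year"])]
        agg = (cases.groupby(["sex", "age_group", "period"], observed=True)
               ["cases_scaled"].sum().reset_index())
    else:
        agg = pd.DataFrame(columns=["sex", "age_group", "period", "cases_scaled"])

    table = census.merge(agg, on=["sex", "age_group", "period"], how="left")
    table["cases_scaled"] = pd.to_numeric(table["cases_scaled"],
                                          errors="coerce").fillna(0.0)
    if ((table["population"] <= 0) & (table["cases_scaled"] > 0)).any():
        raise ValueError("cases observed in a stratum with zero population")
    table["person_years"] = table["population"] * table["period"].map(period_years)
    table["IR"] = table["cases_scaled"] / table["person_years"]
    table["width"] = table["age_group"].map(BAND_WIDTHS)
    if table["width"].isna().any():
        bad = sorted(table.loc[table["width"].isna(), "age_group"].unique())
        raise ValueError(f"unknown age groups {bad}; expected {list(BAND_LABELS)}")
    return table


def prevalence_adjust(table: pd.DataFrame, prevalence: pd.DataFrame) -> pd.DataFrame:
    """Recompute IR after removing prevalent cases from the denominators.

    ``prevalence`` has columns (sex, age_group, period, prevalent).  The
    numerators are left untouched, so the adjusted CIR is never smaller
    than the unadjusted one (an upper bound on the lifetime risk).
    """
    out = table.merge(prevalence, on=["sex", "age_group", "period"], how="left")
    out["prevalent"] = out["prevalent"].fillna(0.0)
    if (out["prevalent"] > out["population"]).any():
        raise ValueError("prevalent cases exceed population in some stratum")
    if (out["prevalent"] < 0).any():
        raise ValueError("prevalence counts must be >= 0")
    # IR scales as population/(population - prevalent); equivalent to
    # recomputing cases/person-years with the reduced denominator
    old_pop = out["population"]
    period_years = out["person_years"] / old_pop
    out["population"] = old_pop - out["prevalent"]
    out["person_years"] = out["population"] * period_years
    with np.errstate(divide="ignore", invalid="ignore"):
        out["IR"] = np.where(out["population"] > 0,
                             out["IR"] * old_pop / out["population"], 0.0)
    return out.drop(columns=["prevalent"])


def cir_18_84(table: pd.DataFrame, variant: str = "unadjusted") -> pd.DataFrame:
    """Lifetime risk per (sex, period) stratum from an incidence table.

    Requires all 13 age bands per stratum.  Returns a DataFrame with
    columns (sex, period, variant, cir, one_in_n): ``cir`` is
    1 - exp(-sum IR_i w_i) and ``one_in_n`` the rounded reciprocal
    ("1 person in N develops the disease between ages 18 and 84").
    """
    results = []
    for (sex, period), sub in table.groupby(["sex", "period"], observed=True):
        missing = set(BAND_LABELS) - set(sub["age_group"].astype(str))
        if missing:
            raise ValueError(
                f"stratum (sex={sex}, period={period}) missing age bands "
                f"{sorted(missing, key=BAND_LABELS.index)}"
            )
        cum = float((sub["IR"] * sub["width"]).sum())
        cir = 1.0 - np.exp(-cum)
        results.append({
            "sex": sex, "period": period, "variant": variant, "cir": cir,
            "one_in_n": int(round(1.0 / cir)) if cir > 0 else np.inf,
        })
    return pd.DataFrame(results)


def cir_micro_oracle(table: pd.DataFrame, n_individuals: int = 100_000,
                     seed: int = 0) -> float:
    """Brute-force check of the CIR formula for a single (sex, period) table.

    Simulates individuals aging from 18 to 84 under the band-wise constant
    hazards IR_i and returns the fraction ever experiencing the event.
    Converges to ``cir_18_84`` within binomial error.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be positive")
    rng = np.random.default_rng(seed)
    sub = table.set_index("age_group")
    alive_eventfree = np.ones(n_individuals, dtype=bool)
    for label in BAND_LABELS:
        ir = float(sub.loc[label, "IR"])
        width = BAND_WIDTHS[label]
        p_band = 1.0 - np.exp(-ir * width)
        hits = rng.random(n_individuals) < p_band
        alive_eventfree &= ~hits
    return 1.0 - alive_eventfree.mean()


def new_cases_from_cohort(patients: pd.DataFrame) -> pd.DataFrame:
    """Tabulate incident cases (sex, age_group, year, cases) from a cohort
    table carrying sex, age_at_index and index_date; ages outside 18-84
    are dropped (they do not enter CIR_18-84)."""
    df = patients.copy()
    df["age_group"] = age_to_band(df["age_at_index"].to_numpy())
    df["year"] = pd.to_datetime(df["index_date"]).dt.year
    df = df.dropna(subset=["age_group"])
    out = (df.groupby(["sex", "age_group", "year"], observed=True)
           .size().rename("cases").reset_index())
    out["age_group"] = out["age_group"].astype(str)
    return out
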