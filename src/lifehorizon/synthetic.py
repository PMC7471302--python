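"""Synthetic claims cohorts with known ground truth.

The real data this pipeline was designed for — national insurer claims with
ICD-10-coded stroke admissions (I60–I63), imaging procedure records, and
monthly reimbursement streams under a 10-year administrative window — are
access-restricted.  This module generates structurally equivalent synthetic
inputs from an explicit stochastic model, so that every downstream stage
(cohort construction, Kaplan–Meier estimation, Monte-Carlo referents,
rolling-over extrapolation, lifetime costs, lifetime risk) can be tested
against known truth:

* mortality follows the supplied life table, optionally inflated by a
  piecewise-constant excess hazard (multiplicative by default) on the
  monthly grid measured from the index event;
* monthly costs are lognormal noise around a baseline level, multiplied by
  a terminal surge during the last K months of life (medical spending rises
  near death);
* a configurable fraction of patients receive washout-period noise codes
  (I60–I69 before the window), lack an admission record, or lack an imaging
  code, exercising each exclusion rule of the cohort builder.

Every generator is deterministic given the scenario seed.  The returned
:class:`GroundTruth` carries the exact (analytic) cohort survival curve,
life expectancy, expected years of life lost, and expected discounted
lifetime costs implied by the generating process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import DAYS_PER_MONTH, SurvivalCurve
from .lifetable import SEXES, LifeTable

# ICD-10 code families used throughout: I60 subarachnoid hemorrhage (SAH),
# I61 intracerebral hemorrhage (ICH), I62 other non-traumatic intracranial
# hemorrhage (NIH), I63 cerebral infarction (CI); I60-I69 = any stroke or
# sequela (washout screen).
SUBTYPE_CODES = {"SAH": "I60", "ICH": "I61", "NIH": "I62", "CI": "I63"}
SUBTYPES = tuple(SUBTYPE_CODES)
WASHOUT_CODES = tuple(f"I6{d}" for d in range(10))

IMAGING_CODES = ("CT01", "MRI01")
SEVERITY_CODES = ("ICU", "AIRWAY", "NGTUBE", "FOLEY", "REHAB")

COMORBIDITY_CODES = {
    "AF": ["I48"], "CHF": ["I50"], "CKD": ["N18"], "COPD": ["J44"],
    "diabetes": ["E11"], "hyperlipidemia": ["E78"], "hypertension": ["I10"],
    "IHD": ["I20", "I21", "I25"], "TIA": ["G45"],
}
_COMORBIDITY_PREV = {
    "AF": 0.09, "CHF": 0.06, "CKD": 0.025, "COPD": 0.10, "diabetes": 0.36,
    "hyperlipidemia": 0.48, "hypertension": 0.64, "IHD": 0.18, "TIA": 0.07,
}

CLAIMS_COLUMNS = [
    "patient_id", "date", "setting", "primary_dx", "procedure_codes",
    "insurer_paid", "copay", "sex", "birth_year", "insurance_type",
    "residence", "death_date",
]


@dataclass(frozen=True)
class ExcessHazard:
    """Piecewise-constant excess over the life-table monthly hazard.

    ``values[i]`` applies from month ``breakpoints[i]`` (inclusive) until the
    next breakpoint.  Multiplicative mode scales the baseline monthly hazard
    (value 1 = no excess, the null case); additive mode adds a monthly
    hazard (value 0 = null).
    """

    mode: str = "multiplicative"
    breakpoints: tuple = (0,)
    values: tuple = (1.0,)

    def __post_init__(self):
        if self.mode not in ("multiplicative", "additive"):
            raise ValueError(f"unknown excess-hazard mode {self.mode!r}")
        bp = tuple(int(b) for b in self.breakpoints)
        if len(bp) != len(self.values) or not bp or bp[0] != 0:
            raise ValueError("breakpoints must start at 0 and match values")
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if any(v < 0 for v in self.values):
            raise ValueError("excess-hazard values must be >= 0")

    @classmethod
    def null(cls) -> "ExcessHazard":
        return cls()

    @classmethod
    def constant(cls, multiplier: float) -> "ExcessHazard":
        return cls(values=(float(multiplier),))

    def at(self, months: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.breakpoints, months, side="right") - 1
        return np.asarray(self.values, dtype=float)[idx]

    def apply(self, p_baseline: np.ndarray) -> np.ndarray:
        """Monthly death probabilities under the excess hazard."""
        p0 = np.asarray(p_baseline, dtype=float)
        with np.errstate(divide="ignore"):
            h0 = -np.log1p(-np.minimum(p0, 1 - 1e-15))
        v = self.at(np.arange(p0.size))
        h = h0 * v if self.mode == "multiplicative" else h0 + v
        p = 1.0 - np.exp(-h)
        p[p0 >= 1.0] = 1.0
        return p

    def is_null(self) -> bool:
        target = 1.0 if self.mode == "multiplicative" else 0.0
        return all(v == target for v in self.values)


@dataclass(frozen=True)
class CostSpec:
    """Monthly cost process: lognormal noise around a baseline level, with a
    terminal surge over the last ``surge_window`` months of life."""

    baseline_monthly: float = 350_000.0   # KRW per survivor-month
    surge_multiplier: float = 6.0
    surge_window: int = 12                # months before death
    copay_share: float = 0.18             # patient-paid fraction of each claim
    lognormal_sigma: float = 0.6

    def __post_init__(self):
        if self.baseline_monthly < 0 or self.surge_multiplier < 1:
            raise ValueError("baseline must be >= 0 and surge multiplier >= 1")
        if not 0 <= self.copay_share <= 1:
            raise ValueError("copay_share must be in [0, 1]")
        if self.surge_window < 0 or self.lognormal_sigma < 0:
            raise ValueError("surge_window and sigma must be >= 0")

    def mean_monthly(self, months_to_death: np.ndarray) -> np.ndarray:
        """Expected cost at a month given the (true) remaining lifetime."""
        surge = months_to_death <= self.surge_window
        return self.baseline_monthly * np.where(surge, self.surge_multiplier, 1.0)


def _default_age_weights() -> dict:
    # Broad adult distribution peaking in the late 60s, ages 18-94.
    ages = np.arange(18, 95)
    w = np.exp(-0.5 * ((ages - 67) / 13.0) ** 2)
    return dict(zip(ages.tolist(), (w / w.sum()).tolist()))


@dataclass
class SyntheticScenario:
    """Full specification of one synthetic claims cohort."""

    seed: int = 0
    n_patients: int = 1000
    age_distribution: dict = field(default_factory=_default_age_weights)
    sex_ratio: float = 0.54                      # proportion male
    subtype_weights: dict = field(default_factory=lambda: {
        "SAH": 0.084, "ICH": 0.145, "NIH": 0.036, "CI": 0.735})
    excess_hazard: ExcessHazard = field(default_factory=ExcessHazard.null)
    cost_spec: CostSpec = field(default_factory=CostSpec)
    admin_start: str = "2006-01-01"
    admin_end: str = "2015-12-31"
    washout_start: str = "2002-01-01"
    washout_end: str = "2005-12-31"
    index_end: str | None = None     # last admissible index date (default: admin_end)
    washout_noise_rate: float = 0.0
    nonhosp_rate: float = 0.0
    no_imaging_rate: float = 0.0

    def __post_init__(self):
        for name in ("sex_ratio", "washout_noise_rate", "nonhosp_rate",
                     "no_imaging_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.subtype_weights.values()) - 1.0) > 1e-9:
            raise ValueError("subtype_weights must sum to 1")
        if set(self.subtype_weights) - set(SUBTYPES):
            raise ValueError(f"subtypes must be among {SUBTYPES}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        ages = np.array(sorted(self.age_distribution), dtype=int)
        if ages.min() < 18 or ages.max() > 100:
            raise ValueError("age_distribution must cover ages within 18-100")
        w = np.array([self.age_distribution[a] for a in ages], dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("age weights must be non-negative and not all zero")
        if pd.Timestamp(self.washout_end) >= pd.Timestamp(self.admin_start):
            raise ValueError("washout must precede the administrative window")
        if pd.Timestamp(self.admin_start) > pd.Timestamp(self.admin_end):
            raise ValueError("admin window start must precede its end")


@dataclass
class GroundTruth:
    """Exact quantities implied by the generating process."""

    patients: pd.DataFrame                  # one row per generated index event
    survival: SurvivalCurve                 # true lifetime curve of the cohort
    reference: SurvivalCurve                # same patients, null excess hazard
    le: float                               # years
    le_ref: float
    eyll: float
    costs: dict                             # {rate: {"insurer":..,"copay":..,"total":..}} KRW

    def __post_init__(self):
        if abs(self.le - self.survival.restricted_mean(self.survival.horizon)) > 1e-6:
            raise ValueError("true LE must equal the integral of the true curve")


def generate_life_table(first_year: int, last_year: int, max_age: int = 110,
                        hazard_shape: dict | None = None) -> LifeTable:
    """Build a synthetic national life table.

    ``hazard_shape`` selects the age pattern of mortality:

    * ``{"kind": "gompertz", "a": .., "b": .., "sex_factor": {"M":..,"F":..},
      "annual_improvement": ..}`` — exponential rise of hazard with age
      (default, calibrated to an East-Asian-style life expectancy around
      80 for males and 86 for females);
    * ``{"kind": "constant", "q": ..}`` — the same annual death probability
      in every cell (useful for closed-form checks).

    The table closes with q = 1 at ``max_age``.
    """
    if first_year > last_year:
        raise ValueError("first_year must be <= last_year")
    if max_age < 85:
        raise ValueError("max_age must be >= 85")
    shape = dict(hazard_shape or {"kind": "gompertz"})
    kind = shape.pop("kind", "gompertz")
    years = np.arange(first_year, last_year + 1)
    ages = np.arange(0, max_age + 1)
    q = {}
    if kind == "constant":
        qv = float(shape.get("q", 0.5))
        if not 0 <= qv <= 1:
            raise ValueError(f"constant q={qv} outside [0, 1]")
        for sex in SEXES:
            arr = np.full((years.size, ages.size), qv)
            arr[:, -1] = 1.0
            q[sex] = arr
    elif kind == "gompertz":
        a = float(shape.get("a", 2.5e-5))
        b = float(shape.get("b", 0.098))
        sex_factor = shape.get("sex_factor", {"M": 1.0, "F": 0.5})
        impr = float(shape.get("annual_improvement", 0.005))
        if a <= 0 or b <= 0:
            raise ValueError("gompertz parameters a, b must be positive")
        if not 0 <= impr < 1:
            raise ValueError("annual_improvement must be in [0, 1)")
        for sex in SEXES:
            f = float(sex_factor[sex])
            if f <= 0:
                raise ValueError("sex_factor values must be positive")
            hazard = a * f * np.exp(b * ages)[None, :] \
                * np.power(1 - impr, years - first_year)[:, None]
            arr = 1.0 - np.exp(-hazard)
            arr[:, -1] = 1.0
            q[sex] = arr
    else:
        raise ValueError(f"unknown hazard shape kind {kind!r}")
    return LifeTable(years=years, ages=ages, q=q)


# ---------------------------------------------------------------------------
# cohort generation

def _group_survival(life_table: LifeTable, groups: pd.DataFrame,
                    excess: ExcessHazard, n_months: int) -> np.ndarray:
    """S(m) = P(T > m) per (sex, age, year) group; shape (n_groups, n_months+1)."""
    S = np.empty((len(groups), n_months + 1))
    for i, row in enumerate(groups.itertuples(index=False)):
        p0 = life_table.monthly_death_prob_path(row.sex, row.age, row.year, n_months)
        p = excess.apply(p0)
        S[i, 0] = 1.0
        np.cumprod(1.0 - p, out=S[i, 1:])
    return S


def _sample_death_months(S_group: np.ndarray, group_idx: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw T (the grid month at which the curve drops) per patient."""
    u = rng.random(group_idx.size)
    T = np.empty(group_idx.size, dtype=int)
    for g in np.unique(group_idx):
        mask = group_idx == g
        neg = -S_group[g]
        T[mask] = np.searchsorted(neg, -u[mask], side="right")
    return np.minimum(T, S_group.shape[1] - 1)


def _expected_discounted_cost(S_group: np.ndarray, spec: CostSpec,
                              rate: float) -> np.ndarray:
    """Per group: E[ sum over months lived of discounted cost ] (both streams)."""
    n_months = S_group.shape[1] - 1
    m = np.arange(n_months)
    disc = np.power(1.0 + rate, -m / 12.0)
    S = S_group
    K = spec.surge_window
    S_mK = np.zeros_like(S[:, :-1])
    upto = np.minimum(m + K, n_months)
    S_mK[:, :] = S[:, upto]
    # alive at m and within K months of death -> surge applies
    p_surge = S[:, :-1] - S_mK
    mean_cost = spec.baseline_monthly * (spec.surge_multiplier * p_surge + S_mK)
    return (mean_cost * disc[None, :]).sum(axis=1)


def generate_cohort(scenario: SyntheticScenario,
                    life_table: LifeTable) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a claims-line table and its ground truth.

    The claims table follows the documented CSV schema (one row per claim
    line) and contains, per patient: an index admission line with the
    subtype ICD-10 code and imaging/severity procedure codes, pre-index
    comorbidity lines, optional washout-period noise, and monthly cost lines
    until death or administrative censoring.  Ground truth records the
    *uncensored* death month of every patient and the analytic cohort-level
    survival, life expectancy, EYLL and expected discounted lifetime costs.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_patients
    admin_start = pd.Timestamp(scenario.admin_start)
    admin_end = pd.Timestamp(scenario.admin_end)
    index_end = pd.Timestamp(scenario.index_end or scenario.admin_end)
    washout_start = pd.Timestamp(scenario.washout_start)
    washout_end = pd.Timestamp(scenario.washout_end)

    ages_avail = np.array(sorted(scenario.age_distribution), dtype=int)
    w = np.array([scenario.age_distribution[a] for a in ages_avail], dtype=float)
    w = w / w.sum()

    sex = np.where(rng.random(n) < scenario.sex_ratio, "M", "F")
    age = rng.choice(ages_avail, size=n, p=w)
    subtypes = np.array(list(scenario.subtype_weights))
    subtype = rng.choice(subtypes, size=n,
                         p=np.array([scenario.subtype_weights[s] for s in subtypes]))
    span_days = max((index_end - admin_start).days, 0)
    index_offset = rng.integers(0, span_days + 1, size=n)
    index_date = admin_start + pd.to_timedelta(index_offset, unit="D")
    index_year = index_date.year.to_numpy()
    birth_year = index_year - age

    # --- true death process -------------------------------------------------
    min_age = int(age.min())
    n_months = (life_table.max_age - min_age) * 12 + 12
    pdf = pd.DataFrame({"sex": sex, "age": age, "year": index_year})
    groups = pdf.drop_duplicates().reset_index(drop=True)
    key = groups["sex"] + "|" + groups["age"].astype(str) + "|" + groups["year"].astype(str)
    gmap = {k: i for i, k in enumerate(key)}
    group_idx = (pdf["sex"] + "|" + pdf["age"].astype(str) + "|"
                 + pdf["year"].astype(str)).map(gmap).to_numpy()

    S_index = _group_survival(life_table, groups, scenario.excess_hazard, n_months)
    S_ref = (S_index if scenario.excess_hazard.is_null()
             else _group_survival(life_table, groups, ExcessHazard.null(), n_months))
    T = _sample_death_months(S_index, group_idx, rng)

    counts = np.bincount(group_idx, minlength=len(groups)).astype(float)
    wts = counts / counts.sum()
    true_curve = SurvivalCurve(
        months=np.arange(n_months + 1), surv=wts @ S_index,
        provenance="referent-MC" if scenario.excess_hazard.is_null() else "index-KM",
    )
    true_ref = SurvivalCurve(months=np.arange(n_months + 1), surv=wts @ S_ref,
                             provenance="referent-MC")
    le = true_curve.restricted_mean(n_months)
    le_ref = true_ref.restricted_mean(n_months)
    costs = {}
    for rate in (0.0, 0.03, 0.05):
        total = float(wts @ _expected_discounted_cost(S_index, scenario.cost_spec, rate))
        costs[rate] = {
            "insurer": total * (1 - scenario.cost_spec.copay_share),
            "copay": total * scenario.cost_spec.copay_share,
            "total": total,
        }

    # --- observed claims ----------------------------------------------------
    pid = np.array([f"P{i:06d}" for i in range(n)])
    death_date = index_date + pd.to_timedelta(
        np.rint(T * DAYS_PER_MONTH).astype(int), unit="D")
    died_in_window = death_date <= admin_end
    death_str = np.where(died_in_window, death_date.strftime("%Y-%m-%d"), "")

    has_admission = rng.random(n) >= scenario.nonhosp_rate
    has_imaging = rng.random(n) >= scenario.no_imaging_rate
    has_washout_noise = rng.random(n) < scenario.washout_noise_rate
    insurance = rng.choice(["self-employed", "employed", "medical-aid"],
                           size=n, p=[0.34, 0.55, 0.11])
    residence = rng.choice(["capital", "metropolitan", "other"],
                           size=n, p=[0.16, 0.24, 0.60])

    demo = pd.DataFrame({
        "patient_id": pid, "sex": sex, "birth_year": birth_year,
        "insurance_type": insurance, "residence": residence,
        "death_date": death_str,
    })

    frames = []

    def lines(mask, dates, setting, dx, procs, insurer, copay):
        d = demo.loc[mask].reset_index(drop=True)
        d.insert(1, "date", pd.Series(dates).dt.strftime("%Y-%m-%d").to_numpy())
        d.insert(2, "setting", setting)
        d.insert(3, "primary_dx", dx)
        d.insert(4, "procedure_codes", procs)
        d.insert(5, "insurer_paid", insurer)
        d.insert(6, "copay", copay)
        frames.append(d)

    # index event line (inpatient admission, or outpatient if suppressed)
    severity_base = {"SAH": 0.75, "ICH": 0.65, "NIH": 0.55, "CI": 0.30}
    rel = np.array([0.9, 0.5, 0.6, 0.7, 0.4])
    sev = np.array([severity_base[s] for s in subtype])
    proc_list = []
    imaging_choice = rng.choice(IMAGING_CODES, size=n, p=[0.55, 0.45])
    sev_draw = rng.random((n, len(SEVERITY_CODES))) < sev[:, None] * rel[None, :]
    for i in range(n):
        codes = []
        if has_admission[i] and has_imaging[i]:
            codes.append(imaging_choice[i])
        if has_admission[i]:
            codes.extend(c for j, c in enumerate(SEVERITY_CODES) if sev_draw[i, j])
        proc_list.append(";".join(codes))
    dx_codes = np.array([SUBTYPE_CODES[s] for s in subtype])
    lines(np.ones(n, bool), pd.Series(index_date),
          np.where(has_admission, "inpatient", "outpatient"),
          dx_codes, np.array(proc_list), 0.0, 0.0)

    # extra outpatient stroke visits for patients without an admission
    nonhosp_idx = np.flatnonzero(~has_admission)
    if nonhosp_idx.size:
        extra = rng.integers(0, 4, size=nonhosp_idx.size)
        rep = np.repeat(nonhosp_idx, extra)
        if rep.size:
            offs = rng.integers(7, 120, size=rep.size)
            d = demo.iloc[rep].reset_index(drop=True)
            dts = (pd.Series(index_date[rep]) + pd.to_timedelta(offs, unit="D"))
            d.insert(1, "date", dts.dt.strftime("%Y-%m-%d").to_numpy())
            d.insert(2, "setting", "outpatient")
            d.insert(3, "primary_dx", dx_codes[rep])
            d.insert(4, "procedure_codes", "")
            d.insert(5, "insurer_paid", 0.0)
            d.insert(6, "copay", 0.0)
            frames.append(d)

    # washout-period noise (any I60-I69 record before the window)
    noise_idx = np.flatnonzero(has_washout_noise)
    if noise_idx.size:
        wspan = (washout_end - washout_start).days
        offs = rng.integers(0, wspan + 1, size=noise_idx.size)
        d = demo.iloc[noise_idx].reset_index(drop=True)
        dts = washout_start + pd.to_timedelta(offs, unit="D")
        d.insert(1, "date", pd.Series(dts).dt.strftime("%Y-%m-%d").to_numpy())
        d.insert(2, "setting", "outpatient")
        d.insert(3, "primary_dx", rng.choice(WASHOUT_CODES, size=noise_idx.size))
        d.insert(4, "procedure_codes", "")
        d.insert(5, "insurer_paid", 0.0)
        d.insert(6, "copay", 0.0)
        frames.append(d)

    # pre-index comorbidity history
    for cond, codes in COMORBIDITY_CODES.items():
        has = np.flatnonzero(rng.random(n) < _COMORBIDITY_PREV[cond])
        if not has.size:
            continue
        back = rng.integers(30, 1200, size=has.size)
        dts = pd.Series(index_date[has]) - pd.to_timedelta(back, unit="D")
        dts = dts.clip(lower=washout_start)
        keep = dts < pd.Series(index_date[has]).reset_index(drop=True)
        d = demo.iloc[has].reset_index(drop=True)[keep.to_numpy()]
        d.insert(1, "date", dts[keep.to_numpy()].dt.strftime("%Y-%m-%d").to_numpy())
        d.insert(2, "setting", "outpatient")
        d.insert(3, "primary_dx", rng.choice(codes, size=len(d)))
        d.insert(4, "procedure_codes", "")
        d.insert(5, "insurer_paid", 0.0)
        d.insert(6, "copay", 0.0)
        frames.append(d)

    # monthly cost lines until death or administrative censoring
    months_in_window = ((admin_end - index_date).days.to_numpy()
                        // DAYS_PER_MONTH).astype(int)
    n_cost = np.clip(np.minimum(T, months_in_window + 1), 0, None)
    rep = np.repeat(np.arange(n), n_cost)
    if rep.size:
        month_of = np.concatenate([np.arange(k) for k in n_cost]) if rep.size else np.array([], int)
        to_death = T[rep] - month_of
        mean = scenario.cost_spec.mean_monthly(to_death)
        sig = scenario.cost_spec.lognormal_sigma
        noise = rng.lognormal(mean=-0.5 * sig ** 2, sigma=sig, size=rep.size)
        total = mean * noise
        d = demo.iloc[rep].reset_index(drop=True)
        dts = (pd.Series(index_date[rep])
               + pd.to_timedelta(np.rint(month_of * DAYS_PER_MONTH).astype(int), unit="D"))
        d.insert(1, "date", dts.dt.strftime("%Y-%m-%d").to_numpy())
        d.insert(2, "setting", rng.choice(["outpatient", "pharmacy"], size=rep.size,
                                          p=[0.7, 0.3]))
        d.insert(3, "primary_dx", dx_codes[rep])
        d.insert(4, "procedure_codes", "")
        d.insert(5, "insurer_paid", np.round(total * (1 - scenario.cost_spec.copay_share), 2))
        d.insert(6, "copay", np.round(total * scenario.cost_spec.copay_share, 2))
        frames.append(d)

    claims = pd.concat([f for f in frames if f is not None and len(f)],
                       ignore_index=True)[CLAIMS_COLUMNS]
    claims = claims.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)

    truth_patients = pd.DataFrame({
        "patient_id": pid, "sex": sex, "age_at_index": age,
        "index_date": pd.Series(index_date).dt.strftime("%Y-%m-%d"),
        "subtype": subtype, "true_death_month": T,
        "died_in_window": died_in_window,
        "has_admission": has_admission, "has_imaging": has_imaging,
        "washout_noise": has_washout_noise,
    })
    truth = GroundTruth(patients=truth_patients, survival=true_curve,
                        reference=true_ref, le=le, le_ref=le_ref,
                        eyll=le_ref - le, costs=costs)
    return claims, truth


# ---------------------------------------------------------------------------
# census denominators

def generate_census(life_table: LifeTable, base_population,
                    periods: list, annual_growth: float = 0.0) -> pd.DataFrame:
    """Person-count denominators per sex x age band x two-year period.

    ``base_population`` is the count per single year of age and sex in the
    first period: a scalar (same everywhere) or ``{sex: scalar}``.  The
    population grows (or shrinks) by ``annual_growth`` per calendar year.
    Age bands follow the lifetime-risk convention: 18-24 (width 7) then
    5-year bands up to 80-84.
    """
    from .risk import AGE_BANDS, band_label
    if not periods:
        raise ValueError("periods must be non-empty")
    periods = [tuple(p) for p in periods]
    first = periods[0][0]
    rows = []
    for (y0, y1) in periods:
        if y1 < y0:
            raise ValueError(f"invalid period ({y0}, {y1})")
        factor = (1.0 + annual_growth) ** (y0 - first)
        for sex in SEXES:
            base = base_population[sex] if isinstance(base_population, dict) \
                else base_population
            if base <= 0:
                raise ValueError("base_population must be positive")
            for (lo, hi) in AGE_BANDS:
                width = hi - lo + 1
                rows.append({
                    "sex": sex, "age_group": band_label(lo, hi),
                    "period": f"{y0}-{y1}",
                    "population": float(base) * width * factor,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study-like subtype profiles

#: age-group mixes (18-44, 45-54, 55-64, 65-74, 75-84, 85+) per stroke subtype
_AGE_MIX = {
    "SAH": (0.194, 0.290, 0.241, 0.161, 0.094, 0.020),
    "ICH": (0.109, 0.221, 0.234, 0.224, 0.179, 0.033),
    "NIH": (0.104, 0.148, 0.159, 0.295, 0.238, 0.055),
    "CI":  (0.042, 0.122, 0.197, 0.307, 0.278, 0.054),
}
_AGE_BINS = ((18, 44), (45, 54), (55, 64), (65, 74), (75, 84), (85, 94))
_SEX_RATIO = {"SAH": 0.388, "ICH": 0.570, "NIH": 0.677, "CI": 0.543}
_COHORT_N = {"SAH": 1182, "ICH": 2022, "NIH": 508, "CI": 2282}
# Declining multiplicative excess hazard: high acute-phase mortality that
# settles to a moderate chronic excess, severity ordered by subtype.
_EXCESS = {
    "SAH": (12.0, 5.0, 2.5, 1.8),
    "ICH": (9.0, 4.0, 2.2, 1.6),
    "NIH": (7.0, 3.0, 2.0, 1.5),
    "CI":  (4.0, 2.5, 1.8, 1.4),
}
_EXCESS_BREAKS = (0, 6, 12, 24)


def _mix_to_age_weights(mix) -> dict:
    weights = {}
    for (lo, hi), p in zip(_AGE_BINS, mix):
        ages = np.arange(lo, hi + 1)
        for a in ages:
            weights[int(a)] = weights.get(int(a), 0.0) + p / ages.size
    return weights


def subtype_scenario(subtype: str, seed: int = 0,
                     n_patients: int | None = None) -> SyntheticScenario:
    """A study-conditions scenario for one stroke subtype.

    Cohort sizes, sex ratios and age mixes mirror the published baseline
    composition (cerebral infarction scaled down to n = 2282 to keep desk-
    scale runtimes); index events fall in the first half-year of the
    10-year administrative window so that ten years of potential follow-up
    exist for the 5-to-10-year extrapolation validation.
    """
    if subtype not in SUBTYPES:
        raise ValueError(f"unknown subtype {subtype!r}")
    return SyntheticScenario(
        seed=seed,
        n_patients=n_patients or _COHORT_N[subtype],
        age_distribution=_mix_to_age_weights(_AGE_MIX[subtype]),
        sex_ratio=_SEX_RATIO[subtype],
        subtype_weights={s: (1.0 if s == subtype else 0.0) for s in SUBTYPES},
        excess_hazard=ExcessHazard(breakpoints=_EXCESS_BREAKS,
                                   values=_EXCESS[subtype]),
        index_end="2006-06-30",
    )


def null_scenario(seed: int = 0, n_patients: int = 1000) -> SyntheticScenario:
    """Zero-excess-hazard cohort: survival equals the matched referents."""
    return SyntheticScenario(seed=seed, n_patients=n_patients,
                             excess_hazard=ExcessHazard.null(),
                             index_end="2006-06-30")


def multiplier_scenario(multiplier: float, seed: int = 0,
                        n_patients: int = 1500) -> SyntheticScenario:
    """Constant multiplicative excess hazard (parameter-recovery scenarios)."""
    return SyntheticScenario(seed=seed, n_patients=n_patients,
                             excess_hazard=ExcessHazard.constant(multiplier),
                             index_end="2006-06-30")
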