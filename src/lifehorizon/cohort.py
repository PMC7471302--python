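"""Index-cohort construction from raw claims lines.

Reproduces the inclusion/exclusion cascade of a first-ever-stroke claims
study: a patient enters the index cohort when their first I60-I63 primary
diagnosis falls inside the study window AND they have no I60-I69 record in
the washout years (prevalent cases and sequelae), an inpatient admission,
a CT/MRI imaging procedure around the index admission, accurate adult age,
and a consistent (single-subtype) diagnosis on the index date.  Patients
failing a criterion are counted once, against the first failed criterion,
in a ledger whose counts always conserve the input patient total.

Subtype assignment follows the index primary diagnosis: I60 -> SAH,
I61 -> ICH, I62 -> NIH, I63 -> CI.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import days_to_months

logger = logging.getLogger(__name__)

STROKE_PREFIXES = ("I60", "I61", "I62", "I63")
ANY_STROKE_RE = re.compile(r"^I6[0-9]")
ICD10_RE = re.compile(r"^[A-Z][0-9]{2}")
SUBTYPE_BY_PREFIX = {"I60": "SAH", "I61": "ICH", "I62": "NIH", "I63": "CI"}

EXCLUSION_ORDER = (
    "washout_stroke_record",
    "no_hospital_admission",
    "no_imaging_record",
    "inaccurate_or_under_age",
    "inconsistent_index_diagnosis",
)


@dataclass(frozen=True)
class SSIConfig:
    """Claims-based stroke severity index: a linear score over first-stay
    service-use indicators, clipped to [score_min, score_max].  Higher is
    more severe.  Coefficients are inputs (placeholders shipped); the
    default bounds 4.1-27.11 follow the published score range."""

    intercept: float = 4.1
    coefficients: dict = field(default_factory=lambda: {
        "ICU": 4.0, "AIRWAY": 3.0, "NGTUBE": 2.5, "FOLEY": 2.0, "REHAB": 1.5})
    score_min: float = 4.1
    score_max: float = 27.11

    def __post_init__(self):
        if not self.score_min < self.score_max:
            raise ValueError("score_min must be < score_max")


@dataclass(frozen=True)
class CohortConfig:
    """Code sets and windows used by the cascade (YAML-overridable)."""

    imaging_codes: tuple = ("CT01", "MRI01")
    #: days before/after the index date in which an imaging record qualifies
    imaging_window_days: tuple = (7, 30)
    comorbidity_codes: dict = field(default_factory=lambda: {
        "AF": ("I48",), "CHF": ("I50",), "CKD": ("N18",), "COPD": ("J44",),
        "diabetes": ("E10", "E11", "E12", "E13", "E14"),
        "hyperlipidemia": ("E78",), "hypertension": ("I10", "I11", "I12", "I13", "I15"),
        "IHD": ("I20", "I21", "I22", "I23", "I24", "I25"), "TIA": ("G45",)})
    min_age: int = 18
    #: birth years before this are treated as inaccurate age records
    min_birth_year: int | None = None
    ssi: SSIConfig = field(default_factory=SSIConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "ssi" in d and isinstance(d["ssi"], dict):
            d["ssi"] = SSIConfig(**d["ssi"])
        if "imaging_codes" in d:
            d["imaging_codes"] = tuple(d["imaging_codes"])
        if "imaging_window_days" in d:
            d["imaging_window_days"] = tuple(d["imaging_window_days"])
        if "comorbidity_codes" in d:
            d["comorbidity_codes"] = {k: tuple(v)
                                      for k, v in d["comorbidity_codes"].items()}
        return cls(**d)


def _prepare(claims: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Parse dates, drop malformed ICD-10 codes (with a counted warning)."""
    df = claims.copy()
    df["date"] = pd.to_datetime(df["date"])
    dx = df["primary_dx"].astype(str)
    bad = ~dx.str.match(ICD10_RE)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("skipping %d claim lines with malformed ICD-10 codes", n_bad)
        df = df[~bad]
    return df, n_bad


def build_cohort(claims: pd.DataFrame, window: tuple, washout: tuple,
                 config: CohortConfig | None = None,
                 ) -> tuple[pd.DataFrame, dict]:
    """Apply the inclusion/exclusion cascade.

    Parameters
    ----------
    claims : claims-line table in the documented CSV schema.
    window : (start, end) of the enrolment window (index events).
    washout : (start, end) of the pre-window washout scan, strictly before
        the window.

    Returns
    -------
    (patients, ledger) : the retained PatientRecord table (one row per
    patient: demographics, subtype, index/death/censor dates, follow-up
    months, event indicator) and a ledger dict with the count removed by
    each criterion, in cascade order, plus conservation totals.
    """
    config = config or CohortConfig()
    w_start, w_end = (pd.Timestamp(x) for x in window)
    wo_start, wo_end = (pd.Timestamp(x) for x in washout)
    if wo_end >= w_start:
        raise ValueError("washout must precede the enrolment window")

    df, n_skipped = _prepare(claims)
    ledger: dict = {"skipped_malformed_lines": n_skipped}
    dx = df["primary_dx"].astype(str)
    is_index_dx = dx.str.startswith(STROKE_PREFIXES)
    is_any_stroke = dx.str.match(ANY_STROKE_RE)

    in_window = df["date"].between(w_start, w_end)
    candidates = df[is_index_dx & in_window]
    if candidates.empty:
        ledger.update({"input_patients": 0,
                       **{k: 0 for k in EXCLUSION_ORDER}, "retained": 0})
        return _empty_patients(), ledger

    index_date = candidates.groupby("patient_id")["date"].min()
    ids = index_date.index.to_numpy()
    ledger["input_patients"] = len(ids)

    # criterion 1: any I60-I69 record during the washout years
    washout_hit = set(df.loc[is_any_stroke
                             & df["date"].between(wo_start, wo_end), "patient_id"])
    # criterion 2: an inpatient admission carrying a stroke diagnosis
    admitted = set(df.loc[is_index_dx & in_window
                          & (df["setting"] == "inpatient"), "patient_id"])
    # criterion 3: an imaging procedure around the index admission
    pre, post = config.imaging_window_days
    procs = df["procedure_codes"].fillna("").astype(str).str.split(";")
    has_imaging_code = procs.apply(
        lambda cs: any(c in config.imaging_codes for c in cs))
    img = df[has_imaging_code].merge(index_date.rename("index_date"),
                                     left_on="patient_id", right_index=True)
    img_ok = set(img.loc[
        (img["date"] >= img["index_date"] - pd.Timedelta(days=pre))
        & (img["date"] <= img["index_date"] + pd.Timedelta(days=post)),
        "patient_id"])

    demo = (df.sort_values("date")
            .groupby("patient_id")[["sex", "birth_year", "insurance_type",
                                    "residence", "death_date"]].first())
    # criterion 4: accurate adult age at index
    age_at_index = index_date.dt.year - demo.loc[ids, "birth_year"]
    # criterion 5: a single stroke subtype among index-date primary codes
    on_index = df[is_index_dx].merge(index_date.rename("index_date"),
                                     left_on="patient_id", right_index=True)
    on_index = on_index[on_index["date"] == on_index["index_date"]]
    n_subtypes = (on_index.assign(prefix=on_index["primary_dx"].str[:3])
                  .groupby("patient_id")["prefix"].nunique())

    counts = {k: 0 for k in EXCLUSION_ORDER}
    retained, excluded_no_admission = [], []
    for pid in ids:
        if pid in washout_hit:
            counts["washout_stroke_record"] += 1
        elif pid not in admitted:
            counts["no_hospital_admission"] += 1
            excluded_no_admission.append(pid)
        elif pid not in img_ok:
            counts["no_imaging_record"] += 1
        elif age_at_index[pid] < config.min_age or (
                config.min_birth_year is not None
                and demo.loc[pid, "birth_year"] < config.min_birth_year):
            counts["inaccurate_or_under_age"] += 1
        elif n_subtypes.get(pid, 0) != 1:
            counts["inconsistent_index_diagnosis"] += 1
        else:
            retained.append(pid)
    ledger.update(counts)
    ledger["retained"] = len(retained)
    ledger["excluded_no_admission_ids"] = sorted(excluded_no_admission)

    if not retained:
        return _empty_patients(), ledger

    subtype = (on_index[on_index["patient_id"].isin(retained)]
               .assign(prefix=lambda x: x["primary_dx"].str[:3])
               .groupby("patient_id")["prefix"].first().map(SUBTYPE_BY_PREFIX))
    patients = pd.DataFrame({
        "patient_id": retained,
        "sex": demo.loc[retained, "sex"].to_numpy(),
        "birth_year": demo.loc[retained, "birth_year"].to_numpy(),
        "age_at_index": age_at_index[retained].astype(int).to_numpy(),
        "index_date": index_date[retained].to_numpy(),
        "subtype": subtype[retained].to_numpy(),
        "insurance_type": demo.loc[retained, "insurance_type"].to_numpy(),
        "residence": demo.loc[retained, "residence"].to_numpy(),
        "death_date": pd.to_datetime(
            demo.loc[retained, "death_date"].replace("", pd.NA)).to_numpy(),
    }).reset_index(drop=True)

    died = patients["death_date"].notna() & (patients["death_date"] <= w_end)
    end = np.where(died, patients["death_date"], np.datetime64(w_end))
    followup_days = (pd.Series(end) - patients["index_date"]).dt.days
    patients["event"] = died.astype(int)
    patients["followup_months"] = days_to_months(followup_days)
    return patients, ledger


def _empty_patients() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "patient_id", "sex", "birth_year", "age_at_index", "index_date",
        "subtype", "insurance_type", "residence", "death_date", "event",
        "followup_months"])


def flag_outpatient_comparators(claims: pd.DataFrame,
                                excluded_ids) -> set:
    """Among patients excluded for lacking a hospital admission, those with
    at least three *distinct* outpatient visit dates carrying a stroke
    diagnosis (claims commonly split one visit across lines)."""
    df, _ = _prepare(claims)
    df = df[df["patient_id"].isin(set(excluded_ids))
            & (df["setting"] == "outpatient")
            & df["primary_dx"].astype(str).str.startswith(STROKE_PREFIXES)]
    n_dates = df.groupby("patient_id")["date"].nunique()
    return set(n_dates[n_dates >= 3].index)


def flag_comorbidities(claims: pd.DataFrame, patients: pd.DataFrame,
                       lookback_start, config: CohortConfig | None = None,
                       ) -> pd.DataFrame:
    """Add one boolean column per comorbidity: true iff at least one
    qualifying record falls strictly before the index date (and on/after
    ``lookback_start``)."""
    config = config or CohortConfig()
    required = {"AF", "CHF", "CKD", "COPD", "diabetes", "hyperlipidemia",
                "hypertension", "IHD", "TIA"}
    missing = required - set(config.comorbidity_codes)
    if missing:
        raise ValueError(f"comorbidity code map missing conditions {sorted(missing)}")
    df, _ = _prepare(claims)
    lookback_start = pd.Timestamp(lookback_start)
    out = patients.copy()
    idx = patients.set_index("patient_id")["index_date"]
    df = df[df["patient_id"].isin(idx.index)].merge(
        idx.rename("index_date"), left_on="patient_id", right_index=True)
    before = df[(df["date"] >= lookback_start) & (df["date"] < df["index_date"])]
    dx = before["primary_dx"].astype(str)
    for cond, prefixes in config.comorbidity_codes.items():
        hit = set(before.loc[dx.str.startswith(tuple(prefixes)), "patient_id"])
        out[cond] = out["patient_id"].isin(hit)
    return out


def first_stay_indicators(claims: pd.DataFrame, patients: pd.DataFrame,
                          config: CohortConfig | None = None,
                          episode_days: int = 30) -> pd.DataFrame:
    """Boolean service-use indicators from procedure codes on inpatient
    lines within the index admission episode, one row per patient."""
    config = config or CohortConfig()
    df, _ = _prepare(claims)
    idx = patients.set_index("patient_id")["index_date"]
    df = df[(df["setting"] == "inpatient") & df["patient_id"].isin(idx.index)]
    df = df.merge(idx.rename("index_date"), left_on="patient_id", right_index=True)
    df = df[(df["date"] >= df["index_date"])
            & (df["date"] <= df["index_date"] + pd.Timedelta(days=episode_days))]
    names = list(config.ssi.coefficients)
    out = pd.DataFrame(False, index=patients["patient_id"], columns=names)
    codes = df["procedure_codes"].fillna("").astype(str).str.split(";")
    for pid, cs in zip(df["patient_id"], codes):
        for c in cs:
            if c in out.columns:
                out.loc[pid, c] = True
    return out.reset_index()


def compute_ssi(indicators: pd.DataFrame, config: SSIConfig | None = None) -> pd.Series:
    """Stroke severity index per patient: intercept + sum(coef x indicator),
    clipped to the configured score range.  Indicator columns absent from
    the config are ignored with a warning."""
    config = config or SSIConfig()
    df = indicators.set_index("patient_id") if "patient_id" in indicators.columns \
        else indicators
    extra = set(df.columns) - set(config.coefficients)
    if extra:
        logger.warning("ignoring indicators not in SSI config: %s", sorted(extra))
    score = pd.Series(float(config.intercept), index=df.index, name="ssi")
    for name, coef in config.coefficients.items():
        if name in df.columns:
            score = score + coef * df[name].astype(float)
    return score.clip(config.score_min, config.score_max)


def monthly_costs(claims: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Per-patient monthly cost streams from the index month onward.

    Aggregates every claim line (any setting, pharmacy included) dated on or
    after the patient's index date into 30.4375-day months since index.
    Returns a long table (patient_id, month, insurer, copay); months without
    any claim are absent (they count as zero when averaging).
    """
    df, _ = _prepare(claims)
    if (df["insurer_paid"] < 0).any() or (df["copay"] < 0).any():
        raise ValueError("negative cost amounts in claims")
    idx = patients.set_index("patient_id")["index_date"]
    df = df[df["patient_id"].isin(idx.index)].merge(
        idx.rename("index_date"), left_on="patient_id", right_index=True)
    df = df[df["date"] >= df["index_date"]]
    days = (df["date"] - df["index_date"]).dt.days
    df = df.assign(month=days_to_months(days))
    out = (df.groupby(["patient_id", "month"])[["insurer_paid", "copay"]]
           .sum().reset_index()
           .rename(columns={"insurer_paid": "insurer"}))
    return out
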