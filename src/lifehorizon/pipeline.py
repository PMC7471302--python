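"""End-to-end orchestration: synthesize -> build -> estimate -> costs -> risk.

`run_all` drives every stage off a single resolved configuration dict,
writes one artifact per stage into the output directory, and stamps every
run with a manifest carrying the exact configuration and its hash, so a
rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import costs as costs_mod
from . import risk as risk_mod
from .extrapolation import (DEFAULT_WINDOW, bootstrap_se, estimate_lifetime,
                            validate_extrapolation)
from .synthetic import (SyntheticScenario, generate_census, generate_cohort,
                        generate_life_table)

logger = logging.getLogger(__name__)

def validation_twin(seed: int = 0, fit_months: int = 60,
                    test_months: int = 120) -> pd.DataFrame:
    """The four-cohort extrapolation validation study.

    For each stroke-subtype profile, generates its study-conditions cohort,
    rebuilds it from the claims lines, censors follow-up at ``fit_months``,
    extrapolates to ``test_months`` against Monte-Carlo referents, and
    compares restricted mean survival with the full-data Kaplan-Meier
    estimate.  Returns one row per subtype with the relative bias.  All
    sub-seeds derive deterministically from ``seed``.
    """
    from .synthetic import SUBTYPES, subtype_scenario

    lt = generate_life_table(2002, 2015)
    ss = np.random.SeedSequence(seed)
    rows = []
    for subtype, child in zip(SUBTYPES, ss.spawn(len(SUBTYPES))):
        scen_seed, ref_seed = (int(s) for s in child.generate_state(2) >> 1)
        scenario = subtype_scenario(subtype, seed=scen_seed)
        claims, _ = generate_cohort(scenario, lt)
        patients, ledger = cohort_mod.build_cohort(
            claims, (scenario.admin_start, scenario.admin_end),
            (scenario.washout_start, scenario.washout_end))
        res = validate_extrapolation(patients, lt, fit_months, test_months,
                                     seed=ref_seed)
        rows.append({"subtype": subtype, "n": ledger["retained"],
                     "extrapolated_rmst": res.extrapolated,
                     "observed_rmst": res.observed,
                     "relative_bias": res.relative_bias})
    return pd.DataFrame(rows)


DEFAULT_CONFIG = {
    "seed": 0,
    "scenario": {
        "n_patients": 2000,
        "washout_noise_rate": 0.05,
        "nonhosp_rate": 0.08,
        "no_imaging_rate": 0.03,
        "index_end": "2006-12-31",
    },
    "life_table": {"first_year": 2002, "last_year": 2015, "max_age": 110},
    "window": {"start": "2006-01-01", "end": "2015-12-31"},
    "washout": {"start": "2002-01-01", "end": "2005-12-31"},
    "estimation": {
        "n_replicates": 100,
        "rolling_window": DEFAULT_WINDOW,
        "bootstrap_B": 0,          # 0 disables bootstrap SEs
        "min_subtype_n": 30,
    },
    "costs": {"discount_rates": [0.0, 0.03, 0.05], "krw_per_usd": 1131.2},
    "risk": {"sampling_fraction": 0.02, "base_population": 50_000},
    "validation": {"fit_months": 60, "test_months": 120},
    "write_claims": False,
}

_REQUIRED = {
    "seed": int,
    "scenario": dict, "life_table": dict, "window": dict, "washout": dict,
    "estimation": dict, "costs": dict, "risk": dict, "validation": dict,
}


def resolve_config(overrides: dict | None = None) -> dict:
    """Merge user overrides into the defaults (one level deep) and validate."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    errors = []
    for key, typ in _REQUIRED.items():
        if key not in cfg:
            errors.append(f"missing field: {key}")
        elif not isinstance(cfg[key], typ):
            errors.append(f"field {key}: expected {typ.__name__}, "
                          f"got {type(cfg[key]).__name__}")
    for sub, field_name in (("window", "start"), ("window", "end"),
                            ("washout", "start"), ("washout", "end"),
                            ("life_table", "first_year"),
                            ("life_table", "last_year")):
        if isinstance(cfg.get(sub), dict) and cfg[sub].get(field_name) is None:
            errors.append(f"missing field: {sub}.{field_name}")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def run_all(config: dict | None = None, out_dir="results") -> dict:
    """Run the whole pipeline; returns the bundle also written to disk."""
    cfg = resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stamp = {"config": cfg, "config_hash": config_hash(cfg)}

    # -- synthesize ----------------------------------------------------------
    lt = generate_life_table(**cfg["life_table"])
    scenario = SyntheticScenario(seed=seed, **cfg["scenario"])
    claims, truth = generate_cohort(scenario, lt)
    logger.info("simulated %d patients -> %d claim lines",
                scenario.n_patients, len(claims))
    lt.write_csv(out / "lifetable.csv")
    if cfg.get("write_claims"):
        claims.to_csv(out / "claims.csv", index=False)

    # -- build cohort --------------------------------------------------------
    ccfg = cohort_mod.CohortConfig()
    patients, ledger = cohort_mod.build_cohort(
        claims, (cfg["window"]["start"], cfg["window"]["end"]),
        (cfg["washout"]["start"], cfg["washout"]["end"]), ccfg)
    comparators = cohort_mod.flag_outpatient_comparators(
        claims, ledger.pop("excluded_no_admission_ids", []))
    ledger["outpatient_comparators"] = len(comparators)
    patients = cohort_mod.flag_comorbidities(
        claims, patients, cfg["washout"]["start"], ccfg)
    indicators = cohort_mod.first_stay_indicators(claims, patients, ccfg)
    ssi = cohort_mod.compute_ssi(indicators, ccfg.ssi)
    patients = patients.merge(ssi.rename("ssi"), left_on="patient_id",
                              right_index=True, how="left")
    logger.info("cohort: %d retained of %d (ledger %s)",
                len(patients), ledger["input_patients"],
                {k: ledger[k] for k in cohort_mod.EXCLUSION_ORDER})
    patients.to_csv(out / "cohort.csv", index=False)
    (out / "ledger.json").write_text(json.dumps(ledger, indent=2))

    # -- baseline summary (table-1 shape) ------------------------------------
    baseline = {}
    for subtype, sub in patients.groupby("subtype", observed=True):
        baseline[subtype] = {
            "n": int(len(sub)),
            "pct_male": round(100 * (sub["sex"] == "M").mean(), 1),
            "mean_age": round(float(sub["age_at_index"].mean()), 1),
            "median_ssi": round(float(sub["ssi"].median()), 1),
            "comorbidity_pct": {
                c: round(100 * float(sub[c].mean()), 1)
                for c in ccfg.comorbidity_codes},
        }
    (out / "baseline.json").write_text(json.dumps(baseline, indent=2))

    # -- survival, EYLL, costs per subtype -----------------------------------
    est_cfg = cfg["estimation"]
    costs_long = cohort_mod.monthly_costs(claims, patients)
    estimates = []
    for i, (subtype, sub) in enumerate(patients.groupby("subtype", observed=True)):
        if len(sub) < est_cfg["min_subtype_n"]:
            logger.info("skipping subtype %s (n=%d too small)", subtype, len(sub))
            continue
        est, lifetime, _ = estimate_lifetime(
            sub.reset_index(drop=True), lt,
            n_replicates=est_cfg["n_replicates"], seed=seed + 1000 + i,
            window=est_cfg["rolling_window"])
        row = est.to_dict()
        if est_cfg["bootstrap_B"] >= 2:
            ses = bootstrap_se(sub.reset_index(drop=True), lt,
                               B=est_cfg["bootstrap_B"], seed=seed + 2000 + i,
                               n_replicates=est_cfg["n_replicates"],
                               window=est_cfg["rolling_window"])
            row.update({"se_le": ses["le"], "se_le_ref": ses["le_ref"],
                        "se_eyll": ses["eyll"], "se_mean_age": ses["mean_age"]})
        profile = costs_mod.monthly_mean_costs(sub, costs_long)
        profile = costs_mod.extrapolate_costs(profile, lifetime)
        row["lifetime_costs_usd"] = {}
        for rate in cfg["costs"]["discount_rates"]:
            lc = costs_mod.lifetime_cost(profile, lifetime,
                                         costs_mod.DiscountSpec(rate))
            row["lifetime_costs_usd"][f"{rate:.2f}"] = {
                k: round(costs_mod.convert_currency(
                    lc[k], cfg["costs"]["krw_per_usd"]), 2)
                for k in ("insurer", "copay", "total")}
        lifetime.write_csv(out / f"survival_{subtype}.csv")
        estimates.append(row)
    (out / "estimates.json").write_text(json.dumps(estimates, indent=2))

    # -- lifetime risk (CIR series) ------------------------------------------
    y0, y1 = (pd.Timestamp(cfg["window"]["start"]).year,
              pd.Timestamp(cfg["window"]["end"]).year)
    periods = [(y, y + 1) for y in range(y0, y1, 2)]
    census = generate_census(lt, cfg["risk"]["base_population"], periods)
    sampling = risk_mod.SamplingFraction(
        {y: cfg["risk"]["sampling_fraction"] for y in range(y0, y1 + 1)})
    cir_frames = []
    for subtype, sub in patients.groupby("subtype", observed=True):
        cases = risk_mod.new_cases_from_cohort(sub)
        if cases.empty:
            continue
        table = risk_mod.incidence_rates(cases, census, sampling, periods)
        res = risk_mod.cir_18_84(table)
        res.insert(0, "subtype", subtype)
        cir_frames.append(res)
    cir = (pd.concat(cir_frames, ignore_index=True) if cir_frames
           else pd.DataFrame())
    cir.to_csv(out / "cir.csv", index=False)

    # -- extrapolation validation --------------------------------------------
    vcfg = cfg["validation"]
    validation = []
    for i, (subtype, sub) in enumerate(patients.groupby("subtype", observed=True)):
        if len(sub) < est_cfg["min_subtype_n"]:
            continue
        try:
            res = validate_extrapolation(
                sub.reset_index(drop=True), lt, vcfg["fit_months"],
                vcfg["test_months"], n_replicates=est_cfg["n_replicates"],
                seed=seed + 3000 + i, window=est_cfg["rolling_window"])
        except ValueError as err:
            logger.info("validation skipped for %s: %s", subtype, err)
            continue
        validation.append({"subtype": subtype,
                           "extrapolated_rmst": res.extrapolated,
                           "observed_rmst": res.observed,
                           "relative_bias": res.relative_bias})
    (out / "validation.json").write_text(json.dumps(validation, indent=2))

    bundle = {"manifest": stamp, "ledger": ledger, "baseline": baseline,
              "estimates": estimates, "validation": validation,
              "cir": cir.to_dict(orient="records")}
    (out / "manifest.json").write_text(json.dumps(stamp, indent=2))
    return bundle
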