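# lifehorizon

Lifetime outcomes of a newly diagnosed disease, estimated from health-insurance
claims cohorts: **lifetime risk**, **life expectancy (LE)** and **expected
years of life lost (EYLL)**, and **survival-weighted discounted lifetime
medical costs**.  The package was built around the stroke use case (ICD-10
I60–I63 subtypes: subarachnoid hemorrhage, intracerebral hemorrhage, other
non-traumatic intracranial hemorrhage, cerebral infarction) under a 10-year
administrative observation window, but every stage is generic over the
supplied code sets, life table and census denominators.

Because the claims databases this methodology targets are access-restricted,
the package ships a first-class **synthetic-claims generator** with known
ground truth (true survival curve, LE, EYLL and expected lifetime costs of the
generating process), so the whole pipeline is testable end to end.

## Who it is for

Health-services researchers and health economists who need per-case lifetime
burden estimates — "how many life-years and how much money does one incident
case cost?" — from right-censored claims follow-up, without committing to a
parametric survival tail.

## Methods at a glance

**Lifetime risk.** Age-/sex-specific incidence rates `IR_i` are computed per
two-year period from sample case counts (scaled by the sampling fraction of
the source cohort) and census denominators, over the age bands 18–24,
25–29, …, 80–84 with widths `w_i` (7, then 5).  The cumulative incidence
rate between ages 18 and 84 is

```
CIR_18-84 = 1 − exp(−Σ_i IR_i · w_i)
```

reported both as a proportion and as "1 in N".  A sensitivity variant
subtracts prevalent cases from the denominators (an upper bound on the risk).

**Survival extrapolation.** Index-cohort survival `S_index(m)` is estimated by
Kaplan–Meier on a monthly grid.  A matched reference survival `S_ref(m)` is
simulated by Monte-Carlo sampling from a national life table, matching each
patient's sex, age and calendar year at index.  The logit survival ratio

```
W(m) = logit( S_index(m) / S_ref(m) )
```

is continued beyond follow-up one month at a time by an OLS trend over a
rolling window (the *rolling-over* algorithm), and lifetime survival is
reconstructed as `Ŝ(m) = expit(Ŵ(m)) · S_ref(m)`, which forces the
extrapolated curve to zero as the referents die out.  Then
`LE = ∫ Ŝ`, `EYLL = LE_ref − LE`, with standard errors from a patient-level
bootstrap.  The extrapolation is validated by fitting on the first 5 years of
follow-up, extrapolating to year 10, and comparing with the full-data
Kaplan–Meier restricted mean (relative bias).

**Lifetime costs.** Observed mean monthly costs among patients under
observation are extrapolated on the log scale with the same rolling-over
trend (capturing the end-of-life surge), weighted by survival and discounted:

```
lifetime cost = Σ_m  Ŝ(m) · cost(m) · (1 + r)^(−m/12),    r ∈ {0, 3%, 5%}
```

separately for the insurer-paid and patient-copayment streams (KRW,
convertible to US$ at a configurable rate, default 1 131.2 KRW/US$).

## Worked example

```python
import lifehorizon as lh

life_table = lh.generate_life_table(2002, 2015)          # synthetic national table
scenario = lh.multiplier_scenario(2.0, seed=0, n_patients=1500)  # 2x excess hazard
claims, truth = lh.generate_cohort(scenario, life_table)

patients, ledger = lh.build_cohort(
    claims, window=("2006-01-01", "2015-12-31"),
    washout=("2002-01-01", "2005-12-31"))
est, lifetime, ref = lh.estimate_lifetime(patients, life_table, seed=100)
print(f"LE {est.le:.2f} y   LE_ref {est.le_ref:.2f} y   "
      f"EYLL {est.eyll:.2f} y   (true EYLL {truth.eyll:.2f} y)")
```

prints

```
LE 14.99 y   LE_ref 21.13 y   EYLL 6.13 y   (true EYLL 5.04 y)
```

i.e. a cohort carrying a constant two-fold excess over background mortality
loses an estimated 6.1 life-years per case (generating-process truth 5.0,
within about one bootstrap SE of ~1.0 y for this cohort size); the matched
referents would have lived 21.1 more years on average.  Continuing
with costs:

```python
costs_long = lh.monthly_costs(claims, patients)
profile = lh.extrapolate_costs(lh.monthly_mean_costs(patients, costs_long), lifetime)
for rate in (0.0, 0.03, 0.05):
    lc = lh.lifetime_cost(profile, lifetime, lh.DiscountSpec(rate))
    print(f"{rate:.0%}: total ${lh.convert_currency(lc['total']):>8,.0f} "
          f"(copay share {lc['copay_share']:.1%})")
```

```
0%: total $  75,578 (copay share 18.0%)
3%: total $  54,716 (copay share 18.0%)
5%: total $  45,777 (copay share 18.0%)
```

The same stages are scriptable from the shell:

```bash
lifehorizon simulate --seed 0 --n-patients 2000 --out-dir data/
lifehorizon build-cohort --claims data/claims.csv --out cohort.csv --ledger ledger.json
lifehorizon estimate --cohort cohort.csv --lifetable data/lifetable.csv --out estimates.json
lifehorizon run-all --seed 0 --out-dir results/   # whole pipeline + manifest
```

## Layout

| module | role |
| --- | --- |
| `lifehorizon.synthetic` | life tables, census, claims cohorts with ground truth |
| `lifehorizon.cohort` | inclusion/exclusion cascade, comorbidities, severity score, cost binning |
| `lifehorizon.reference` | Monte-Carlo matched-referent survival |
| `lifehorizon.survival` | Kaplan–Meier on the monthly grid, restricted means |
| `lifehorizon.extrapolation` | rolling-over extrapolation, LE/EYLL, bootstrap, validation |
| `lifehorizon.costs` | cost profiles, extrapolation, discounted lifetime costs |
| `lifehorizon.risk` | incidence rates, CIR_18–84, prevalence adjustment, micro-simulation oracle |
| `lifehorizon.pipeline` / `lifehorizon.cli` | end-to-end orchestration and the `lifehorizon` command |

See `docs/methods.md` for modelling assumptions, parameter defaults and known
limitations.
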