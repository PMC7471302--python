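# Methods

This note documents the models, numerical choices and known limitations of
`lifehorizon`.  It states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## Time grid and conventions

All survival and cost arithmetic lives on an integer monthly grid measured
from the index date; one month is 30.4375 days (365.25/12) and years are
months/12.  Day-scale follow-up snaps to the nearest grid month, so a death
recorded during the interval around month *t* drops the survival curve at
grid point *t*; `S(m)` is the probability of surviving beyond month *m*,
with `S(0) = 1` (a death on day 0 is the one exception: it lands in month 0
and drops `S(0)` itself).  All integrals are trapezoidal on this grid.
Annual life-table death probabilities convert to monthly hazards under a
constant-hazard-within-year assumption, `h = −ln(1 − q)/12`, hence a
monthly death probability `p = 1 − (1 − q)^{1/12}`.  The synthetic
generator, the Monte-Carlo referents and the Kaplan–Meier stage all share
these conventions, so discretization offsets cancel in differences such as
EYLL.

## Cohort construction

The claims cascade retains a patient when their first I60–I63 primary
diagnosis falls inside the enrolment window and they pass, in order:

1. **washout** — no I60–I69 record during the pre-window washout years
   (prevalent cases and sequelae are excluded);
2. **hospitalization** — at least one inpatient line with a stroke primary
   code (outpatient-only diagnoses are considered unverified; those with ≥3
   distinct outpatient stroke-visit dates are flagged as a comparison
   group);
3. **imaging** — a CT/MRI procedure code within a configurable window
   around the index date (default 7 days before to 30 days after; the
   admission episode is not explicitly delimited in claims);
4. **accurate adult age** — age ≥ 18 at index, with an optional minimum
   birth-year cut for implausible records;
5. **consistent diagnosis** — all stroke primary codes on the index date
   map to a single subtype (I60→SAH, I61→ICH, I62→NIH, I63→CI).

Each excluded patient is counted once, against the first failed rule, so the
ledger always conserves the input count.  Comorbidity flags require at least
one qualifying record *strictly* before the index date.  The severity score
is a linear function of first-stay service-use indicators clipped to
[4.1, 27.11]; its coefficients are configuration inputs, not re-derived.

## Referent survival

For each patient, referent lifetimes are simulated by walking the life
table forward from (sex, completed age, calendar year at index), age and
year advancing together; beyond the table's last calendar year the last
column is carried forward, and the table must close with q = 1 so every
referent dies (age cap 110).  The pooled curve uses only demographics —
never the patients' event data.  Default 100 replicates per patient keeps
the referent Monte-Carlo error well below Kaplan–Meier noise for cohorts of
a few hundred or more; the per-seed determinism contract makes runs
reproducible.

## Rolling-over extrapolation

Let `W(m) = logit(S_index(m)/S_ref(m))`, with the ratio clipped into
`(1e-12, 1 − 1e-12)` and the series truncated at the last month with
positive Kaplan–Meier mass.  Beyond follow-up, `W` is continued one month
at a time: an OLS line is fitted over the trailing window of points
(observed, then progressively the freshly extrapolated ones), the next
value predicted, and survival reconstructed as `expit(Ŵ)·S_ref`, clipped to
be non-increasing.

Two design choices here deserve emphasis, because the naive construction is
unstable:

* **Trend gating.** Kaplan–Meier noise enters `W` as a near-random walk, so
  a fitted OLS slope can be large and "significant" (by its iid-residual
  t-statistic) even when the true trend is zero — the classic spurious
  regression.  Extrapolating such a slope over a multi-decade horizon
  collapses survival one-sidedly (`expit` saturates upward but not
  downward), which in benchmark runs inflated EYLL by years in cohorts with
  no excess hazard at all.  The predictor therefore tests the drift on the
  month-to-month *increments* of `W` (approximately independent) and
  continues the window mean unless `|t| ≥ 2`.  Under a genuine excess
  hazard the drift test is passed overwhelmingly and behavior is unchanged.
* **Window length.** The default trailing window is 36 months.  Short
  windows track the terminal trend but amplify noise; long windows reach
  into the early-follow-up transient, where the logit diverges as the ratio
  approaches 1, and bias the slope.  The default was selected by simulation
  benchmark against known ground truth across null, constant-multiplier
  and declining-excess scenarios (criteria: null-case EYLL centered on
  zero; multiplier-recovery z-scores; 5→10-year validation bias).  The full
  observed history remains available via the `window` argument.

LE and LE_ref are the integrals of the extrapolated and referent curves
(both must be exhausted below 1e-6 survival); EYLL is their difference.
SEs come from a patient-level bootstrap that reruns the entire pipeline per
resample, with a fresh referent seed per replicate so referent noise is not
artificially shared.

The 5→10-year validation censors every patient's follow-up at 60 months,
extrapolates to 120, and compares restricted means — the relative bias
`(extrapolated − observed)/observed` is the headline accuracy statistic.

A known limitation: for a *constant* multiplicative excess hazard the true
`W` is convex in time near the start of follow-up (the logit diverges as
the ratio leaves 1), so a linear continuation fitted on the observed decade
tends to overstate the lifetime decline slightly; in benchmark runs the
resulting EYLL overshoot was within about one bootstrap SE at n = 1500.
The validation statistic, which extrapolates only 5 years ahead, is not
materially affected.

## Lifetime costs

Mean monthly cost is averaged over patients *under observation* (alive and
uncensored) in that month, counting claim-free months as zero; survival
weighting at aggregation time then yields an expected per-case cost.
Extrapolation beyond follow-up applies the same rolling-over trend on
`log(1 + cost)` (positivity; the end-of-life surge enters through the
rising trend as the surviving pool ages toward death), floored at zero.
Discounting is `(1 + r)^{−m/12}` from index month 0, with r = 3% base and
0%/5% sensitivity.  Insurer-paid and copayment streams are computed
separately and add exactly.

## Lifetime risk

`CIR_18−84 = 1 − exp(−Σ IR_i·w_i)` over the 13 bands 18–24 (width 7) and
25–29 … 80–84 (width 5); ages 85+ are excluded because tiny denominators
would be over-weighted by the equal-weight construction.  Sample case
counts are scaled by per-year sampling fractions before division by census
person-years.  The prevalence-adjusted variant shrinks only the
denominators, so it can only raise the estimate (an upper bound).  No
competing-mortality adjustment is applied — the CIR is the conventional
lifetime-risk reading of cumulative incidence.  A micro-simulation oracle
(individuals aged 18→84 under band-wise constant hazards) cross-checks the
closed form in the test suite.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *structure* the pipeline consumes: ICD-10-coded
index admissions with imaging and severity procedure codes, washout-period
noise diagnoses, pre-index comorbidity records, death/censoring under an
administrative window, and monthly two-stream cost lines whose mean rises
by a terminal-surge multiplier during the last K months of life.  Mortality
is the life-table hazard times a piecewise-constant excess (multiplicative
by default, so a multiplier of 1 reproduces referent survival exactly);
costs are lognormal noise around the stage-dependent mean.  Ground truth
(per-patient uncensored death month, analytic cohort survival, LE, EYLL,
expected discounted lifetime costs) is computed from the same hazards, not
re-simulated.

Key default conditions: a Gompertz-like life table calibrated to an
East-Asian-style life expectancy (≈80 male / 86 female, 0.5% annual
mortality improvement); baseline cost 350 000 KRW per survivor-month with a
6× surge over the final 12 months and an 18% copayment share; subtype
scenario profiles reproduce the published cohort composition (sizes
1182/2022/508/2282 — the largest subtype scaled down to keep desk-scale
runtimes — sex ratios, and age mixes), with a declining excess hazard
(e.g. 12× → 1.8× across the first two years for SAH) and index events in
the first half-year of the 10-year window so that ten years of potential
follow-up exist.

What passing tests on these data do **not** show: robustness to real-world
coding practice (miscoding, rule-out diagnoses, hospital-level variation),
non-proportional or covariate-dependent excess hazards, secular treatment
improvements within follow-up, reimbursement-schedule changes, or costs
outside the two claim streams.  Absolute cost levels are illustrative, not
calibrated to any fee schedule.

## Degenerate inputs and numerical edges

Empty cohorts, all-censored-at-zero cohorts, referent curves that never
reach the survival floor, misaligned grids, windows shorter than 2 months,
negative costs, missing CIR age bands, prevalence exceeding population and
non-rectangular life tables all raise with explicit messages.  If the
Kaplan–Meier curve hits zero within follow-up, extrapolation is a no-op
(survival stays zero).  Bootstrap replicates that fail are skipped; more
than 10% failures aborts.
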