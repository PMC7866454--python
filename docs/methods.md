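# Methods

This note documents the models and conventions implemented in `rxmsm`, the
design of the synthetic cohort the package is validated against, the
numerical choices, and the limitations of both.

## Day-level exposure model

Coverage is a pill-stock simulation per patient and drug class. Each fill
adds its days-supply to the class stock; a day is covered iff the stock is
positive at day start; every outpatient covered day consumes one day of
stock. Three refinements:

* **Early refills** of the same drug stack: the remaining supply carries
  over, capped at 90 days (`CoverageRules.stock_cap_days`) — the standard
  PDC stockpiling convention.
* **Within-class switches** (a fill of a different drug in the same class)
  reset the stock to the new fill's supply; unused supply of the previous
  drug is forfeited at the fill date. Every fill therefore truncates its
  predecessor's coverage interval.
* **Hospital days** are covered (medication is dispensed in-house and does
  not appear in refill data) and do not consume outpatient stock. They
  count as covered only from the first fill of the class onward.
* An optional **incompatibility map** lets a fill of one class truncate the
  stock of another; the default map is empty.

A fill covers its own fill date; intervals are closed on both ends in day
units. The vectorized interval builder is verified, exactly, against an
independent day-by-day simulator on 1000+ randomized schedules.

**PDC** at anchor *t* is the covered-day fraction of `(t-365, t]`; before a
full year of observation the denominator is the days observed so far, so
early anchors are defined without artificial deflation. The "time-weighted
running average" is realized as the uniform trailing-365-day mean (no decay
kernel). Anchors are weekly from entry plus every event day.

## Exposure levels

At every anchor each class group (LLT = statins + fibrates/fish
oil/ezetimibe/niacin; AHT = angiotensin antagonists, beta blockers, calcium
channel blockers, non-loop diuretics; ASA) is in exactly one level:

| level | rule |
|---|---|
| consistent | ≥ 11 of the 12 trailing 30.44-day month blocks contain a covered day **and** trailing PDC > 0.91 (strict) **and**, by default, a covered day within the last 30 days |
| recent inconsistent | any covered day in the trailing year, not consistent |
| remote | prior use only (nothing in the trailing year) |
| never | no covered day ever (reference) |

The 30-day recency gate is on by default (`LevelRules.consistent_recency_days`);
it can be disabled, in which case months + PDC alone decide. A PDC of
exactly 0.91 is excluded from consistent (strict inequality).

Sublevels: consistent LLT splits into statin-only / combination /
statin-free by which drugs contributed covered days in the trailing year;
recent and remote LLT carry a binary statin-containing flag; consistent AHT
distinguishes single vs combination (≥ 2 subclasses active in the trailing
year). Two variants support the additional analyses: *ongoing current use*
(≥ 3 of the 4 trailing 7-day blocks contain a covered day) and the
*since-initiation* redefinition of consistency (> 91.5% coverage between
the first fill and min(first fill + 365, anchor)), which removes the
11-month exposure prerequisite and with it any mechanical immortal-time
component.

## Follow-up, endpoints, person-periods

Entry is the first undetectable viral load (< 50 copies/mL). Exit is the
earliest of death, a care gap > 396 days ("> 13 months"; censor date = last
contact, configurable to gap end), or the administrative end of data. Death
wins whenever it occurs before a gap completes — death records are assumed
registry-reconciled and observed between visits. Care contacts are the
union of all dated records; *outpatient follow-up frequency* (a covariate
the propensity models always receive) counts only clinic-type contacts
(labs, viral loads, admissions), annualized over the in-care part of the
trailing year — pharmacy fills are deliberately excluded there because they
would proxy the exposure itself.

ASCVD events require corroboration: a diagnosis code counts only if a
qualifying procedure code, biomarker value or neuroimaging record falls
within ± 7 days (configurable); the event date is the earliest corroborated
diagnosis. Infection and cancer are the first qualifying code after entry
with configured exclusion lists (cellulitis, URI, cystitis; squamous and
basal cell skin cancers). Each explanatory endpoint gets its own
single-event dataset truncated at first occurrence.

Person-periods are half-open `(start, stop]` intervals split at weekly
anchors plus the event day; covariates take their period-start values;
events on a boundary belong to the period ending there. Person-time and
event counts are conserved exactly (tested).

For model estimation, consecutive weekly rows with identical exposure
levels, sublevels and follow-up-frequency category are collapsed into runs
of at most 56 days (`collapse_days`); smooth covariates (HAART adherence,
age, lab running averages) refresh at run starts. This leaves the partial
likelihood identical up to the within-run refresh rate of those covariates
and cuts row counts by roughly an order of magnitude.

## Weights

Per class group, an unpenalized multinomial logit (person-time-weighted)
predicts the observed level from the screened covariates; the stabilized
weight is the marginal (person-time) level frequency over the predicted
probability of the observed level. **Truncation is applied within each
level's own weight distribution** at its 5th/95th percentiles (asymmetric
truncation): with a rare top level, pooled-percentile clipping is
one-sided and visibly mis-centres that level's mean weight, whereas
per-level clipping keeps all level means near 1 — which is also the
diagnostic the method is expected to satisfy. Censoring weights come from a
pooled logistic model of remaining uncensored, cumulated over each
patient's preceding periods (stabilized by the marginal rate). The total
weight is the product of the three class-group weights and the censoring
weight; weights are per-interval (current covariates), not sequential
cumulative products — the classical sequential form can be built on top by
cumulating, but per-interval weights are the implemented default.

Predictor screening fits an unweighted counting-process Cox model of the
endpoint on the candidate covariates and retains terms with p < 0.05,
always appending the follow-up-frequency category.

## Weighted Cox engine

No installed Python survival implementation combines case weights,
`(start, stop]` counting-process rows and a cluster-robust sandwich
covariance, so the engine is implemented here: Newton–Raphson on the
weighted partial likelihood with Efron tie handling (Breslow available),
risk sets evaluated by suffix segment sums over rows sorted by interval
start/stop (O(n·p²) per iteration), model-based covariance from the
observed information, and a Huber–White sandwich with per-patient score
residuals (Efron-adjusted) for the robust covariance. It reproduces R
`survival::coxph` coefficients, naive and robust standard errors to ~1e-7
on tied, weighted, clustered data (tested), and lifelines' time-varying
point estimates. Proportional hazards are checked with a
Grambsch–Therneau-type test on per-event-time Schoenfeld residual sums
(identity time transform), calibrated by simulation in the test suite.

The MSM itself regresses on level indicators for the three class groups
simultaneously (reference = never; optional sublevel coding for LLT).
Levels with zero events are reported as undefined rather than dropped
silently. Reference recoding is an exact reparametrization (tested to
1e-6). Benjamini–Hochberg correction is applied across the full endpoint ×
class × level grid of the overall analysis; subgroup analyses are left
uncorrected.

## Synthetic cohort

The generator is a discrete-time daily simulation shaped to the printed
moments of the kind of registry cohort the pipeline targets (HIV-positive
veterans followed after first virologic suppression over a 16-year window),
at a scaled-down 8-year horizon:

* staggered care entry (uniform over the first 3 years), suppression with
  probability 0.85 after an exponential delay, entry at the first
  undetectable viral load;
* crude mortality ≈ 33/1000 patient-years, median follow-up ≈ 5.2 years,
  ≈ 14–16% gap-censored, ever-use ≈ 42%/60%/36% for LLT/AHT/ASA — matching
  the published cohort's shape;
* a standard-normal latent frailty score *z* multiplies the death hazard
  (`exp(0.6 z)`) and the treatment-start rates (`exp(0.8 z)`), creating
  indication confounding. *z* is emitted as a laboratory covariate
  (`comorbidity_index`), making the confounding measurable: the module's
  validation contract (weighted recovery of the true hazard ratios)
  requires the confounder to be in principle adjustable, which a purely
  latent frailty would preclude. Age plays the same dual role with small
  coefficients. Visit intensity is heterogeneous and frailty-linked, so
  follow-up frequency is an informative, balanceable covariate;
* refill persistence follows a three-class mixture (high / intermittent /
  poor = 0.55/0.30/0.15) governing refill punctuality, gap lengths and
  discontinuation; the mixture was set to reproduce the printed adherence
  moments (median one-year HAART adherence ≈ 0.8; statin coverage ≈ half
  of follow-up after initiation). The `adherence_frailty_corr` knob
  correlates poor adherence with frailty for healthy-adherer
  demonstrations. ARV agents of the regimen refill together (one dispensing
  event covers all three), which clusters adherence across drugs;
* the death hazard at week *w* multiplies the baseline by
  `exp(Σ_g true_log_hr[g, level_g(w)])` where `level_g(w)` is computed by
  the *same* classifier the pipeline uses, on a weekly grid; event days are
  placed within the week by a conditional geometric draw. The analysis
  model is therefore correctly specified by construction, and the
  configured hazard ratios are the estimand. Explanatory endpoints run as
  independent competing processes with their own (default null) level
  effects; death does not require a preceding event;
* ASCVD diagnosis codes carry corroborating procedures / troponin values /
  neuroimaging 90% of the time; uncorroborated administrative codes and
  excluded-code noise (cellulitis, skin cancers) are added for the
  adjudicator and the exclusion lists to act on.

Ground truth (frailty, adherence class, true event days, weekly level
codes) stays on the in-memory `SyntheticCohort` and is never written to
the file set the pipeline reads.

What the generator does **not** emulate: realistic ICD-9 coding behaviour,
dose strength, drug–drug interactions, per-compound effects, secular
calendar trends, competing-risk dependence between endpoints, or
measurement error in the confounder proxy. Passing tests therefore show
that the pipeline recovers known effects *when its assumptions hold at the
simulated scale* — they do not certify performance on real registry data,
where confounders are incompletely measured.

## Study sizes and numerical choices

The replicate studies in the test suite are scaled to run on one CPU:
null calibration uses 200 replicates of n = 1200 patients over a 6-year
horizon; parameter recovery 40 replicates of n = 3000 over 8 years
(weighted |log-HR bias| < 0.1 also holds at n = 5000, where the cell event
counts are larger); the adherence-bias demonstration 40 replicates of
n = 2500 over 6 years, with coverage judged against the exact binomial
1%-level bound for its replicate count; the diagnostics check one n = 5000
cohort. Confidence-interval coverage is summarized per exposure level
pooled over the three class groups. Replicate seeds derive from the base seed by a fixed stride and
stay below 2³¹.

Small cells matter: with fewer than ~15 events in an exposure level the
partial-likelihood estimate of that level's log hazard ratio carries
noticeable finite-sample bias away from zero; the study sizes above keep
the consistent-level death counts beyond that regime.

Other numerical choices: Newton iterations stop at |score|∞ < 1e-6 or a
log-likelihood change < 1e-9, with step halving; covariates are centered
(estimates invariant); propensity features are standardized; lbfgs
tolerance 1e-8; weight truncation percentiles are person-time-weighted;
exposure-level design columns with zero variance or zero events are
excluded from the fit and reported as undefined.

## Limitations

* Per-interval (not sequential-cumulative) weights; with purely baseline
  confounding, as simulated, both coincide in expectation. A time-indexed
  treatment model with a time-stratified stabilization numerator is
  available (`compute_weights(..., time_cols=...)`) but does not improve
  recovery on the simulated designs.
* The prescribed 5th/95th-percentile weight truncation trades a small
  residual confounding bias for variance; under the simulated confounding
  strength that residual stays within the recovery tolerance but is not
  exactly zero.
* The censoring model ignores interval-length differences across collapsed
  runs (censoring is rare and near-uniform in the simulated designs).
* The Schoenfeld test uses the averaged-information approximation rather
  than per-event-time variance; its calibration is demonstrated only by
  simulation.
* Marginal vs conditional non-collapsibility of the hazard ratio is
  present in principle (frailty sd 0.6); at the simulated mortality its
  magnitude (< 0.05 in log HR) stays inside the recovery tolerance.
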