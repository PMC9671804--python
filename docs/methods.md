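# Methods

`stepcourse` implements the analysis chain that links longitudinal consumer
step-count streams to incident chronic disease recorded in an EHR: wearable
processing, phenotype construction, a phenome-wide logistic screen, and
time-varying Cox models with restricted cubic splines, all exercised against
a synthetic cohort generator with known ground truth. This note records the
model, the parameter choices, and the places where the design was genuinely
open.

## Wearable processing

The exposure signal is steps per minute. A **valid day** requires at least 10
clock hours (00–23 buckets) containing a nonzero step minute and at least 100
total steps; days failing either rule carry no exposure information. Wear
time is deliberately bucketed by clock hour rather than by sliding 60-minute
windows — it is the simplest reading of "hours in a day with steps" and it
makes the brute-force oracle trivial to state.

**Cadence bouts** are maximal runs of ≥2 consecutive minutes at or above a
threshold: 60 steps/min (slow walking) or 100 steps/min (moderate-to-vigorous).
Mean bout cadence is pooled time-weighted — total bout steps divided by total
bout minutes across all valid days — not as a mean of per-bout means. The two
definitions disagree whenever bout lengths vary; time-weighting follows the
"average steps over the time in bouts" reading and makes the statistic
invariant to how a stream is chunked.

A **month** is a consecutive 30-day block on the participant's own monitoring
clock, starting at their first monitored day. Calendar months are meaningless
here: the generator (like privacy-protected EHR linkages) permits per-person
date shifts, so only the monitoring clock is well defined. A month is usable
as an exposure measurement when it holds ≥15 valid days. Participants need
≥6 months between first and last valid day to enter any analysis.

## Exposure attachment and the no-leakage rule

The default time-varying exposure is the **running mean** of daily steps over
all valid days up to a cutoff (a per-month mean is available via
`exposure_mode="month"`). The counting-process row covering the risk interval
(m, m+1] carries the exposure computed from months ≤ m−1, and the row exists
only when month m−1 was valid; invalid months therefore open gaps in the risk
set (the person leaves and re-enters). The event-containing interval is always
retained, since its lagged exposure is still well defined; a person with no
valid month contributes nothing and is logged.

This one-month lag is a deliberate design choice. Attaching month m's own
average to the interval (m, m+1] would let minutes recorded after an event
influence the covariate of the row in which the event happens. With the lag,
perturbing any step data on or after the event month provably leaves the
analysis table unchanged — a property the test suite checks directly. The
cost is that the exposure is half a month staler on average; with multi-year
running means this is negligible.

## Phenotypes, washout, censoring

ICD9CM/ICD10CM condition rows are mapped many-to-one to phecodes; for each
(person, phecode) the earliest date is kept and unmapped codes are counted
and dropped. Clinically overlapping phecode pairs (diabetes with
manifestation + diabetes; obstructive sleep apnea + sleep apnea) can be
declared as a combined outcome, in which case the earliest qualifying
occurrence across the set defines the event.

A first occurrence before monitoring or within the first 6 months (the
**washout**) marks the condition as prevalent-but-undiagnosed and excludes
the person for that outcome. Survivors enter the risk set at washout end —
late entry, not time 0, so no washout person-time is counted — and are
censored at their last medical encounter, the maximum date across the
measurement, lab, procedure and condition domains. Occurrence exactly at the
washout boundary counts as prevalent (exclusion requires exit > entry in any
case).

## Phenome-wide screen

For each phecode, cases are persons with a first occurrence after washout,
washout occurrences exclude, and everyone else is a control. A logistic model
adjusts for age, sex and race (complete case; imputation is reserved for the
Cox models) and reports the odds ratio per 1,000-step increase in overall
mean daily steps with a Wald CI. Fits with fewer than 20 cases are flagged
unstable rather than dropped; separated fits are flagged without
coefficients. The Bonferroni threshold is 0.05 divided by the number of
phecodes actually fitted, and that count is reported next to the threshold.

## Time-varying Cox models

The estimator maximizes the counting-process partial likelihood by
Newton–Raphson with step-halving, on internally standardized covariates
(exactly back-transformed afterwards). Ties use the Efron correction by
default; Breslow is a flag. The implementation is verified against
brute-force enumeration of the partial likelihood on random small tables
(tolerance 1e-6) and cross-checked against an independent time-varying Cox
implementation on tie-free data.

Restricted cubic splines use the Harrell truncated-power basis (k knots →
k−1 columns, linear beyond the boundary knots, normalized by the squared
boundary span) with knots at the standard quantiles — 3 knots:
0.10/0.50/0.90; 4: 0.05/0.35/0.65/0.95; 5: 0.05/0.275/0.50/0.725/0.95 — of
the pooled person-month exposure distribution, since that is the scale the
model sees. Candidate models with 3, 4 and 5 knots are compared by
AIC = −2ℓ + 2·dim(β); ties break toward fewer knots.

Inference on a block of terms uses the Wald **chunk test** β′Σ⁻¹β: all
exposure terms for overall association, the nonlinear terms alone for
curvature. Hazard-ratio curves are HR(s) = exp(f̂(s) − f̂(s_ref)) with the
cohort median as reference and delta-method intervals; the 75th-vs-25th
percentile contrast uses percentiles of person-level mean steps within the
outcome cohort. The model suite is: M1 exposure + age, sex, race; M2 = M1 +
systolic BP, CAD, cancer, smoking, education, alcohol, BMI; M3 = M2 +
time-varying wear hours; M4/M5 = M2 + baseline steps averaged over the first
3/6 months. A linear BMI×steps interaction and a second spline in bout
cadence (intensity-adjusted models) are supported through the same design
machinery.

Cumulative incidence holds the exposure fixed: F(t|s) = 1 − exp(−Λ̂₀(t)
e^{lp}), with the Breslow baseline Λ̂₀ and a covariate profile of median
continuous values and modal categories (the profile is a package choice; no
canonical profile exists). The interval reflects uncertainty in β only — the
Breslow estimator's own sampling variability is not propagated, which
understates the width somewhat at the time horizon tails. Proportional
hazards are checked by the scaled-Schoenfeld score test (Grambsch–Therneau,
average-information approximation) with identity, rank or log time
transforms; identity is the default since the canonical choice is unstated
in most applied work.

## Multiple imputation

Missing covariates are imputed by predictive mean matching: a linear model on
the observed rows predicts the incomplete column, each missing cell picks
uniformly among its k = 5 nearest-predicted-mean donors and copies the
donor's observed value, so imputed values are always in-domain. Categorical
columns run through the same mechanism on integer score codes. One pass
suffices when a single column is incomplete; otherwise five chained sweeps
are used. This matches on predicted means like aregImpute-style PMM but does
not reproduce any particular implementation's internals. m = 5 completed
datasets are drawn; estimates pool by Rubin's rules, T = W̄ + (1 + 1/m)B,
with Barnard–Rubin degrees of freedom.

## Synthetic cohort generator

The generator is first-class, tested code, not a fixture. Per person, daily
step totals are log-normal: between-person log-SD 0.38 around a median of
7,700 steps/day (giving an IQR near 5,900–9,800) and within-person
day-to-day log-SD 0.32. Non-wear arrives in multi-day episodes from a
two-state Markov chain (stationary non-wear fraction 0.18, mean episode 10
days) so that a realistic share of months — roughly 12–15% — fail the
15-valid-day rule; independent daily non-wear would almost never produce an
invalid month. Wear-day bout structure is drawn as a cadence mixture (slow
~85 steps/min, fast ~112) whose person-level cadence shift is coupled to
volume, reproducing the strong positive volume–intensity rank correlation
seen in real cohorts. The minute-level path allocates each day's exact total
multinomially over an intensity profile with planted cadence runs inside the
wear block, so re-aggregating minutes reproduces the daily table identically.

Covariate marginals echo a predominantly female, white, college-educated
tracker cohort; missingness is injected MCAR per column (age stays complete
so imputation always has an observed predictor). MCAR is a deliberate
simplification: it lets PMM's validity be tested without MAR machinery, and
it means passing tests say nothing about informative missingness.

Outcome events come from a piecewise-constant monthly hazard
λ_m = λ₀ · exp(g(s_m)), where s_m is the same lagged running-mean exposure
the analysis model uses, and g is null (falsification), log-linear
(parameterized as an HR per 1,000 steps), or plateau (log-linear below a
knot, default 9,000 steps/day, flat above — the shape reported for incident
diabetes and hypertension). Event times are drawn by exact inverse-transform
sampling on the cumulative hazard, so the generator is seed-deterministic.
A configurable fraction of persons receives a pre-washout diagnosis to
exercise the exclusion logic, and encounters are sprinkled through each
person's monitoring window with a terminal visit so censoring dates are well
defined. An optional uniform 1–365-day date shift emulates privacy
transforms and must leave every estimate unchanged, since all analysis runs
on the monitoring clock.

What the generator does not emulate: circadian structure within days, device
heterogeneity, seasonality, informative (MAR/MNAR) missingness, reverse
causation, or diagnosis-code noise. Recovery of injected effects therefore
validates the estimator chain, not robustness to those real-world features.
Per-person step-variance components are not calibrated to any published
decomposition — the defaults above are documented choices.

## Validation studies and problem sizes

The simulation studies in `stepcourse.studies` are run at sizes chosen to
keep Monte-Carlo error well inside the assertion bands: effect recovery at
n = 2,000 × 20 replicates (per-replicate SE of the log HR per 1,000 steps is
≈0.03, so the replicate mean resolves bias to ≈0.007), nonlinearity
detection at n = 1,200 × 20 with a 0.70-per-1,000 plateau slope, and null
calibration at n = 800 × 50 (≈140 events per replicate, enough for the Wald
chunk statistic to reach its asymptotic χ² behavior — at half that event
count the test is visibly anticonservative). Three years of monitoring is
the default window.

## Known limitations

* Incidence-curve intervals ignore baseline-hazard variance (above).
* The PH score test uses the average-information approximation of
  cox.zph-style software rather than per-event risk-set variances.
* PMM uses a single linear predictor per column; no posterior draws of the
  regression coefficients (so imputation uncertainty is slightly
  understated at small n).
* The phenome screen treats phecodes independently. Sex-specific phecode
  restrictions in the map are honored when person-level sex is supplied to
  the mapper (and ignored with a warning otherwise); phecode hierarchy
  exclusion ranges are not applied.
* Time is measured in 30-day months; a "year" is 365.25/30 ≈ 12.17 such
  months wherever incidence is reported by year.
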