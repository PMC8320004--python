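# Methods

## Estimand and data model

The estimand is 12-month contact coverage: the proportion `c = p_t / p_g`
of people expected to have a disorder who had at least one contact with a
specialist mental-health service in 12 months.  Inputs are one row per
country × disorder with inpatient/outpatient case counts, visit counts, a
representativeness fraction (share of the national population covered by
the reporting system), a 4-category inpatient follow-up rate and a
self-reported population; a country-context table (income group, WHO
region, GBD region and super-region, UN population); and per-disorder
prevalence estimates with 95% intervals.

Coverage is computed *within the covered population*: the denominator is
`prevalence × population × representativeness`.  The alternative —
inflating treated counts by 1/representativeness — yields the same ratio;
shrinking the denominator keeps both counts interpretable.  Which
convention the original reporting exercise used is not documented; ours is
a stated choice, not a claim about that exercise.

## Validity screens

* **Completeness.** A row lacking either facility's case count, or the
  representativeness fraction, is excluded.  Missing is never conflated
  with zero: an empty CSV cell parses to an absent field, and a reported
  `0` is a legitimate count.
* **Visits per case.** Total visits divided by total cases (pooled across
  settings, since the source items report totals) below 1 — strictly —
  excludes the row; equal to 1 passes.  Rows with no visit data at all
  pass with a logged warning: the check screens reported visits, it is not
  a completeness requirement.  Visits reported against zero cases exclude
  the row (the ratio is undefined, which itself signals inconsistency).
* **Population resolution.** The self-reported population is used when it
  is within a configurable relative divergence (default 0.30) of the UN
  estimate, otherwise the UN estimate is substituted and logged.  The
  trigger ("dramatically different") has no documented quantitative
  definition; 0.30 is our default and is exposed in configuration.

## Expected cases

Prevalence inputs arrive in the conventions the burden-of-disease
literature publishes: schizophrenia point prevalence, bipolar 12-month
prevalence, all-severity depression point prevalence.  Adjustments:

* psychosis: divide rate and interval bounds by the schizophrenia share
  of non-affective psychosis, 0.49.  Point prevalence is accepted as a
  12-month proxy (the two were statistically indistinguishable in
  burden-of-disease covariate modelling).
* depression: multiply by a point→12-month factor and by the combined
  moderate (0.17, 95% CI 0.13–0.22) + severe (0.10, 95% CI 0.03–0.20)
  severity split.  The published value of the point→12-month covariate
  coefficient is **not recoverable**; `depression_point_to_12m_factor`
  defaults to 1.30 and must be treated as an editable assumption.

Interval bounds are scaled by the same factor as the rate under
multiplicative adjustment (preserves relative uncertainty).  The severity
split is applied at its central value; its uncertainty enters by adding
the relative SE of the combined split in quadrature to the relative SE of
the prevalence — the simplest symmetric rule, isolated in one function so
it can be replaced.  Prevalence SEs are reconstructed from the 95%
interval as `(upper − lower) / (2 × 1.959964)`.

## Double-counting correction

Countries are classified by which setting treats the majority of reported
cases; ties go to outpatient-prioritised (the conservative side: the
correction applies).  In outpatient-prioritised countries every inpatient
receiving an outpatient follow-up also appears in the outpatient tally,
so unique cases = `inpatient + (outpatient − m × inpatient)` with `m` the
midpoint of the reported follow-up category (≤25% → 0.125, 26–50% → 0.38,
51–75% → 0.63, >75% → 0.875).  A negative adjusted outpatient count falls
back to the raw sum (flagged): the report is internally inconsistent and
the formula would fabricate information.  In inpatient-prioritised
countries no adjustment is applied; we read "not adjusted" as keeping the
raw sum of both tallies.  Missing categories are imputed with the median
midpoint of the country's GBD region (median of midpoints, i.e. on the
scale the formula uses), falling back to the global median.  Fractional
unique cases are kept — downstream quantities are proportions.

## Uncertainty chain

1. `se(p_t) = sqrt(p_t (1 − p_t) / N)` (binomial, N = covered population);
2. `se(p_g)` from the interval as above;
3. `c = p_t / p_g`, `se(c) = c sqrt((se_t/p_t)² + (se_g/p_g)²)`
   (independent-ratio delta method; with `p_t = 0` only the numerator
   term survives);
4. `logit(c)` with `se_logit = se_c / (c (1 − c))` (logit delta method).

The exact SE formulas behind the four named steps of the original
exercise are not printed in running text; these standard forms are our
choices, each isolated in a single function.  A ratio above 1 is capped
at 0.999 with a warning rather than excluded — exclusion is the threshold
filter's mandate.  Boundary estimates use the continuity correction
`1/(4N)` (or `1 − 1/(4N)`) with a binomial floor on the SE so pooling
weights stay finite.  Natural-scale CIs are inverse-logit transforms of
`logit(c) ± 1.96 se_logit`, respecting (0, 1).

## Thresholds

Per disorder × income group admissible bands: psychosis has lower bounds
only (specialist coverage can legitimately be high); bipolar and
depression have upper bounds only (their true specialist coverage is
expected to be low).  The published numeric table is not machine-readable
from the source text, so `data/thresholds.yaml` ships *reconstructed,
editable placeholders* that encode the structure; absent bounds never
exclude.  A consequence worth stating: a registry reporting visits as
cases for **psychosis** cannot be caught, because no upper bound exists
for it.  That is a property of the screen design itself, and the
synthetic generator therefore assigns this corruption only to bipolar and
depression rows by default.

## Pooling

DerSimonian–Laird random-effects meta-analysis on the logit scale:
fixed weights `w_i = 1/se_i²`, `Q = Σ w_i (y_i − ȳ_w)²`,
`τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`, random weights
`1/(se_i² + τ²)`, `I² = max(0, (Q − (k−1))/Q) × 100`.  The original
exercise names only its software; DL is our choice for its closed form
and deterministic testability, and the estimator sits behind a single
function so a REML variant can be added.  Groups of one country report
the raw estimate with τ² = 0.  Baujat coordinates (contribution to Q
versus standardised leave-one-out influence, both under fixed-effect
weights) are emitted for every group of k ≥ 2; influential countries are
reported, never auto-excluded.

## Synthetic worlds

The generator emulates structure, not the 2017 country distribution.
Defaults, chosen once:

* coverage means per disorder × income group follow the reported
  income-group gradients (psychosis 0.109/0.215/0.292/0.595, bipolar
  0.031/0.035/0.031/0.104, depression 0.029/0.043/0.130/0.311), with
  between-country SD 1.0 on the logit scale — the heterogeneity implied
  by the width of published group CIs;
* prevalence means in input conventions: schizophrenia 0.003, bipolar
  0.006, depression 0.035; countries scatter log-normally (SD 0.3)
  around them, with ±10% relative 95% intervals.  The *reported*
  prevalence is a noisy measurement of the true prevalence (log-normal
  error matching the stated interval), so stated SEs describe realised
  error — without this, delta-method weights would be mis-stated by
  construction;
* inpatient share of treated persons uniform on (0.05, 0.40): most
  synthetic countries are outpatient-prioritised, matching
  deinstitutionalised service mixes;
* true follow-up fractions uniform on (0.02, 0.98); the reported
  category is the containing bin, masked at rate 0.15 to exercise
  regional-median imputation;
* clean reporters draw per-case visit rates ≥ 1, so the visits screen
  can only fire on corrupted rows; `incomplete` rows omit one required
  field; `visits_mistaken_as_cases` rows put visit volumes in the case
  columns with a per-case rate floored at `1.2 / true coverage`, which
  guarantees the inflated ratio exceeds 1, is capped at 0.999 and trips
  any configured upper threshold — the "caught by construction"
  guarantee the screening tests rely on.

The patient-level simulator instantiates individuals (treatment contact,
setting, follow-up as independent Bernoulli draws) and returns the exact
unique count next to the double-counted tallies; it is the oracle for
the midpoint formula.  Over 1,000 simulated registries with the default
inpatient-share range the formula's mean absolute relative error is
≈1.4%: the irreducible part is the bin-midpoint discretisation (mean
|m − m̂| ≈ 0.06 within bins) times the inpatient share, plus binomial
noise.

What the generator does **not** emulate: reporting correlated across
disorders within a country, non-random missingness, diagnostic
misclassification, prevalence error correlated across countries (as a
shared estimation model would induce), or the real 2017 distribution of
country sizes and qualities.  Passing tests demonstrate the pipeline's
internal correctness and calibration under these stated conditions, not
the accuracy of any real-world coverage figure.

## Parameter-recovery study conditions

The calibration study generates four-income-group worlds of clean
reporters, estimates every country, pools per group with DL, and checks
whether the 95% CI contains the group's true mean coverage.  Conditions:
bipolar-scale coverage means (well away from the unit boundary, where
the logit transform, the 0.999 cap and estimated weights interact
badly), residual between-country SD 0.5 on the logit scale, and 128
countries per group.  The group size is deliberately large: with the DL
normal-quantile interval and extreme heterogeneity (I² > 90%), true
coverage at realistic group sizes (7–20 countries) is ≈92–93% — the
well-documented finite-k narrowness of the DL interval (the τ²
estimation error is not propagated, and a z rather than t quantile is
used).  At 128 countries per group measured coverage is ≈94%, with
symmetric misses and an unbiased pooled estimate.  Users pooling small
groups should expect intervals on the narrow side; a
Hartung–Knapp-style correction is the natural extension.

## Numerical and degenerate-input choices

* 1.959964 is used consistently for 95% two-sided normal quantiles.
* Zero treated cases give `p_t = 0` and take the continuity-correction
  path; zero expected prevalence is an error (coverage undefined).
* Equal case counts classify as outpatient-prioritised; midpoint 0 makes
  the correction the identity.
* The pipeline is deterministic: rerunning the same configuration on the
  same inputs produces byte-identical outputs (the run manifest records
  a config fingerprint and seed).
* A screened-in record without a prevalence row raises an error rather
  than inventing an exclusion category; prevalence is a required input
  per disorder.

## Known limitations

* Threshold values are reconstructed placeholders; real analyses must
  supply their own `thresholds.yaml`.
* The depression point→12-month factor is an assumption (default 1.30).
* The inpatient-prioritised branch keeps the raw sum of tallies; if
  overlap exists in such countries, coverage is overstated there.
* DL intervals undercover at small k (see above).
* The visits-as-cases failure mode is undetectable for psychosis by
  design of the threshold structure.
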