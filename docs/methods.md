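# Methods

## The case definition and how it is evaluated

The claims-level sepsis surrogate is the conjunction of two components,
evaluated per hospitalization on 1-based calendar-day indices (day 1 =
admission day; length of stay = discharge − admission + 1, so a same-day
stay has LOS 1):

**Presumed serious infection.** The detector scans candidate initiation
days *d* and accepts the earliest one satisfying all three clauses:

* (a) some IV antibiotic agent is administered on *d* and that same agent
  was not administered on any of days *d−L .. d−1* ("newly initiated");
* (b) a blood culture occurs on some day *c* with |*c − d*| ≤ 2;
* (c) IV antibiotics — any agent, switches allowed — cover every day of
  *d .. d+3* (≥ 4 consecutive days).

**Organ dysfunction.** Any of six flag groups anywhere in the stay:
vasopressor; respiratory support (mechanical ventilation *or* oxygen
supplementation, pooled); kidney injury (diuretic, renal-dysfunction
code, or renal replacement therapy); liver-dysfunction code;
thrombocytopenia code; metabolic-acidosis code. Timing relative to the
infection episode is deliberately not constrained ("during hospital
stay"); the data model keeps ventilation and oxygen distinct so the
pooling is a classifier choice, not a data loss.

Design choices where the rule is underdetermined:

* *Lookback L.* "New" is not formally defined in claims practice; we use
  the narrowest self-consistent reading — the same agent absent from the
  previous `lookback_days` (default 2, matching the ±2-day window scale) —
  and expose it as a parameter.
* *Ordering.* The ±2-day window is symmetric, so no culture-before-
  antibiotic ordering is enforced; the antibiotic initiation day anchors
  the episode, and the reported culture day is the one closest to it
  (earliest on ties).
* *Censored runs.* By default the 4-day requirement is strict; with
  `allow_censored_run=True` a run truncated by discharge/death before day
  *d+3* qualifies if coverage reaches the last day of the stay (some
  surveillance definitions waive the run for early deaths; ours does not
  by default).
* *Age rule.* "Adults" means age ≥ 20 — the youngest analysis band is
  20–64, which includes age 20.
* *Non-monotonicity.* Clause (a) makes detection non-monotone in the
  event set: adding a same-agent dose just before an initiation day can
  strip it of novelty and flip a positive timeline negative. This is a
  property of the rule itself; the test suite asserts the corrected
  invariants (fresh-agent additions preserve episodes, whole-agent
  removals never create one) and checks the detector against a literal
  brute-force oracle that enumerates every (initiation, culture) pair on
  random ≤30-day timelines.

Cohort screening applies, in order: age filter → infection episode →
organ dysfunction → missing-site exclusion, and the four exclusion
tallies always partition the screened set (asserted as an invariant).
Site assignment: no recorded code → `missing` (excluded); exactly the
explicit "unknown" code → `unknown_explicit` (kept, its own category);
one site code → that site; ≥ 2 distinct codes → `multiple`.

## Cost metrics

Per-admission nominal-JPY costs are deflated to reference-year (2017)
prices with `cost × CPI_ref / CPI_year`, then converted to USD at 115.25
JPY/$, then aggregated. The order is mathematically immaterial (all three
steps are scalar multiplications) but fixed for bit-reproducibility.
Yearly gross costs are additionally rescaled by
`registrants_ref / registrants_year` to correct for growing database
coverage; the rescaling direction follows the formula even where a year's
registrant count exceeds the reference year's.

Mortality and survivor counts deduplicate repeat admissions by keeping
each patient's **first** admission over the whole study (ordered by
admission year, then admission id) — the least ambiguous reproducible
reading of "repeated admissions were excluded from mortality analysis".
The effective cost per survivor divides the **un-deduplicated** gross
cost of all admissions in a year by the deduplicated survivor count; the
numerator/denominator population mismatch is the metric's own definition.
By default the ECS numerator uses raw (not registrant-adjusted) gross
cost; `ecs_uses_adjusted_gross=True` switches it.

Quartiles use the median-of-halves convention (middle value dropped when
n is odd) so printed IQRs can be matched exactly on small fixtures.
Years with no admissions yield zero counts and NaN statistics rather than
errors.

## Trend tests and the cost model

Yearly trends are OLS of the aggregate on calendar year: slope per year,
t-based 95% CI and two-sided p on n−2 degrees of freedom. Trends operate
on yearly aggregates (8 points at study scale) rather than admission-level
rows, matching how per-year rates are reported; a series with zero
residual variance (constant, or an exact line) returns the slope with a
`degenerate` flag and NaN p-value instead of a fabricated one. Subgroup
trends recompute the yearly summaries within each level (age band, sex,
site, ICU, transfer, single-vs-multiple site, mechanical ventilation,
vasopressor, renal replacement therapy) and flag levels missing years.

The driver model is OLS on natural-log cost (regression residuals of raw
costs are heavily right-skewed; the log transform normalizes them) with
abdominal site and female sex as reference categories; age, length of
stay and admission year enter per unit. Coefficients and CIs are
exponentiated to multiplicative effects; `100 × (coef − 1)` is the
percent change. Rows with non-positive cost or missing site are dropped
with a warning count. Screening is the conventional two-stage procedure:
univariable log-cost regression per candidate, retained at p < 0.10 (the
model F-test, so multi-level site is screened as a block). VIFs
(`1/(1−R²_j)`) are reported per design column, warned above 10, never
auto-excluded; perfectly collinear or constant columns report `inf`, and
a rank-deficient design raises naming the columns. Covariate-adjusted
subgroup costs come from a log-cost model on target + covariates,
back-transformed at the design-matrix means with a delta-method CI; this
estimates the adjusted *geometric* mean (no smearing correction — a known
downward bias relative to arithmetic means, accepted because contrasts
between levels are the quantity of interest). A log-link gamma GLM would
be the natural alternative for arithmetic means.

No multiple-testing correction is applied anywhere; two-sided α = 0.05
for reporting.

## The synthetic generator

The generator emulates the *marginal* structure of the published
nationwide cohort (module `calibration`): yearly admission counts
(defaults are the published counts × a scale factor, 1/100 by default ≈
12,800 admissions, keeping the eight-year simulation under a minute on
one CPU), yearly sepsis mortality (24.1% → 16.9%), log-normal LOS with
the published yearly medians and σ = 0.88 on the log scale (implied by
the published mean/median ratio ≈ 50.3/34), and a multiplicative
log-normal cost model whose driver effects equal the published log-cost
regression coefficients — so parameter-recovery tests have exact ground
truth. Remaining values, chosen once for realism: residual log-cost SD
0.4 (cost models with LOS as a covariate typically leave residual SD
0.4–0.6); base log cost 14.0 (nominal JPY), calibrated so realized yearly
mean per-hospitalization costs land on the published $19–26k scale; site
mixture with the three published frequencies (respiratory 0.33, multiple
0.28, abdominal 0.13) and chosen minor-site/missing frequencies; male
fraction 0.589, ICU 0.156, transfer 0.239 (published); sepsis fraction
0.9; repeat-admission fraction 0.05; discretized-normal ages (mean 77,
SD 13, truncated 18–104) with a 0.5% pediatric admixture to exercise the
age filter; surgery 0.25 and binomial(8, 0.25) chronic diseases.

True sepsis cases emit rule-exact timelines (culture within the window,
new-agent run ≥ 4 days — occasionally with a mid-run agent switch — plus
1–3 dysfunction events); non-sepsis cases violate exactly one clause
drawn from four adversarial modes (3-day run, culture shifted ≥ 3 days
off, no culture, no dysfunction), so the classifier's agreement with
ground truth is exactly 100% by construction — which is what makes any
disagreement a real defect. `perturb_to_negative` applies the same
single-clause edits to arbitrary positive timelines and verifies the flip,
raising when a mode is inapplicable.

What the generator does **not** emulate — and what passing tests
therefore do not show about real claims: ICD-10 coding behaviour and
code-frequency drift, within-year seasonality and calendar dates, tariff
line items (costs are totals), correlation between severity and site or
between LOS and mortality, inter-hospital variation, and coding errors.
Real extracts will also contain rule-ambiguous timelines (e.g. chronic
suppressive antibiotics) that the generator never produces.

The `null_config` variant flattens mortality, LOS, yearly counts and the
per-year cost multiplier for type-I-error studies of the trend test; the
null study also uses a flat CPI series, since a varying deflator is
itself a deterministic yearly trend.

## Problem sizes and numerical choices

Test and acceptance problem sizes are the package's own desk-scale
choices: the shared fixture uses scale 3/1000 (~3,800 admissions);
parameter recovery runs at scale 1/20 (~64,000 generated, ~54,000
included), where every multiplier is recovered within ±5% (observed ≤ ~2%);
null calibration uses 1,000 replicates at scale 1/1000; the acceptance
script runs the pipeline at scale 1/50. Degenerate inputs are handled
explicitly rather than numerically: LOS < 1, negative costs and unknown
vocabulary tokens are validation errors; zero survivors yields NaN ECS
with a warning; empty event lists classify as non-sepsis.

## Known limitations

* The case definition is a claims surrogate, not a clinical (SOFA-based)
  sepsis definition; no laboratory data are modelled.
* First-admission dedup is one of several defensible readings of
  repeat-admission exclusion (alternatives: per-year dedup, last
  admission).
* Published per-hospitalization and daily-cost trend rates are not exactly
  reproducible from yearly means alone (they depend on admission-level
  weighting not derivable from aggregates); both granularities are exposed
  and the aggregate is the default.
* The ICD-10 → site/dysfunction mapping is a user-supplied upstream step;
  the pipeline consumes pre-abstracted labels.
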