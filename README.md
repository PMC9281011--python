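# sepsistrend

Claims-based sepsis cohort construction and cost-effectiveness trend
analysis for administrative hospital billing data.

## The problem

National claims systems — such as Japan's DPC (Diagnosis Procedure
Combination) bundled-payment database — record every acute-care
hospitalization with its diagnoses, procedures, daily drug
administrations and total cost, but no laboratory values. Epidemiologists
studying sepsis at national scale therefore need:

1. **A rule-based sepsis case definition** that works on claims signals
   alone. An admission counts as sepsis when it shows *presumed serious
   infection* — a newly initiated intravenous antibiotic within ±2
   calendar days of a blood culture, with IV antibiotic coverage on at
   least 4 consecutive days — **and** at least one organ-dysfunction
   marker during the stay (vasopressor, mechanical ventilation or oxygen
   supplementation, kidney-injury markers, liver dysfunction,
   thrombocytopenia, metabolic acidosis). Adults (age ≥ 20) are included;
   admissions with a missing site of infection are excluded, and multiple
   recorded sites collapse to a single "multiple" category.

2. **Comparable yearly cost aggregates.** Nominal per-hospitalization
   costs are deflated to reference-year prices,
   `cost × CPI_ref / CPI_year`, converted to USD (115.25 JPY/$), and
   yearly gross costs are rescaled by the number of registered patients to
   correct for growing database coverage.

3. **A cost-effectiveness metric and its trend.** The *effective cost per
   survivor* (ECS) for year *y* is

   `ECS_y = (gross cost of all admissions in y) / (survivors in y)`,

   with survivors counted after removing repeat admissions (first
   admission per patient). Yearly trends are OLS slopes of the aggregate
   on calendar year with t-based 95% CIs (`YearlyTrend`), overall and
   within subgroups (age bands 20–64 / 65–74 / ≥75, sex, site, ICU,
   transfer, organ-support therapies).

4. **A driver model for costs.** Per-hospitalization costs are
   right-skewed, so drivers are estimated by OLS on log cost
   (`LogCostModel`): age, sex, chronic diseases, infection site (abdominal
   reference), ICU admission, surgery, length of stay and admission year.
   Exponentiated coefficients are multiplicative effects —
   `100 × (coef − 1)` is the percent cost change — with univariable
   screening at p < 0.10 and VIF multicollinearity diagnostics.

Because patient-level claims are not public, the package ships a
**synthetic claims generator** (`sepsistrend.simulate`) that emulates the
published cohort structure — yearly counts growing from 67,318 (2010) to
233,825 (2017), mortality declining 24.1% → 16.9%, log-normal stays with
declining medians, and a multiplicative log-normal cost model whose driver
effects equal the published regression coefficients — and emits rule-exact
event timelines with ground-truth sepsis labels, so every stage of the
pipeline is testable end to end.

## Worked example

```python
import sepsistrend as st

cfg = st.default_config(scale=0.005, seed=11)        # 1/200 of study scale
admissions, events, truth = st.generate(cfg)
cohort = st.build_cohort(admissions, events)

series = st.default_series_config()                  # CPI, registrants, FX
summary = st.yearly_summary(cohort, series)
print(st.effective_cost_trend(summary).summary())

model = st.LogCostModel.from_dataframe(cohort).fit()
print(model.as_frame().loc[["icu", "surgery", "per_year"]].round(3))
```

prints

```
slope = -1366.83/year [95% CI -1746.12 to -987.551], p = 0.0001181 (8 years)
          multiplier  ci_low  ci_high  p_value  percent_change    vif
icu            1.750   1.700    1.801      0.0          74.952  1.002
surgery        2.164   2.112    2.217      0.0         116.384  1.002
per_year       0.971   0.966    0.975      0.0          -2.942  1.011
```

The effective cost per survivor falls by about $1,400 per year in this
1/200-scale replicate (p < 0.001): survival improves and
per-hospitalization costs shrink simultaneously, so each survivor costs
less over time. The cost model recovers the generator's ground truth:
ICU admission multiplies cost by ~1.75 (+75%), surgery by ~2.16, and each
later admission year by ~0.97 (−3% per year), all with VIFs near 1 (no
multicollinearity).

The same analysis is scriptable from a shell:

```bash
sepsistrend simulate --seed 11 --scale 0.005 --outdir data/
sepsistrend identify --admissions data/admissions.csv --events data/events.csv --out cohort.csv
sepsistrend analyze trends --cohort cohort.csv --out analysis/
sepsistrend report analysis/
```

or in one step: `sepsistrend run --seed 11 --outdir analysis/`.

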