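"""Yearly trend tests and the admission-level log-cost model."""

import numpy as np
import pandas as pd
import pytest

import sepsistrend.calibration as cal
from sepsistrend import (
    adjusted_subgroup_costs,
    all_subgroup_trends,
    default_config,
    effective_cost_trend,
    fit_cost_model,
    generate,
    linear_trend,
    percent_change,
    screen_variables,
    subgroup_trends,
    vif,
    yearly_summary,
)
from sepsistrend.simulate import GeneratorConfig
from sepsistrend.trends import YearlyTrend, age_band

from conftest import make_admission


# ------------------------------------------------------------- trends ----
def test_exact_line_recovers_slope():
    res = linear_trend([0, 1, 2, 3], [2010, 2011, 2012, 2013])
    assert res.slope == pytest.approx(1.0)
    assert res.degenerate  # zero residual variance: no p-value
    assert np.isnan(res.p_value)


def test_constant_series_degenerate():
    res = linear_trend([5.0, 5.0, 5.0, 5.0], [2010, 2011, 2012, 2013])
    assert res.slope == pytest.approx(0.0)
    assert res.degenerate and np.isnan(res.p_value)


def test_trend_input_validation():
    with pytest.raises(ValueError, match="at least 3"):
        linear_trend([1, 2], [2010, 2011])
    with pytest.raises(ValueError, match="strictly increasing"):
        linear_trend([1, 2, 3], [2010, 2010, 2011])
    with pytest.raises(ValueError, match="2012"):
        linear_trend([1.0, 2.0, np.nan], [2010, 2011, 2012])


def test_trend_matches_scipy_reference():
    rng = np.random.default_rng(0)
    years = np.arange(2010, 2018)
    vals = 3.0 * (years - 2010) + rng.normal(0, 2.0, size=8)
    res = linear_trend(vals, years)
    from scipy import stats

    ref = stats.linregress(years, vals)
    assert res.slope == pytest.approx(ref.slope)
    assert res.p_value == pytest.approx(ref.pvalue)
    half = stats.t.ppf(0.975, 6) * ref.stderr
    assert res.ci_low == pytest.approx(ref.slope - half)
    assert res.ci_high == pytest.approx(ref.slope + half)


def test_trend_equivariance():
    rng = np.random.default_rng(1)
    years = np.arange(2010, 2018)
    vals = rng.normal(10, 2, size=8)
    base = linear_trend(vals, years)
    shifted = linear_trend(vals, years + 100)
    assert shifted.slope == pytest.approx(base.slope)
    assert shifted.p_value == pytest.approx(base.p_value)
    scaled = linear_trend(vals * 3.5, years)
    assert scaled.slope == pytest.approx(3.5 * base.slope)
    assert scaled.ci_low == pytest.approx(3.5 * base.ci_low)


def test_published_mean_los_series_reproduces_printed_rate():
    """OLS of the cohort's eight yearly mean LOS values on calendar year
    gives the reported -1.7 days/year decline."""
    years = cal.STUDY_YEARS
    los = [cal.MEAN_LOS_BY_YEAR[y] for y in years]
    res = linear_trend(los, years)
    assert res.slope == pytest.approx(-1.7, abs=0.05)
    assert res.p_value < 0.001


def test_effective_cost_trend_is_negative_under_default_generator(
    small_cohort, series
):
    summary = yearly_summary(small_cohort, series)
    res = effective_cost_trend(summary)
    assert res.slope < 0
    assert res.p_value < 0.05


# --------------------------------------------------------- subgroups -----
def test_age_bands_boundaries():
    bands = age_band([19, 20, 64, 65, 74, 75, 90])
    assert pd.isna(bands.iloc[0])
    assert list(bands.iloc[1:]) == [
        "adults_20_64",
        "adults_20_64",
        "early_elderly_65_74",
        "early_elderly_65_74",
        "late_elderly_75_plus",
        "late_elderly_75_plus",
    ]


def test_subgroup_trends_levels_and_direction(small_cohort, series):
    table = subgroup_trends(small_cohort, series, "age_band")
    assert set(table["level"]) == {
        "adults_20_64",
        "early_elderly_65_74",
        "late_elderly_75_plus",
    }
    assert (table["slope"] < 0).all()

    table = subgroup_trends(small_cohort, series, "mechanical_ventilation")
    assert set(table["level"]) == {"yes", "no"}

    full = all_subgroup_trends(small_cohort, series)
    assert set(full["grouping"]) == {
        "age_band", "sex", "site", "icu", "transfer",
        "single_vs_multiple_site", "mechanical_ventilation", "vasopressor",
        "rrt",
    }


def test_unknown_grouping_rejected(small_cohort, series):
    with pytest.raises(ValueError, match="unknown grouping"):
        subgroup_trends(small_cohort, series, "ward")


# ------------------------------------------------------- cost model ------
def test_percent_change():
    assert percent_change(1.740) == pytest.approx(74.0)
    assert percent_change(1.0) == 0.0
    assert percent_change(0.966) == pytest.approx(-3.4)
    with pytest.raises(ValueError):
        percent_change(0.0)


def test_vif_closed_forms():
    rng = np.random.default_rng(3)
    a = rng.normal(size=4000)
    b = rng.normal(size=4000)
    ortho = vif(pd.DataFrame({"a": a, "b": b}))
    assert ortho["a"] == pytest.approx(1.0, abs=0.01)

    rho = 0.9
    c = rho * a + np.sqrt(1 - rho**2) * b
    # population VIF = 1 / (1 - rho^2) = 5.263
    corr = vif(pd.DataFrame({"a": a, "c": c}))
    assert corr["a"] == pytest.approx(1 / (1 - rho**2), rel=0.05)

    dup = vif(pd.DataFrame({"a": a, "b": b, "a2": a}))
    assert np.isinf(dup["a"]) and np.isinf(dup["a2"])
    assert np.isinf(vif(pd.DataFrame({"a": a, "const": np.ones_like(a)}))["const"])


def test_screening_retains_true_drivers(small_cohort):
    retained = screen_variables(small_cohort)
    # every generator driver is a true effect and must survive screening
    for var in ("icu", "surgery", "site", "chronic_disease_count", "los",
                "admission_year"):
        assert var in retained


def test_screening_excludes_pure_noise_at_alpha():
    """A covariate with zero true effect is excluded in about 90% of null
    replicates at the 0.10 screening threshold."""
    rng = np.random.default_rng(8)
    kept = 0
    reps = 300
    for _ in range(reps):
        n = 150
        df = pd.DataFrame(
            {
                "total_cost": np.exp(rng.normal(10, 0.5, n)),
                "icu_admission": rng.random(n) < 0.5,
            }
        )
        kept += "icu" in screen_variables(df, candidates=["icu"])
    rate = kept / reps
    se = np.sqrt(0.1 * 0.9 / reps)
    assert abs(rate - 0.10) < 3 * se + 0.02


def test_empty_candidate_list_errors(small_cohort):
    with pytest.raises(ValueError, match="empty"):
        screen_variables(small_cohort, candidates=[])


def test_cost_model_reference_and_format(small_cohort):
    res = fit_cost_model(small_cohort)
    frame = res.as_frame()
    assert "site:abdominal" not in frame.index  # reference category
    assert res.reference["site"] == "abdominal"
    assert (frame["multiplier"] > 0).all()
    assert ((frame["ci_low"] <= frame["multiplier"])
            & (frame["multiplier"] <= frame["ci_high"])).all()
    assert (frame.drop(index="intercept")["vif"] < 10).all()
    assert "Log-linear cost model" in res.summary()


def test_constant_cost_gives_unit_effects():
    """With a constant response every effect is exactly multiplicative 1
    and the intercept carries the whole (log) cost."""
    n = 60
    rows = []
    for i in range(n):
        rows.append(
            make_admission(
                admission_id=f"A{i}", patient_id=f"P{i}",
                total_cost=1_000_000.0, length_of_stay=5 + i % 20,
                age=40 + i % 50,
            )
        )
    frame = pd.concat(rows, ignore_index=True)
    frame["site_label"] = "abdominal"
    res = fit_cost_model(frame, variables=("age", "los"))
    assert res.multipliers["age_per_year"] == pytest.approx(1.0)
    assert res.multipliers["per_los_day"] == pytest.approx(1.0)
    assert res.multipliers["intercept"] == pytest.approx(1_000_000.0)


def test_aliased_columns_raise_singular_design():
    n = 40
    rows = [
        make_admission(admission_id=f"A{i}", patient_id=f"P{i}", age=70)
        for i in range(n)
    ]
    frame = pd.concat(rows, ignore_index=True)
    frame["site_label"] = "abdominal"
    # constant age is aliased with the intercept
    with pytest.raises(ValueError, match="singular design"):
        fit_cost_model(frame, variables=("age", "los"))


def test_adjusted_subgroup_costs_without_confounding():
    """With covariates independent of the target and no noise, adjusted
    means equal the raw group geometric means."""
    rng = np.random.default_rng(5)
    n = 500
    icu = rng.random(n) < 0.4
    df = pd.DataFrame(
        {
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
            "age": rng.integers(40, 90, n),
            "chronic_disease_count": rng.integers(0, 5, n),
            "site_label": rng.choice(["abdominal", "respiratory"], n),
            "icu_admission": icu,
            "total_cost": np.exp(13.0 + 0.5 * icu),
        }
    )
    out = adjusted_subgroup_costs(df, "icu").set_index("level")
    geo_no = np.exp(np.mean(np.log(df.loc[~icu, "total_cost"])))
    geo_yes = np.exp(np.mean(np.log(df.loc[icu, "total_cost"])))
    assert out.loc[False, "adjusted_mean"] == pytest.approx(geo_no, rel=1e-6)
    assert out.loc[True, "adjusted_mean"] == pytest.approx(geo_yes, rel=1e-6)


def test_adjusted_subgroup_costs_removes_confounding():
    """When ICU admissions are also longer stays, raw means are biased but
    the adjusted ICU effect matches the ground-truth multiplier."""
    cfg = default_config(scale=0.004)
    adm, _, _ = generate(cfg, seed=13, with_events=False)
    adm = adm[adm["infection_site_codes"].map(len) > 0].copy()
    adm["site_label"] = adm["infection_site_codes"].map(
        lambda c: "multiple" if len(c) > 1
        else ("unknown_explicit" if c == frozenset({"unknown"}) else next(iter(c)))
    )
    # confound: inflate LOS (a cost driver) for ICU admissions
    adm.loc[adm["icu_admission"], "length_of_stay"] += 40
    adm.loc[adm["icu_admission"], "total_cost"] *= (
        cfg.cost_multipliers["per_los_day"] ** 40
    )
    out = adjusted_subgroup_costs(
        adm, "icu", covariates=("sex", "age", "chronic_disease_count", "site",
                                "los"),
    ).set_index("level")
    ratio = out.loc[True, "adjusted_mean"] / out.loc[False, "adjusted_mean"]
    assert ratio == pytest.approx(cfg.cost_multipliers["icu"], rel=0.10)
    raw_ratio = (
        np.exp(np.log(adm.loc[adm["icu_admission"], "total_cost"]).mean())
        / np.exp(np.log(adm.loc[~adm["icu_admission"], "total_cost"]).mean())
    )
    assert raw_ratio > ratio * 1.05  # the unadjusted contrast is biased up


def test_single_level_target_errors():
    df = make_admission()
    df["site_label"] = "abdominal"
    with pytest.raises(ValueError, match="fewer than 2"):
        adjusted_subgroup_costs(df, "icu")
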