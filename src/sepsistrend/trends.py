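"""Yearly linear-trend tests on cohort aggregates.

The trend estimate is an ordinary least-squares regression of a yearly
aggregate (effective cost per survivor, mean cost per hospitalization,
mean length of stay, ...) on calendar year: the slope is the change per
year in the aggregate's units, with a two-sided t test on n-2 degrees of
freedom and a t-based 95% confidence interval.  Trends operate on the
yearly aggregates (eight points in the reference cohort), matching how
per-year rates are reported; admission-level modelling lives in
:mod:`sepsistrend.costmodel`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .costs import yearly_summary
from .identify import SepsisCohort

#: age bands used for subgroup analyses: adults, early elderly, late elderly
AGE_BANDS = (
    ("adults_20_64", 20, 64),
    ("early_elderly_65_74", 65, 74),
    ("late_elderly_75_plus", 75, None),
)

GROUPINGS = (
    "age_band",
    "sex",
    "site",
    "icu",
    "transfer",
    "single_vs_multiple_site",
    "mechanical_ventilation",
    "vasopressor",
    "rrt",
)


@dataclass(frozen=True)
class TrendResult:
    """Slope per calendar year with 95% CI and two-sided p-value.

    ``degenerate`` marks a series with zero residual variance (e.g. a
    constant series), for which no meaningful p-value exists; the slope is
    still reported and the CI collapses onto it.
    """

    slope: float
    ci_low: float
    ci_high: float
    p_value: float
    n_years: int
    intercept: float = float("nan")
    stderr: float = float("nan")
    degenerate: bool = False

    def summary(self) -> str:
        if self.degenerate:
            return (
                f"slope = {self.slope:.6g}/year over {self.n_years} years "
                "(degenerate fit: zero residual variance, no p-value)"
            )
        return (
            f"slope = {self.slope:.6g}/year "
            f"[95% CI {self.ci_low:.6g} to {self.ci_high:.6g}], "
            f"p = {self.p_value:.4g} ({self.n_years} years)"
        )


class YearlyTrend:
    """OLS model of a yearly aggregate on calendar year.

    Parameters
    ----------
    values, years
        Aligned aggregate values and strictly increasing calendar years;
        at least three points are required.
    """

    def __init__(self, values, years):
        values = np.asarray(values, dtype=float)
        years = np.asarray(years, dtype=float)
        if len(values) != len(years):
            raise ValueError("values and years must be aligned")
        if len(years) < 3:
            raise ValueError("need at least 3 yearly points for a trend test")
        if np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.isnan(values).any():
            bad = [int(y) for y, v in zip(years, values) if np.isnan(v)]
            raise ValueError(f"aggregate undefined for year(s) {bad}")
        self.values = values
        self.years = years

    def fit(self) -> TrendResult:
        exog = sm.add_constant(self.years)
        res = sm.OLS(self.values, exog).fit()
        n = len(self.years)
        slope = float(res.params[1])
        # zero residual variance: an exact line (or constant); the t test
        # is undefined there
        scale = float(res.ssr / (n - 2))
        mean_sq = float(np.mean(self.values**2))
        if scale <= 1e-12 * max(mean_sq, 1.0):
            return TrendResult(
                slope=slope,
                ci_low=slope,
                ci_high=slope,
                p_value=float("nan"),
                n_years=n,
                intercept=float(res.params[0]),
                stderr=0.0,
                degenerate=True,
            )
        tcrit = stats.t.ppf(0.975, n - 2)
        se = float(res.bse[1])
        return TrendResult(
            slope=slope,
            ci_low=slope - tcrit * se,
            ci_high=slope + tcrit * se,
            p_value=float(res.pvalues[1]),
            n_years=n,
            intercept=float(res.params[0]),
            stderr=se,
        )


def linear_trend(values, years) -> TrendResult:
    """Convenience wrapper: fit :class:`YearlyTrend` and return the result."""
    return YearlyTrend(values, years).fit()


def effective_cost_trend(summaries: pd.DataFrame) -> TrendResult:
    """Trend of the effective cost per survivor — the primary outcome."""
    vals = summaries["effective_cost_per_survivor"].to_numpy(dtype=float)
    years = summaries["year"].to_numpy(dtype=float)
    if np.isnan(vals).any():
        bad = [int(y) for y, v in zip(years, vals) if np.isnan(v)]
        raise ValueError(
            f"effective cost per survivor undefined for year(s) {bad}"
        )
    return linear_trend(vals, years)


def age_band(ages) -> pd.Series:
    """Map ages to the three adult bands (20-64, 65-74, >=75)."""
    ages = pd.Series(ages)
    out = pd.Series(pd.NA, index=ages.index, dtype=object)
    for label, lo, hi in AGE_BANDS:
        mask = ages >= lo if hi is None else (ages >= lo) & (ages <= hi)
        out[mask] = label
    return out


def _grouping_levels(frame: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping == "age_band":
        return age_band(frame["age"])
    if grouping == "sex":
        return frame["sex"]
    if grouping == "site":
        return frame["site_label"]
    if grouping == "icu":
        return frame["icu_admission"].map({True: "yes", False: "no"})
    if grouping == "transfer":
        return (frame["discharge_status"] == "transfer").map(
            {True: "yes", False: "no"}
        )
    if grouping == "single_vs_multiple_site":
        return (frame["site_label"] == "multiple").map(
            {True: "multiple", False: "single"}
        )
    if grouping in ("mechanical_ventilation", "vasopressor", "rrt"):
        col = {
            "mechanical_ventilation": "has_mechanical_ventilation",
            "vasopressor": "has_vasopressor",
            "rrt": "has_rrt",
        }[grouping]
        return frame[col].map({True: "yes", False: "no"})
    raise ValueError(f"unknown grouping {grouping!r}; choose from {GROUPINGS}")


def subgroup_trends(
    cohort,
    series,
    grouping: str,
    *,
    outcome: str = "effective_cost_per_survivor",
    ecs_uses_adjusted_gross: bool = False,
) -> pd.DataFrame:
    """Per-level yearly trend of a cohort aggregate (default: ECS).

    Splits the included cohort by ``grouping``, recomputes the yearly
    summaries within each level, and fits the linear trend of ``outcome``
    on year.  Levels missing the outcome in some years are fitted on the
    available years and flagged (``complete_years=False``).
    """
    frame = cohort.included if isinstance(cohort, SepsisCohort) else cohort
    levels = _grouping_levels(frame, grouping)
    all_years = sorted(frame["admission_year"].unique())
    rows = []
    for level in sorted(levels.dropna().unique(), key=str):
        sub = frame[levels == level]
        summary = yearly_summary(
            sub, series, ecs_uses_adjusted_gross=ecs_uses_adjusted_gross
        )
        ok = summary[outcome].notna()
        complete = bool(ok.all() and len(summary) == len(all_years))
        res = linear_trend(
            summary.loc[ok, outcome].to_numpy(),
            summary.loc[ok, "year"].to_numpy(),
        )
        rows.append(
            {
                "grouping": grouping,
                "level": level,
                "n_admissions": len(sub),
                "slope": res.slope,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "n_years": res.n_years,
                "degenerate": res.degenerate,
                "complete_years": complete,
            }
        )
    return pd.DataFrame(rows)


def all_subgroup_trends(cohort, series, **kwargs) -> pd.DataFrame:
    """Subgroup ECS trend table across every supported grouping."""
    return pd.concat(
        [subgroup_trends(cohort, series, g, **kwargs) for g in GROUPINGS],
        ignore_index=True,
    )
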