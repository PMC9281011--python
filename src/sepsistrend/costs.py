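"""Cost metrics: CPI deflation, USD conversion, yearly aggregates and the
effective cost per survivor.

Pipeline convention (fixed for reproducibility, mathematically order-free):
per-admission nominal-JPY costs are first deflated to reference-year prices
with the consumer price index, then converted to USD, then aggregated.

The cost-effectiveness metric is the **effective cost per survivor**:
yearly gross medical cost of *all* treated patients (survivors and
non-survivors, every admission) divided by the number of patients who
survived that year.  Survivor counts deduplicate repeat admissions —
only the first admission per patient counts toward mortality — while the
gross-cost numerator keeps every admission, following the metric's
definition.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .identify import SepsisCohort
from .records import SeriesConfig


def cpi_adjust(cost, year, series: SeriesConfig):
    """Deflate nominal cost(s) to reference-year prices.

    ``adjusted = cost * CPI[reference_year] / CPI[admission year]``.
    ``cost`` and ``year`` may be scalars or aligned arrays.
    """
    ref = series.cpi_by_year[series.reference_year]
    years = np.atleast_1d(np.asarray(year))
    missing = sorted({int(y) for y in years} - set(series.cpi_by_year))
    if missing:
        raise KeyError(f"CPI series missing year(s) {missing}")
    cpi = np.array([series.cpi_by_year[int(y)] for y in years])
    out = np.asarray(cost) * ref / cpi
    return float(out[0]) if np.isscalar(year) else out


def to_usd(cost, series: SeriesConfig):
    """Convert JPY cost(s) to USD at the configured exchange rate."""
    return np.asarray(cost) / series.jpy_per_usd if not np.isscalar(cost) else (
        cost / series.jpy_per_usd
    )


def adjusted_cost_usd(frame: pd.DataFrame, series: SeriesConfig) -> pd.Series:
    """Per-admission CPI-adjusted, USD-converted total cost."""
    adj = cpi_adjust(
        frame["total_cost"].to_numpy(), frame["admission_year"].to_numpy(), series
    )
    return pd.Series(adj / series.jpy_per_usd, index=frame.index, name="cost_usd")


def daily_cost(frame: pd.DataFrame, series: SeriesConfig) -> pd.Series:
    """Adjusted USD cost per hospital day (total cost / length of stay)."""
    if (frame["length_of_stay"] < 1).any():
        raise ValueError("length_of_stay must be >= 1 for daily cost")
    return adjusted_cost_usd(frame, series) / frame["length_of_stay"]


def registrant_adjust(
    gross_by_year: Mapping[int, float], series: SeriesConfig
) -> dict[int, float]:
    """Rescale yearly gross costs for growing claims-system coverage.

    ``adjusted[y] = gross[y] * registrants[reference_year] / registrants[y]``;
    the reference year is unchanged by construction.
    """
    missing = sorted(set(gross_by_year) - set(series.registrants_by_year))
    if missing:
        raise KeyError(f"registrant series missing year(s) {missing}")
    ref = series.registrants_by_year[series.reference_year]
    return {
        int(y): g * ref / series.registrants_by_year[int(y)]
        for y, g in gross_by_year.items()
    }


def _first_admissions(frame: pd.DataFrame) -> pd.DataFrame:
    """Retain the earliest admission per patient over the whole study."""
    ordered = frame.sort_values(["admission_year", "admission_id"], kind="stable")
    return ordered.drop_duplicates(subset="patient_id", keep="first")


def survivors_per_year(cohort) -> pd.DataFrame:
    """Per-year unique patients, deaths and survivors after dedup.

    Repeat admissions are removed from the mortality tally by keeping only
    each patient's first admission; a patient is counted in the year of
    that admission, and survives iff it did not end in death.
    """
    frame = cohort.included if isinstance(cohort, SepsisCohort) else cohort
    first = _first_admissions(frame)
    died = first["discharge_status"] == "death"
    out = (
        pd.DataFrame(
            {
                "admission_year": first["admission_year"],
                "death": died.astype(int),
            }
        )
        .groupby("admission_year")
        .agg(n_unique_patients=("death", "size"), n_deaths=("death", "sum"))
        .reset_index()
        .rename(columns={"admission_year": "year"})
    )
    out["survivors"] = out["n_unique_patients"] - out["n_deaths"]
    return out


def effective_cost_per_survivor(gross_cost: float, survivors: float) -> float:
    """Gross cost of all admissions divided by deduplicated survivors.

    Returns NaN (with a warning) when there are no survivors.
    """
    if survivors == 0:
        warnings.warn("no survivors: effective cost per survivor undefined")
        return float("nan")
    return gross_cost / survivors


def quartiles(values) -> tuple[float, float, float]:
    """(Q1, median, Q3) by the median-of-halves convention.

    The sorted sample is split at the median (the middle value is dropped
    when n is odd); Q1 and Q3 are the medians of the halves.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 0:
        return (float("nan"),) * 3
    med = float(np.median(x))
    if n < 3:
        return med if n == 1 else float(x[0]), med, med if n == 1 else float(x[1])
    lower = x[: n // 2]
    upper = x[n // 2 + 1 :] if n % 2 else x[n // 2 :]
    return float(np.median(lower)), med, float(np.median(upper))


def _describe(values, prefix: str) -> dict[str, float]:
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        return {
            f"{prefix}_{k}": float("nan")
            for k in ("mean", "sd", "median", "q1", "q3")
        }
    q1, med, q3 = quartiles(x)
    return {
        f"{prefix}_mean": float(np.mean(x)),
        f"{prefix}_sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        f"{prefix}_median": med,
        f"{prefix}_q1": q1,
        f"{prefix}_q3": q3,
    }


def yearly_summary(
    cohort,
    series: SeriesConfig,
    *,
    years=None,
    ecs_uses_adjusted_gross: bool = False,
) -> pd.DataFrame:
    """One row per year with the cohort's cost and stay aggregates.

    Columns: admission / unique-patient / death / survivor counts, gross
    and registrant-adjusted gross cost, mean/SD/median/quartiles of
    per-hospitalization cost, daily cost per person, and length of stay,
    and the effective cost per survivor.  All costs are CPI-adjusted and
    USD-converted.  By default the ECS numerator is the raw (unadjusted)
    gross cost; set ``ecs_uses_adjusted_gross`` to use the
    registrant-adjusted series instead.
    """
    frame = cohort.included if isinstance(cohort, SepsisCohort) else cohort
    frame = frame.copy()
    frame["cost_usd"] = adjusted_cost_usd(frame, series)
    frame["daily_usd"] = frame["cost_usd"] / frame["length_of_stay"]

    if years is None:
        years = sorted(frame["admission_year"].unique())
    surv = survivors_per_year(frame).set_index("year")

    gross_by_year = {
        int(y): float(frame.loc[frame["admission_year"] == y, "cost_usd"].sum())
        for y in years
    }
    adjusted_by_year = registrant_adjust(gross_by_year, series)

    rows = []
    for y in years:
        sub = frame[frame["admission_year"] == y]
        row: dict = {"year": int(y), "n_admissions": len(sub)}
        if y in surv.index:
            row["n_unique_patients"] = int(surv.loc[y, "n_unique_patients"])
            row["n_deaths"] = int(surv.loc[y, "n_deaths"])
            row["survivors"] = int(surv.loc[y, "survivors"])
        else:
            row.update(n_unique_patients=0, n_deaths=0, survivors=0)
        row["mortality_pct"] = (
            100.0 * row["n_deaths"] / row["n_unique_patients"]
            if row["n_unique_patients"]
            else float("nan")
        )
        row["gross_cost"] = gross_by_year[int(y)]
        row["adjusted_gross_cost"] = adjusted_by_year[int(y)]
        row.update(_describe(sub["cost_usd"], "cost"))
        row.update(_describe(sub["daily_usd"], "daily_cost"))
        row.update(_describe(sub["length_of_stay"], "los"))
        ecs_numerator = (
            row["adjusted_gross_cost"] if ecs_uses_adjusted_gross else row["gross_cost"]
        )
        if row["survivors"]:
            row["effective_cost_per_survivor"] = effective_cost_per_survivor(
                ecs_numerator, row["survivors"]
            )
        else:
            row["effective_cost_per_survivor"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def summary_total_row(summary: pd.DataFrame, frame, series: SeriesConfig) -> dict:
    """Whole-study totals matching the yearly summary's columns."""
    frame = frame.included if isinstance(frame, SepsisCohort) else frame
    frame = frame.copy()
    frame["cost_usd"] = adjusted_cost_usd(frame, series)
    frame["daily_usd"] = frame["cost_usd"] / frame["length_of_stay"]
    first = _first_admissions(frame)
    deaths = int((first["discharge_status"] == "death").sum())
    row = {
        "year": "total",
        "n_admissions": int(summary["n_admissions"].sum()),
        "n_unique_patients": len(first),
        "n_deaths": deaths,
        "survivors": len(first) - deaths,
        "mortality_pct": 100.0 * deaths / len(first) if len(first) else float("nan"),
        "gross_cost": float(summary["gross_cost"].sum()),
        "adjusted_gross_cost": float(summary["adjusted_gross_cost"].sum()),
    }
    row.update(_describe(frame["cost_usd"], "cost"))
    row.update(_describe(frame["daily_usd"], "daily_cost"))
    row.update(_describe(frame["length_of_stay"], "los"))
    row["effective_cost_per_survivor"] = (
        row["gross_cost"] / row["survivors"] if row["survivors"] else float("nan")
    )
    return row
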