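"""Admission-level log-linear model of per-hospitalization cost.

Per-hospitalization costs are heavily right-skewed, so the model is
ordinary least squares on natural-log cost:

    ln cost ~ age + male + chronic diseases + site + ICU + surgery
              + length of stay + admission year

with the abdominal site as the reference category, age / length of stay /
admission year entered per unit (year, day, calendar year).  Exponentiated
coefficients are multiplicative effects on cost — ``100 * (coef - 1)`` is
the percent change per unit — and multicollinearity is diagnosed with
variance inflation factors (reported, never auto-excluded).

Variable screening follows the two-stage convention of claims cost
analyses: each candidate is tested in a univariable log-cost regression
and retained for the multivariable model when its p-value is below 0.10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .identify import SepsisCohort

DEFAULT_VARIABLES = (
    "age",
    "sex",
    "chronic_disease_count",
    "site",
    "icu",
    "surgery",
    "los",
    "admission_year",
)

SITE_REFERENCE = "abdominal"

#: model term for each variable name
_TERMS = {
    "age": "age",
    "sex": "C(sex, Treatment('female'))",
    "chronic_disease_count": "chronic_disease_count",
    "site": f"C(site_label, Treatment('{SITE_REFERENCE}'))",
    "icu": "icu_admission",
    "surgery": "surgery",
    "los": "length_of_stay",
    "admission_year": "admission_year",
}

#: readable labels for the fitted design columns
_LABELS = {
    "Intercept": "intercept",
    "age": "age_per_year",
    "C(sex, Treatment('female'))[T.male]": "male",
    "chronic_disease_count": "per_chronic_disease",
    "icu_admission[T.True]": "icu",
    "surgery[T.True]": "surgery",
    "length_of_stay": "per_los_day",
    "admission_year": "per_year",
}


def _label(design_name: str) -> str:
    if design_name in _LABELS:
        return _LABELS[design_name]
    if design_name.startswith("C(site_label"):
        return "site:" + design_name.split("[T.")[1].rstrip("]")
    return design_name


def percent_change(coefficient: float) -> float:
    """Percent change in cost per unit: ``100 * (coefficient - 1)``."""
    if coefficient <= 0:
        raise ValueError(f"exponentiated coefficient must be > 0, got {coefficient}")
    return 100.0 * (coefficient - 1.0)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per design column.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing column j on the others.
    A constant column, or a perfectly collinear one, reports ``inf``.
    """
    X = np.asarray(design, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two design columns")
    out = {}
    for j, name in enumerate(design.columns):
        y = X[:, j]
        if np.ptp(y) == 0:
            out[name] = float("inf")
            continue
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(y, others).fit().rsquared
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return pd.Series(out, name="vif")


def _prepare(frame: pd.DataFrame, cost_col: str) -> pd.DataFrame:
    df = frame.copy()
    nonpos = df[cost_col] <= 0
    if nonpos.any():
        warnings.warn(f"dropping {int(nonpos.sum())} row(s) with cost <= 0")
        df = df[~nonpos]
    if "site_label" in df.columns:
        missing = df["site_label"] == "missing"
        if missing.any():
            warnings.warn(
                f"dropping {int(missing.sum())} row(s) with missing site label"
            )
            df = df[~missing]
    df = df.copy()
    df["log_cost"] = np.log(df[cost_col])
    return df


@dataclass
class LogCostResults:
    """Fitted log-cost model: multiplicative effects, CIs, p-values, VIF."""

    multipliers: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    vif: pd.Series
    nobs: int
    n_dropped: int
    reference: dict[str, str]
    _sm_results: object = None

    def percent_changes(self) -> pd.Series:
        return (self.multipliers - 1.0) * 100.0

    def as_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "multiplier": self.multipliers,
                "ci_low": self.conf_int["ci_low"],
                "ci_high": self.conf_int["ci_high"],
                "p_value": self.pvalues,
                "percent_change": self.percent_changes(),
            }
        )
        out["vif"] = self.vif.reindex(out.index)
        return out

    def summary(self) -> str:
        lines = [
            f"Log-linear cost model: n = {self.nobs} "
            f"({self.n_dropped} row(s) dropped)",
            f"reference categories: {self.reference}",
            self.as_frame().to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        high = self.vif[self.vif > 10]
        if len(high):
            lines.append(
                "WARNING: variance inflation factor > 10 for "
                f"{list(high.index)} — strong multicollinearity"
            )
        return "\n".join(lines)


class LogCostModel:
    """OLS model of log per-hospitalization cost on admission covariates.

    Build with :meth:`from_dataframe` (or from a :class:`SepsisCohort`),
    then :meth:`fit` to obtain :class:`LogCostResults`.
    """

    def __init__(self, frame: pd.DataFrame, variables=DEFAULT_VARIABLES,
                 cost_col: str = "total_cost"):
        unknown = [v for v in variables if v not in _TERMS]
        if unknown:
            raise ValueError(f"unknown variable(s) {unknown}; choose from {list(_TERMS)}")
        self.variables = tuple(variables)
        self.cost_col = cost_col
        self._raw = frame
        self.frame = _prepare(frame, cost_col)
        self.n_dropped = len(frame) - len(self.frame)
        self.formula = "log_cost ~ " + " + ".join(_TERMS[v] for v in self.variables)

    @classmethod
    def from_dataframe(cls, frame, variables=DEFAULT_VARIABLES,
                       cost_col: str = "total_cost") -> "LogCostModel":
        if isinstance(frame, SepsisCohort):
            frame = frame.included
        return cls(frame, variables=variables, cost_col=cost_col)

    def fit(self) -> LogCostResults:
        model = smf.ols(self.formula, data=self.frame)
        exog = pd.DataFrame(model.exog, columns=model.exog_names)
        rank = np.linalg.matrix_rank(model.exog)
        if rank < model.exog.shape[1]:
            raise ValueError(
                "singular design matrix: aliased column(s) among "
                f"{model.exog_names}"
            )
        res = model.fit()
        labels = [_label(n) for n in res.params.index]
        mult = pd.Series(np.exp(res.params.to_numpy()), index=labels,
                         name="multiplier")
        ci = np.exp(res.conf_int().to_numpy())
        conf = pd.DataFrame(ci, index=labels, columns=["ci_low", "ci_high"])
        pvals = pd.Series(res.pvalues.to_numpy(), index=labels, name="p_value")
        vifs = vif(exog.drop(columns="Intercept"))
        vifs.index = [_label(n) for n in vifs.index]
        reference = {}
        if "site" in self.variables:
            reference["site"] = SITE_REFERENCE
        if "sex" in self.variables:
            reference["sex"] = "female"
        return LogCostResults(
            multipliers=mult,
            conf_int=conf,
            pvalues=pvals,
            vif=vifs,
            nobs=int(res.nobs),
            n_dropped=self.n_dropped,
            reference=reference,
            _sm_results=res,
        )


def fit_cost_model(cohort, variables=DEFAULT_VARIABLES,
                   cost_col: str = "total_cost") -> LogCostResults:
    """Fit the multivariable log-cost model on a cohort (or frame)."""
    return LogCostModel.from_dataframe(cohort, variables=variables,
                                       cost_col=cost_col).fit()


def screen_variables(cohort, candidates=DEFAULT_VARIABLES, alpha: float = 0.10,
                     cost_col: str = "total_cost") -> list[str]:
    """Univariable screening: retain candidates with p < ``alpha``.

    Each candidate is fitted alone against log cost; the candidate's
    p-value is the model F test (which covers multi-level categorical
    candidates such as the infection site).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    frame = cohort.included if isinstance(cohort, SepsisCohort) else cohort
    df = _prepare(frame, cost_col)
    retained = []
    for var in candidates:
        if var not in _TERMS:
            raise ValueError(f"unknown variable {var!r}")
        res = smf.ols(f"log_cost ~ {_TERMS[var]}", data=df).fit()
        if float(res.f_pvalue) < alpha:
            retained.append(var)
    return retained


def adjusted_subgroup_costs(
    cohort,
    target: str,
    covariates=("sex", "age", "chronic_disease_count", "site"),
    cost_col: str = "total_cost",
) -> pd.DataFrame:
    """Covariate-adjusted mean cost per level of ``target``.

    Fits log cost on the target plus covariates, then reports each target
    level's back-transformed prediction at the covariate means (marginal
    standardization over the design-matrix means) with a delta-method 95%
    CI.  The back-transform estimates the geometric mean; no smearing
    correction is applied.
    """
    if target in covariates:
        raise ValueError("target cannot also be a covariate")
    frame = cohort.included if isinstance(cohort, SepsisCohort) else cohort
    df = _prepare(frame, cost_col)

    target_term = _TERMS.get(target, f"C({target})")
    levels = sorted(pd.unique(_target_values(df, target)), key=str)
    if len(levels) < 2:
        raise ValueError(f"target {target!r} has fewer than 2 levels")

    cov_terms = [_TERMS[c] for c in covariates]
    formula = "log_cost ~ " + " + ".join([target_term] + cov_terms)
    model = smf.ols(formula, data=df)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError(
            f"singular design matrix: aliased column(s) among {model.exog_names}"
        )
    res = model.fit()

    design_info = model.data.design_info
    slices = design_info.term_name_slices
    target_cols = None
    for term, sl in slices.items():
        if term != "Intercept" and target_term in term:
            target_cols = sl
            break
    if target_cols is None:
        raise ValueError(f"target term {target_term!r} not found in design")

    xbar = model.exog.mean(axis=0)
    cov = res.cov_params().to_numpy()
    tcrit = stats.t.ppf(0.975, res.df_resid)
    col_names = np.asarray(model.exog_names)

    rows = []
    for level in levels:
        x = xbar.copy()
        x[target_cols] = 0.0
        dummy = f"[T.{level}]"
        hit = [
            i
            for i in range(*target_cols.indices(len(col_names)))
            if col_names[i].endswith(dummy)
        ]
        for i in hit:
            x[i] = 1.0
        lp = float(x @ res.params.to_numpy())
        se = float(np.sqrt(x @ cov @ x))
        rows.append(
            {
                "level": level,
                "adjusted_mean": float(np.exp(lp)),
                "ci_low": float(np.exp(lp - tcrit * se)),
                "ci_high": float(np.exp(lp + tcrit * se)),
                "n": int((_target_values(df, target) == level).sum()),
            }
        )
    return pd.DataFrame(rows)


def _target_values(df: pd.DataFrame, target: str) -> pd.Series:
    mapping = {
        "sex": "sex",
        "site": "site_label",
        "icu": "icu_admission",
        "surgery": "surgery",
    }
    return df[mapping.get(target, target)]
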