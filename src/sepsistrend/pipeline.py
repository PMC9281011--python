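"""End-to-end pipeline: simulate -> identify -> cost tables -> trend tables.

A single config (YAML or JSON) drives every stage; all randomness flows
from one seed, so identical config + seed gives byte-identical outputs.
Each stage logs its counts and writes its table:

* ``admissions.csv`` / ``events.csv`` / ``ground_truth.csv`` (simulate)
* ``cohort.csv``        — one row per screened admission with the
  classification audit columns and exclusion reason
* ``table_yearly.csv``  — yearly cost / LOS / mortality aggregates plus a
  whole-study total row
* ``table_subgroups.csv`` — subgroup ECS trend table
* ``table_costmodel.csv`` — multivariable log-cost model
* ``trend_primary.csv`` — the ECS yearly trend (primary outcome)
* ``report.md``         — human-readable summary
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import costs, io, trends
from .costmodel import fit_cost_model
from .identify import EXCLUSION_REASONS, SepsisCohort, build_cohort
from .records import SeriesConfig
from .simulate import default_config, default_series_config, generate

log = logging.getLogger("sepsistrend")

YEARLY_TABLE = "table_yearly.csv"
SUBGROUP_TABLE = "table_subgroups.csv"
COSTMODEL_TABLE = "table_costmodel.csv"
PRIMARY_TREND = "trend_primary.csv"
REPORT = "report.md"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""

    outdir: str = "sepsistrend_out"
    simulate: bool = True
    seed: int = 0
    scale_factor: float = 0.01
    admissions_path: str | None = None
    events_path: str | None = None
    series: SeriesConfig = field(default_factory=default_series_config)
    age_threshold: int = 20
    antibiotic_lookback_days: int = 2
    allow_censored_run: bool = False
    ecs_uses_adjusted_gross: bool = False

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        series = (
            io.series_config_from_dict(data["series"])
            if "series" in data
            else default_series_config()
        )
        known = {
            k: v for k, v in data.items() if k in cls.__dataclass_fields__ and k != "series"
        }
        return cls(series=series, **known)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise PipelineError(name, exc) from exc

    return wrap


def write_cohort(cohort: SepsisCohort, path) -> None:
    out = cohort.frame.copy()
    out["infection_site_codes"] = out["infection_site_codes"].map(
        io.format_site_cell
    )
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out["exclusion_reason"] = out["exclusion_reason"].fillna("")
    out.to_csv(path, index=False)


def read_cohort(path) -> SepsisCohort:
    df = pd.read_csv(path, dtype={"admission_id": str, "patient_id": str},
                     keep_default_na=False)
    df["infection_site_codes"] = df["infection_site_codes"].map(io.parse_site_cell)
    for col in (
        "icu_admission", "surgery", "has_episode", "vasopressor",
        "respiratory_support", "kidney_injury", "liver_injury",
        "thrombocytopenia", "metabolic_acidosis", "any_dysfunction",
        "has_mechanical_ventilation", "has_vasopressor", "has_rrt",
        "is_sepsis", "included",
    ):
        if col in df.columns:
            df[col] = df[col].astype(str).isin(["1", "True", "true"])
    df["exclusion_reason"] = df["exclusion_reason"].replace("", None)
    exclusions = {
        key: int((df["exclusion_reason"] == key).sum()) for key in EXCLUSION_REASONS
    }
    return SepsisCohort(frame=df, exclusions=exclusions)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns the paths of the written outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    if config.simulate:
        gen_cfg = default_config(scale=config.scale_factor, seed=config.seed)
        admissions, events, truth = _stage("simulate")(generate, gen_cfg)
        for name, df, writer in (
            ("admissions.csv", admissions, io.write_admissions),
            ("events.csv", events, io.write_events),
        ):
            writer(df, outdir / name)
            outputs[name] = outdir / name
        truth.to_csv(outdir / "ground_truth.csv", index=False)
        outputs["ground_truth.csv"] = outdir / "ground_truth.csv"
        log.info("simulate: %d admissions, %d events", len(admissions), len(events))
    else:
        if not (config.admissions_path and config.events_path):
            raise PipelineError(
                "load", ValueError("admissions_path and events_path required")
            )
        admissions = _stage("load")(io.read_admissions, config.admissions_path)
        events = _stage("load")(io.read_events, config.events_path)
        log.info("load: %d admissions, %d events", len(admissions), len(events))

    report = _stage("validate")(io.validate, admissions, events)
    if not report.passed:
        raise PipelineError("validate", ValueError(str(report)))
    log.info("validate: PASS (%d admissions, %d events)",
             report.n_admissions, report.n_events)

    cohort = _stage("identify")(
        build_cohort,
        admissions,
        events,
        age_threshold=config.age_threshold,
        lookback_days=config.antibiotic_lookback_days,
        allow_censored_run=config.allow_censored_run,
    )
    write_cohort(cohort, outdir / "cohort.csv")
    outputs["cohort.csv"] = outdir / "cohort.csv"
    log.info(
        "identify: screened %d, included %d, exclusions %s",
        cohort.n_screened, cohort.n_included, cohort.exclusions,
    )

    summary = _stage("costs")(
        costs.yearly_summary,
        cohort,
        config.series,
        ecs_uses_adjusted_gross=config.ecs_uses_adjusted_gross,
    )
    total = costs.summary_total_row(summary, cohort, config.series)
    table1 = pd.concat([summary, pd.DataFrame([total])], ignore_index=True)
    table1.to_csv(outdir / YEARLY_TABLE, index=False)
    outputs[YEARLY_TABLE] = outdir / YEARLY_TABLE
    log.info("costs: %d year rows, gross total %.0f USD",
             len(summary), summary["gross_cost"].sum())

    primary = _stage("trends")(trends.effective_cost_trend, summary)
    pd.DataFrame(
        [
            {
                "outcome": "effective_cost_per_survivor",
                "slope_per_year": primary.slope,
                "ci_low": primary.ci_low,
                "ci_high": primary.ci_high,
                "p_value": primary.p_value,
                "n_years": primary.n_years,
            }
        ]
    ).to_csv(outdir / PRIMARY_TREND, index=False)
    outputs[PRIMARY_TREND] = outdir / PRIMARY_TREND
    log.info("trends: ECS %s", primary.summary())

    table2 = _stage("trends")(
        trends.all_subgroup_trends,
        cohort,
        config.series,
        ecs_uses_adjusted_gross=config.ecs_uses_adjusted_gross,
    )
    table2.to_csv(outdir / SUBGROUP_TABLE, index=False)
    outputs[SUBGROUP_TABLE] = outdir / SUBGROUP_TABLE

    model = _stage("costmodel")(fit_cost_model, cohort)
    table3 = model.as_frame().reset_index(names="variable")
    table3.to_csv(outdir / COSTMODEL_TABLE, index=False)
    outputs[COSTMODEL_TABLE] = outdir / COSTMODEL_TABLE
    log.info("costmodel: %d rows fitted, %d dropped", model.nobs, model.n_dropped)

    render_report(outdir)
    outputs[REPORT] = outdir / REPORT
    return outputs


def render_report(outdir) -> str:
    """Write a markdown summary of an analysis output directory."""
    outdir = Path(outdir)
    needed = [YEARLY_TABLE, SUBGROUP_TABLE, COSTMODEL_TABLE, PRIMARY_TREND]
    for name in needed:
        if not (outdir / name).exists():
            raise FileNotFoundError(f"missing analysis output {outdir / name}")
    table1 = pd.read_csv(outdir / YEARLY_TABLE)
    table2 = pd.read_csv(outdir / SUBGROUP_TABLE)
    table3 = pd.read_csv(outdir / COSTMODEL_TABLE)
    primary = pd.read_csv(outdir / PRIMARY_TREND).iloc[0]

    yearly = table1[table1["year"] != "total"]
    n_included = int(yearly["n_admissions"].sum())
    lines = ["# Sepsis cost-effectiveness report", ""]
    if n_included == 0:
        lines.append("Zero included admissions — nothing to analyze.")
    else:
        lines += [
            f"Included admissions: {n_included} across "
            f"{len(yearly)} years.",
            "",
            "## Effective cost per survivor",
            "",
            f"Trend: {primary['slope_per_year']:.1f} USD/year "
            f"[95% CI {primary['ci_low']:.1f} to {primary['ci_high']:.1f}], "
            f"p = {primary['p_value']:.4g}.",
            "",
            "Yearly values (USD/survivor): "
            + ", ".join(
                f"{int(float(y))}: {v:.0f}"
                for y, v in zip(
                    yearly["year"], yearly["effective_cost_per_survivor"]
                )
            ),
            "",
            "## Subgroup ECS trends",
            "",
            table2.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "",
            "## Multivariable log-cost model",
            "",
            table3.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
    text = "\n".join(lines) + "\n"
    (outdir / REPORT).write_text(text)
    return text
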