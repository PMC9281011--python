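"""Reading, validating and writing the claims tables and the series config.

File dialect: comma-separated UTF-8 with one header row.  Set-valued cells
(``infection_site_codes``) use ``;`` as the inner separator; an empty cell
is an empty set.  Booleans are written as ``1``/``0``.

In memory both tables are :class:`pandas.DataFrame` objects;
``infection_site_codes`` holds ``frozenset`` values.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .records import (
    DISCHARGE_STATUSES,
    EVENT_TYPES,
    MAX_CHRONIC_DISEASES,
    SEXES,
    SITE_CODES,
    UNKNOWN_CODE,
    AdmissionRecord,
    EventRecord,
    SeriesConfig,
    ValidationReport,
    Violation,
)

ADMISSION_COLUMNS = [
    "admission_id",
    "patient_id",
    "admission_year",
    "age",
    "sex",
    "length_of_stay",
    "discharge_status",
    "icu_admission",
    "surgery",
    "chronic_disease_count",
    "infection_site_codes",
    "total_cost",
]

EVENT_COLUMNS = ["admission_id", "day_index", "event_type", "agent"]

_ALLOWED_SITE_TOKENS = set(SITE_CODES) | {UNKNOWN_CODE}


class SchemaError(ValueError):
    """The file header does not match the documented column schema."""


class RowError(ValueError):
    """One or more rows failed to parse; the message lists line numbers."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _fail_rows(path, errors: list[str]) -> None:
    if errors:
        shown = "\n".join(errors[:20])
        more = "" if len(errors) <= 20 else f"\n... and {len(errors) - 20} more"
        raise RowError(f"{path}: {len(errors)} bad row(s):\n{shown}{more}")


def parse_site_cell(cell) -> frozenset[str]:
    """Parse a ``;``-separated site cell into a frozenset; empty -> empty set."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return frozenset()
    tokens = [t.strip() for t in str(cell).split(";") if t.strip()]
    bad = [t for t in tokens if t not in _ALLOWED_SITE_TOKENS]
    if bad:
        raise ValueError(
            f"unrecognized site code(s) {bad}; allowed: "
            f"{sorted(_ALLOWED_SITE_TOKENS)}"
        )
    return frozenset(tokens)


def format_site_cell(codes) -> str:
    return ";".join(sorted(codes))


def read_admissions(path) -> pd.DataFrame:
    """Read and validate an admissions table.

    Returns a DataFrame with one row per hospitalization; site codes are
    parsed into frozensets.  Raises :class:`SchemaError` for a bad header,
    :class:`RowError` (listing line numbers) for bad values, and
    ``ValueError`` for duplicated ``admission_id``.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, ADMISSION_COLUMNS, path)

    errors: list[str] = []
    out = {}
    # line numbers are 1-based including the header row
    lines = raw.index + 2

    def to_int(col, minimum=None, maximum=None):
        s = pd.to_numeric(raw[col], errors="coerce")
        bad = s.isna() | (s != s.round())
        if minimum is not None:
            bad |= s < minimum
        if maximum is not None:
            bad |= s > maximum
        for ln, val in zip(lines[bad], raw.loc[bad, col]):
            errors.append(f"line {ln}: bad {col} value {val!r}")
        return s.fillna(0).astype(int)

    out["admission_id"] = raw["admission_id"]
    out["patient_id"] = raw["patient_id"]
    out["admission_year"] = to_int("admission_year")
    out["age"] = to_int("age", minimum=0)
    out["length_of_stay"] = to_int("length_of_stay", minimum=1)
    out["chronic_disease_count"] = to_int(
        "chronic_disease_count", minimum=0, maximum=MAX_CHRONIC_DISEASES
    )

    for col, vocab in (("sex", SEXES), ("discharge_status", DISCHARGE_STATUSES)):
        bad = ~raw[col].isin(vocab)
        for ln, val in zip(lines[bad], raw.loc[bad, col]):
            errors.append(f"line {ln}: {col} {val!r} not in {list(vocab)}")
        out[col] = raw[col]

    for col in ("icu_admission", "surgery"):
        bad = ~raw[col].isin(["0", "1", "true", "false", "True", "False"])
        for ln, val in zip(lines[bad], raw.loc[bad, col]):
            errors.append(f"line {ln}: {col} {val!r} is not a boolean (use 0/1)")
        out[col] = raw[col].isin(["1", "true", "True"])

    cost = pd.to_numeric(raw["total_cost"], errors="coerce")
    bad = cost.isna() | (cost < 0)
    for ln, val in zip(lines[bad], raw.loc[bad, "total_cost"]):
        errors.append(f"line {ln}: total_cost {val!r} must be a number >= 0")
    out["total_cost"] = cost.fillna(0.0)

    sites = []
    for ln, cell in zip(lines, raw["infection_site_codes"]):
        try:
            sites.append(parse_site_cell(cell))
        except ValueError as exc:
            errors.append(f"line {ln}: {exc}")
            sites.append(frozenset())
    out["infection_site_codes"] = sites

    _fail_rows(path, errors)

    dup = raw["admission_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicate admission_id value(s): "
            f"{sorted(raw.loc[dup, 'admission_id'].unique()[:10])}"
        )
    return pd.DataFrame(out, columns=ADMISSION_COLUMNS)


def read_events(path) -> pd.DataFrame:
    """Read and validate a daily events table.

    ``agent`` must be present exactly for ``iv_antibiotic`` rows; missing
    cells become ``None``.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, EVENT_COLUMNS, path)

    errors: list[str] = []
    lines = raw.index + 2

    day = pd.to_numeric(raw["day_index"], errors="coerce")
    bad = day.isna() | (day != day.round()) | (day < 1)
    for ln, val in zip(lines[bad], raw.loc[bad, "day_index"]):
        errors.append(f"line {ln}: bad day_index value {val!r} (integer >= 1)")

    bad = ~raw["event_type"].isin(EVENT_TYPES)
    for ln, val in zip(lines[bad], raw.loc[bad, "event_type"]):
        errors.append(f"line {ln}: unknown event_type {val!r}")

    is_abx = raw["event_type"] == "iv_antibiotic"
    bad = is_abx & (raw["agent"] == "")
    for ln in lines[bad]:
        errors.append(f"line {ln}: iv_antibiotic requires an agent label")
    bad = ~is_abx & (raw["agent"] != "")
    for ln, val in zip(lines[bad], raw.loc[bad, "agent"]):
        errors.append(f"line {ln}: agent {val!r} only allowed on iv_antibiotic")

    _fail_rows(path, errors)

    return pd.DataFrame(
        {
            "admission_id": raw["admission_id"],
            "day_index": day.astype(int),
            "event_type": raw["event_type"],
            "agent": raw["agent"].where(raw["agent"] != "", None),
        },
        columns=EVENT_COLUMNS,
    )


def write_admissions(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["infection_site_codes"] = out["infection_site_codes"].map(format_site_cell)
    out["icu_admission"] = out["icu_admission"].astype(int)
    out["surgery"] = out["surgery"].astype(int)
    out.to_csv(path, index=False, columns=ADMISSION_COLUMNS)


def write_events(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["agent"] = out["agent"].fillna("")
    out.to_csv(path, index=False, columns=EVENT_COLUMNS)


def admissions_to_records(df: pd.DataFrame) -> list[AdmissionRecord]:
    return [AdmissionRecord(**row) for row in df.to_dict("records")]


def events_to_records(df: pd.DataFrame) -> list[EventRecord]:
    return [EventRecord(**row) for row in df.to_dict("records")]


def validate(admissions: pd.DataFrame, events: pd.DataFrame) -> ValidationReport:
    """Cross-table validation; returns every violation, not just the first."""
    report = ValidationReport(n_admissions=len(admissions), n_events=len(events))
    v = report.violations

    dup = admissions["admission_id"].duplicated(keep=False)
    for aid in admissions.loc[dup, "admission_id"].unique():
        v.append(Violation("unique_admission_id", aid, "duplicated admission_id"))
    for aid in admissions.loc[admissions["length_of_stay"] < 1, "admission_id"]:
        v.append(Violation("length_of_stay", aid, "length_of_stay must be >= 1"))
    for aid in admissions.loc[admissions["age"] < 0, "admission_id"]:
        v.append(Violation("age", aid, "age must be >= 0"))
    for aid in admissions.loc[admissions["total_cost"] < 0, "admission_id"]:
        v.append(Violation("total_cost", aid, "total_cost must be >= 0"))

    known = set(admissions["admission_id"])
    orphan = ~events["admission_id"].isin(known)
    for aid in events.loc[orphan, "admission_id"].unique():
        v.append(Violation("event_reference", aid, "event references unknown admission"))

    los = admissions.set_index("admission_id")["length_of_stay"]
    linked = events.loc[~orphan]
    over = linked["day_index"].to_numpy() > los.reindex(
        linked["admission_id"]
    ).to_numpy()
    for aid, day in zip(
        linked.loc[over, "admission_id"], linked.loc[over, "day_index"]
    ):
        v.append(
            Violation(
                "day_within_stay",
                aid,
                f"day_index {day} exceeds length_of_stay {los[aid]}",
            )
        )

    is_abx = events["event_type"] == "iv_antibiotic"
    has_agent = events["agent"].notna() & (events["agent"] != "")
    for aid in events.loc[is_abx & ~has_agent, "admission_id"]:
        v.append(Violation("agent_required", aid, "iv_antibiotic without agent"))
    for aid in events.loc[~is_abx & has_agent, "admission_id"]:
        v.append(Violation("agent_forbidden", aid, "agent on non-antibiotic event"))
    return report


def read_series_config(path) -> SeriesConfig:
    """Load a :class:`SeriesConfig` from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return series_config_from_dict(data)


def series_config_from_dict(data: dict) -> SeriesConfig:
    try:
        return SeriesConfig(
            cpi_by_year={int(k): float(v) for k, v in data["cpi_by_year"].items()},
            registrants_by_year={
                int(k): float(v) for k, v in data["registrants_by_year"].items()
            },
            reference_year=int(data["reference_year"]),
            jpy_per_usd=float(data["jpy_per_usd"]),
        )
    except KeyError as exc:
        raise ValueError(f"series config missing key {exc}") from exc
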