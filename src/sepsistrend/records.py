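"""Domain types for administrative-claims sepsis analysis.

Two tables describe a claims extract:

* an **admissions** table — one row per hospitalization, carrying
  demographics, the stay, discharge status, care flags and the total
  (nominal JPY) cost of the hospitalization; and
* a daily **events** table — one row per dated clinical event within an
  admission (intravenous antibiotic administrations, blood cultures, and
  the organ-support / organ-dysfunction markers used by the claims-level
  sepsis surrogate).

All temporal logic is day-granular: ``day_index`` is 1-based, day 1 being
the admission day, and length of stay follows the inclusive convention
``discharge day - admission day + 1`` (a same-day stay has LOS 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

# -- closed vocabularies ----------------------------------------------------

SEXES = ("male", "female")

DISCHARGE_STATUSES = ("home", "nursing_facility", "transfer", "death")

#: The seven single infection-site labels recorded in the claims extract.
SITE_CODES = (
    "respiratory",
    "urogenital",
    "abdominal",
    "bone_soft_tissue",
    "meninges_brain_spinal",
    "heart",
    "blood",
)

#: An explicitly recorded "site unknown" code (distinct from a missing cell).
UNKNOWN_CODE = "unknown"

#: Cohort-level site labels after collapsing multi-site admissions.
SITE_LABELS = SITE_CODES + ("multiple", "unknown_explicit", "missing")

EVENT_TYPES = (
    "iv_antibiotic",
    "blood_culture",
    "vasopressor",
    "mechanical_ventilation",
    "oxygen_supplementation",
    "diuretic",
    "renal_dysfunction_code",
    "renal_replacement_therapy",
    "liver_dysfunction_code",
    "thrombocytopenia_code",
    "metabolic_acidosis_code",
)

MAX_CHRONIC_DISEASES = 8


@dataclass(frozen=True)
class AdmissionRecord:
    """One hospitalization.

    ``infection_site_codes`` is the set of recorded site codes (possibly
    empty — a genuinely missing site); ``total_cost`` is the nominal-JPY
    cost of the whole hospitalization.
    """

    admission_id: str
    patient_id: str
    admission_year: int
    age: int
    sex: str
    length_of_stay: int
    discharge_status: str
    icu_admission: bool
    surgery: bool
    chronic_disease_count: int
    infection_site_codes: frozenset[str]
    total_cost: float

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if self.length_of_stay < 1:
            raise ValueError(
                f"length_of_stay must be >= 1, got {self.length_of_stay}"
            )
        if self.total_cost < 0:
            raise ValueError(f"total_cost must be >= 0, got {self.total_cost}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.discharge_status not in DISCHARGE_STATUSES:
            raise ValueError(
                f"discharge_status must be one of {DISCHARGE_STATUSES}, "
                f"got {self.discharge_status!r}"
            )
        if not 0 <= self.chronic_disease_count <= MAX_CHRONIC_DISEASES:
            raise ValueError(
                "chronic_disease_count must be within "
                f"0..{MAX_CHRONIC_DISEASES}, got {self.chronic_disease_count}"
            )
        allowed = set(SITE_CODES) | {UNKNOWN_CODE}
        bad = set(self.infection_site_codes) - allowed
        if bad:
            raise ValueError(f"unrecognized infection site codes: {sorted(bad)}")

    @property
    def died(self) -> bool:
        return self.discharge_status == "death"


@dataclass(frozen=True)
class EventRecord:
    """One dated clinical event within an admission.

    ``agent`` names the antibiotic and is required exactly for
    ``iv_antibiotic`` events.
    """

    admission_id: str
    day_index: int
    event_type: str
    agent: str | None = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(
                f"event_type must be one of {EVENT_TYPES}, got {self.event_type!r}"
            )
        if self.day_index < 1:
            raise ValueError(f"day_index must be >= 1, got {self.day_index}")
        if self.event_type == "iv_antibiotic":
            if not self.agent:
                raise ValueError("iv_antibiotic events require an agent label")
        elif self.agent:
            raise ValueError(
                f"agent is only allowed on iv_antibiotic events, got "
                f"{self.agent!r} on {self.event_type!r}"
            )


@dataclass(frozen=True)
class SeriesConfig:
    """Deflation / adjustment series for cost analysis.

    * ``cpi_by_year``       — consumer price index per calendar year;
    * ``registrants_by_year`` — patients registered in the claims system
      per year (corrects gross costs for growing database coverage);
    * ``reference_year``    — the year whose CPI and registrant count
      anchor both adjustments;
    * ``jpy_per_usd``       — JPY per USD exchange rate.
    """

    cpi_by_year: dict[int, float]
    registrants_by_year: dict[int, float]
    reference_year: int
    jpy_per_usd: float

    def __post_init__(self) -> None:
        if self.jpy_per_usd <= 0:
            raise ValueError(f"jpy_per_usd must be > 0, got {self.jpy_per_usd}")
        for name, series in (
            ("cpi_by_year", self.cpi_by_year),
            ("registrants_by_year", self.registrants_by_year),
        ):
            if any(v <= 0 for v in series.values()):
                raise ValueError(f"all {name} values must be > 0")
            if self.reference_year not in series:
                raise ValueError(
                    f"reference_year {self.reference_year} missing from {name}"
                )


@dataclass(frozen=True)
class Violation:
    rule: str
    offending_id: str
    message: str


@dataclass
class ValidationReport:
    """Outcome of cross-table validation; violations are data, not errors."""

    n_admissions: int
    n_events: int
    violations: list[Violation] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        head = (
            f"ValidationReport: {self.n_admissions} admissions, "
            f"{self.n_events} events, "
            f"{'PASS' if self.passed else f'{len(self.violations)} violation(s)'}"
        )
        lines = [head]
        lines += [f"  [{v.rule}] {v.offending_id}: {v.message}" for v in self.violations]
        return "\n".join(lines)
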