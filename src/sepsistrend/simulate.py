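"""Synthetic administrative-claims generator with known sepsis ground truth.

Emulates the statistical structure of the nationwide Japanese DPC sepsis
cohort at desk scale: yearly admission counts that grow over 2010-2017,
in-hospital mortality that declines year over year, log-normal lengths of
stay with declining medians, and per-hospitalization costs drawn from a
multiplicative log-normal model whose driver effects equal the published
cohort's log-cost regression coefficients (so parameter-recovery tests
have exact ground truth).

For every admission flagged as a true sepsis case the generator emits a
timeline that satisfies the claims sepsis rule exactly — a blood culture
within +/- 2 days of a newly initiated IV antibiotic covered for >= 4
consecutive days, plus at least one organ-dysfunction event.  Timelines of
non-sepsis admissions violate at least one clause by construction (short
antibiotic run, culture outside the window, missing culture, or no organ
dysfunction), so the rule-based classifier reproduces the ground-truth
labels exactly.

Costs and lengths of stay have no published distributional form; the
log-normal choices here are assumptions of the generator, not claims
about the DPC data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import calibration as cal
from .identify import DYSFUNCTION_GROUPS, detect_infection_episode
from .io import ADMISSION_COLUMNS, EVENT_COLUMNS
from .records import SITE_CODES, SeriesConfig

#: dysfunction event types the generator draws from (one per flag group,
#: plus alternates), with realistic relative frequencies
_DYSFUNCTION_EVENT_POOL = (
    ("oxygen_supplementation", 0.30),
    ("mechanical_ventilation", 0.12),
    ("vasopressor", 0.16),
    ("diuretic", 0.16),
    ("renal_replacement_therapy", 0.05),
    ("renal_dysfunction_code", 0.05),
    ("liver_dysfunction_code", 0.06),
    ("thrombocytopenia_code", 0.05),
    ("metabolic_acidosis_code", 0.05),
)

_AGENTS = ("CTRX", "MEPM", "TAZ/PIPC", "CFPM", "VCM", "LVFX")

NEGATIVE_MODES = ("shorten_run", "shift_culture", "no_culture", "drop_dysfunction")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic claims generator.

    ``patients_per_year`` stores (possibly fractional) admissions per year
    at the configured scale; generation rounds to integers.  Cost drivers
    are multiplicative effects on per-hospitalization cost:
    ``cost = exp(base_log_cost + sum of log multipliers + noise)`` in
    nominal JPY.  ``per_year`` applies per year elapsed since the first
    study year.
    """

    years: tuple[int, ...]
    patients_per_year: dict[int, float]
    sepsis_fraction: float
    mortality_by_year: dict[int, float]
    los_lognormal_by_year: dict[int, tuple[float, float]]
    base_log_cost: float
    cost_multipliers: dict[str, float]
    log_cost_noise_sd: float
    age_distribution: dict[str, float]
    male_fraction: float
    site_mixture: dict[str, float]
    repeat_admission_fraction: float
    seed: int = 0
    nonsepsis_mortality: float = 0.05
    icu_fraction: float = 0.156
    surgery_fraction: float = 0.25
    chronic_mean_count: float = 2.0
    transfer_fraction: float = 0.239
    nursing_facility_fraction: float = 0.12
    underage_fraction: float = 0.005

    def __post_init__(self) -> None:
        probs = {
            "sepsis_fraction": self.sepsis_fraction,
            "male_fraction": self.male_fraction,
            "repeat_admission_fraction": self.repeat_admission_fraction,
            "nonsepsis_mortality": self.nonsepsis_mortality,
            "icu_fraction": self.icu_fraction,
            "surgery_fraction": self.surgery_fraction,
            "transfer_fraction": self.transfer_fraction,
            "nursing_facility_fraction": self.nursing_facility_fraction,
            "underage_fraction": self.underage_fraction,
            **{f"mortality_by_year[{y}]": p for y, p in self.mortality_by_year.items()},
            **{f"site_mixture[{s}]": p for s, p in self.site_mixture.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if abs(sum(self.site_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("site_mixture probabilities must sum to 1")
        if any(m <= 0 for m in self.cost_multipliers.values()):
            raise ValueError("all cost multipliers must be > 0")
        if any(v <= 0 for v in self.patients_per_year.values()):
            raise ValueError("patients_per_year counts must be > 0")
        if self.log_cost_noise_sd < 0:
            raise ValueError("log_cost_noise_sd must be >= 0")
        for y in self.years:
            for name, series in (
                ("patients_per_year", self.patients_per_year),
                ("mortality_by_year", self.mortality_by_year),
                ("los_lognormal_by_year", self.los_lognormal_by_year),
            ):
                if y not in series:
                    raise ValueError(f"{name} missing year {y}")


#: LOS log-scale sigma implied by the cohort's yearly mean/median ratio
#: (mean/median = exp(sigma^2 / 2) ~ 50.3/34 -> sigma ~ 0.88).
LOS_SIGMA = 0.88


def default_config(scale: float = 0.01, seed: int = 0) -> GeneratorConfig:
    """Generator defaults calibrated to the published cohort aggregates.

    ``scale`` rescales the yearly admission counts (default 1/100 keeps
    the full eight-year simulation at desk scale, ~12,800 admissions).
    """
    years = tuple(cal.STUDY_YEARS)
    site_mixture = {
        "respiratory": 0.330,
        "multiple": 0.280,
        "abdominal": 0.130,
        "urogenital": 0.100,
        "bone_soft_tissue": 0.045,
        "meninges_brain_spinal": 0.012,
        "heart": 0.012,
        "blood": 0.010,
        "unknown_explicit": 0.031,
        "missing": 0.050,
    }
    return GeneratorConfig(
        years=years,
        patients_per_year={y: cal.PATIENTS_BY_YEAR[y] * scale for y in years},
        sepsis_fraction=0.9,
        mortality_by_year={
            y: cal.MORTALITY_PCT_BY_YEAR[y] / 100.0 for y in years
        },
        los_lognormal_by_year={
            y: (math.log(cal.MEDIAN_LOS_BY_YEAR[y]), LOS_SIGMA) for y in years
        },
        base_log_cost=14.0,
        cost_multipliers=dict(cal.COST_MULTIPLIERS),
        log_cost_noise_sd=0.4,
        age_distribution={"mean": 77.0, "sd": 13.0, "min": 18, "max": 104},
        male_fraction=0.589,
        site_mixture=site_mixture,
        repeat_admission_fraction=0.05,
        seed=seed,
    )


def default_series_config() -> SeriesConfig:
    """Series config matching the generator defaults (CPI, registrants, FX)."""
    return SeriesConfig(
        cpi_by_year=dict(cal.CPI_BY_YEAR),
        registrants_by_year=dict(cal.SYNTHETIC_REGISTRANTS_BY_YEAR),
        reference_year=2017,
        jpy_per_usd=cal.JPY_PER_USD,
    )


def _site_codes_for_label(label: str, rng: np.random.Generator) -> frozenset[str]:
    if label == "missing":
        return frozenset()
    if label == "unknown_explicit":
        return frozenset({"unknown"})
    if label == "multiple":
        k = int(rng.integers(2, 4))
        return frozenset(rng.choice(SITE_CODES, size=k, replace=False))
    return frozenset({label})


def _log_cost(cfg: GeneratorConfig, row: dict, site_label: str) -> float:
    m = cfg.cost_multipliers
    lp = cfg.base_log_cost
    lp += row["age"] * math.log(m["age_per_year"])
    lp += (row["sex"] == "male") * math.log(m["male"])
    lp += row["chronic_disease_count"] * math.log(m["per_chronic_disease"])
    lp += row["icu_admission"] * math.log(m["icu"])
    lp += row["surgery"] * math.log(m["surgery"])
    lp += row["length_of_stay"] * math.log(m["per_los_day"])
    lp += (row["admission_year"] - min(cfg.years)) * math.log(m["per_year"])
    lp += math.log(m.get(f"site:{site_label}", 1.0))
    return lp


def _positive_timeline(
    aid: str, los: int, rng: np.random.Generator, events: list
) -> tuple[int, list[str]]:
    """Emit a rule-exact sepsis timeline; returns (initiation day, flags)."""
    d = int(rng.integers(1, min(max(los - 3, 1), 8) + 1))
    run = max(min(3 + int(rng.geometric(0.35)), los - d + 1), 4)
    c = int(np.clip(d + rng.integers(-2, 3), 1, los))
    agent = str(rng.choice(_AGENTS))
    events.append((aid, c, "blood_culture", None))
    for day in range(d, d + run):
        events.append((aid, day, "iv_antibiotic", agent))
    if run >= 6 and rng.random() < 0.3:  # escalation: second agent mid-run
        agent2 = str(rng.choice([a for a in _AGENTS if a != agent]))
        for day in range(d + 2, d + run):
            events.append((aid, day, "iv_antibiotic", agent2))
    types, weights = zip(*_DYSFUNCTION_EVENT_POOL)
    w = np.asarray(weights) / sum(weights)
    k = int(rng.integers(1, 4))
    chosen = rng.choice(types, size=k, replace=False, p=w)
    for t in chosen:
        events.append((aid, int(np.clip(d + rng.integers(0, 4), 1, los)), t, None))
    flags = sorted(
        {g for g, members in DYSFUNCTION_GROUPS.items() if set(chosen) & set(members)}
    )
    return d, flags


def _negative_timeline(
    aid: str, los: int, rng: np.random.Generator, events: list
) -> None:
    """Emit a timeline that fails at least one clause of the sepsis rule."""
    mode = str(rng.choice(NEGATIVE_MODES))
    agent = str(rng.choice(_AGENTS))
    add_dysfunction = True
    if mode == "drop_dysfunction" and los >= 4:
        d = int(rng.integers(1, min(max(los - 3, 1), 8) + 1))
        c = int(np.clip(d + rng.integers(-2, 3), 1, los))
        events.append((aid, c, "blood_culture", None))
        for day in range(d, d + 4):
            events.append((aid, day, "iv_antibiotic", agent))
        add_dysfunction = False
    elif mode == "shift_culture" and los >= 7:
        d = int(rng.integers(1, los - 6 + 1))
        events.append((aid, d + 3 + int(rng.integers(0, min(3, los - d - 3))),
                       "blood_culture", None))
        for day in range(d, d + 4):
            events.append((aid, day, "iv_antibiotic", agent))
    elif mode == "no_culture":
        d = int(rng.integers(1, min(max(los - 3, 1), 8) + 1))
        for day in range(d, min(d + 4, los + 1)):
            events.append((aid, day, "iv_antibiotic", agent))
    else:  # shorten_run (also the fallback when the stay is too short)
        d = int(rng.integers(1, min(max(los - 2, 1), 8) + 1))
        run = min(3, los - d + 1)
        c = int(np.clip(d + rng.integers(-2, 3), 1, los))
        events.append((aid, c, "blood_culture", None))
        for day in range(d, d + run):
            events.append((aid, day, "iv_antibiotic", agent))
    if add_dysfunction and rng.random() < 0.5:
        types, weights = zip(*_DYSFUNCTION_EVENT_POOL)
        w = np.asarray(weights) / sum(weights)
        t = str(rng.choice(types, p=w))
        events.append((aid, int(rng.integers(1, los + 1)), t, None))


def generate(
    config: GeneratorConfig,
    seed: int | None = None,
    *,
    with_events: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate ``(admissions, events, ground_truth)`` tables.

    Deterministic for a fixed seed (``seed`` overrides ``config.seed``).
    With ``with_events=False`` the events table is empty — useful for
    large Monte-Carlo studies of cost aggregates where only the
    admissions table and the ground-truth labels are needed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    adm_rows: list[dict] = []
    events: list[tuple] = []
    truth_rows: list[dict] = []

    counter = 0
    patients: list[tuple[str, str, int, int]] = []  # (patient_id, sex, age, year)

    for year in config.years:
        n = int(round(config.patients_per_year[year]))
        mu, sigma = config.los_lognormal_by_year[year]
        mortality = config.mortality_by_year[year]
        for _ in range(n):
            counter += 1
            aid = f"A{counter:07d}"
            is_repeat = patients and rng.random() < config.repeat_admission_fraction
            if is_repeat:
                pid, sex, age0, year0 = patients[int(rng.integers(len(patients)))]
                age = age0 + (year - year0)
            else:
                pid = f"P{counter:07d}"
                if rng.random() < config.underage_fraction:
                    age = int(rng.integers(1, 20))
                else:
                    a = config.age_distribution
                    age = int(
                        np.clip(
                            round(rng.normal(a["mean"], a["sd"])), a["min"], a["max"]
                        )
                    )
                sex = "male" if rng.random() < config.male_fraction else "female"
                patients.append((pid, sex, age, year))

            is_sepsis = rng.random() < config.sepsis_fraction
            los = max(1, int(round(rng.lognormal(mu, sigma))))
            if is_sepsis:
                los = max(los, 4)
            died = rng.random() < (
                mortality if is_sepsis else config.nonsepsis_mortality
            )
            if died:
                status = "death"
            elif rng.random() < config.transfer_fraction:
                status = "transfer"
            elif rng.random() < config.nursing_facility_fraction:
                status = "nursing_facility"
            else:
                status = "home"

            site_label = str(
                rng.choice(
                    list(config.site_mixture), p=list(config.site_mixture.values())
                )
            )
            row = {
                "admission_id": aid,
                "patient_id": pid,
                "admission_year": year,
                "age": age,
                "sex": sex,
                "length_of_stay": los,
                "discharge_status": status,
                "icu_admission": bool(rng.random() < config.icu_fraction),
                "surgery": bool(rng.random() < config.surgery_fraction),
                "chronic_disease_count": int(
                    rng.binomial(8, config.chronic_mean_count / 8.0)
                ),
                "infection_site_codes": _site_codes_for_label(site_label, rng),
            }
            row["total_cost"] = float(
                np.exp(_log_cost(config, row, site_label)
                       + rng.normal(0.0, config.log_cost_noise_sd))
            )
            adm_rows.append(row)

            start_day, flags = -1, []
            if with_events:
                if is_sepsis:
                    start_day, flags = _positive_timeline(aid, los, rng, events)
                else:
                    _negative_timeline(aid, los, rng, events)
            truth_rows.append(
                {
                    "admission_id": aid,
                    "is_sepsis": is_sepsis,
                    "episode_start_day": start_day if is_sepsis else -1,
                    "dysfunction_flags": ";".join(flags),
                }
            )

    admissions = pd.DataFrame(adm_rows, columns=ADMISSION_COLUMNS)
    events_df = pd.DataFrame(events, columns=EVENT_COLUMNS)
    if len(events_df):
        events_df = events_df.sort_values(
            ["admission_id", "day_index"], kind="stable"
        ).reset_index(drop=True)
        events_df = events_df.drop_duplicates().reset_index(drop=True)
    ground_truth = pd.DataFrame(
        truth_rows,
        columns=["admission_id", "is_sepsis", "episode_start_day", "dysfunction_flags"],
    )
    return admissions, events_df, ground_truth


def perturb_to_negative(
    events: pd.DataFrame, mode: str, *, length_of_stay: int | None = None
) -> pd.DataFrame:
    """Minimally edit a sepsis-positive timeline to fail one targeted clause.

    Modes: ``shorten_run`` truncates antibiotic coverage below 4 days;
    ``shift_culture`` moves all blood cultures outside the +/- 2-day window
    of every possible initiation day; ``drop_dysfunction`` removes every
    organ-dysfunction event.  Raises ``ValueError`` when the mode is
    inapplicable or the edit fails to flip the classification.
    """
    if mode not in ("shorten_run", "shift_culture", "drop_dysfunction"):
        raise ValueError(f"unknown perturbation mode {mode!r}")
    ev = events.sort_values("day_index", kind="stable").reset_index(drop=True)
    episode = detect_infection_episode(ev)

    if mode == "drop_dysfunction":
        dys_types = {t for members in DYSFUNCTION_GROUPS.values() for t in members}
        keep = ~ev["event_type"].isin(dys_types)
        if keep.all():
            raise ValueError("drop_dysfunction: no dysfunction events to remove")
        return ev[keep].reset_index(drop=True)

    if episode is None:
        raise ValueError(f"{mode}: timeline has no infection episode to break")

    if mode == "shorten_run":
        d = episode.initiation_day
        keep = ~(
            (ev["event_type"] == "iv_antibiotic") & (ev["day_index"] >= d + 3)
        )
        out = ev[keep].reset_index(drop=True)
        if detect_infection_episode(out) is not None:
            raise ValueError("shorten_run: residual timeline still qualifies")
        return out

    # shift_culture: move cultures beyond +/-2 days of every candidate
    abx = ev[ev["event_type"] == "iv_antibiotic"]
    days_by_agent: dict[str, set[int]] = {}
    for day, agent in zip(abx["day_index"], abx["agent"]):
        days_by_agent.setdefault(agent, set()).add(int(day))
    candidates = sorted(
        d
        for days in days_by_agent.values()
        for d in days
        if not any((d - k) in days for k in (1, 2))
    )
    target = max(candidates) + 3
    if length_of_stay is not None and target > length_of_stay:
        target = min(candidates) - 3
        if target < 1:
            raise ValueError("shift_culture: no in-stay day outside every window")
    out = ev.copy()
    out.loc[out["event_type"] == "blood_culture", "day_index"] = target
    out = out.sort_values("day_index", kind="stable").reset_index(drop=True)
    if detect_infection_episode(out) is not None:
        raise ValueError("shift_culture: residual timeline still qualifies")
    return out


def null_config(scale: float = 0.01, seed: int = 0) -> GeneratorConfig:
    """A no-trend variant: flat mortality, LOS and cost across years.

    Used for type-I-error studies of the yearly trend tests.
    """
    cfg = default_config(scale=scale, seed=seed)
    years = cfg.years
    flat_m = float(np.mean(list(cfg.mortality_by_year.values())))
    mu = float(np.mean([cfg.los_lognormal_by_year[y][0] for y in years]))
    multipliers = dict(cfg.cost_multipliers)
    multipliers["per_year"] = 1.0
    n = float(np.mean(list(cfg.patients_per_year.values())))
    return replace(
        cfg,
        patients_per_year={y: n for y in years},
        mortality_by_year={y: flat_m for y in years},
        los_lognormal_by_year={y: (mu, LOS_SIGMA) for y in years},
        cost_multipliers=multipliers,
    )


def verify_labels(
    admissions: pd.DataFrame,
    events: pd.DataFrame,
    ground_truth: pd.DataFrame,
) -> float:
    """Fraction of admissions whose classifier label matches ground truth."""
    from .identify import build_cohort

    cohort = build_cohort(admissions, events)
    merged = cohort.frame[["admission_id", "is_sepsis"]].merge(
        ground_truth[["admission_id", "is_sepsis"]],
        on="admission_id",
        suffixes=("_pred", "_true"),
    )
    return float((merged["is_sepsis_pred"] == merged["is_sepsis_true"]).mean())
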