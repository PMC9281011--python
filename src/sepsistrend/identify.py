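"""Claims-level sepsis case identification.

A hospitalization counts as sepsis when it shows **presumed serious
infection** — a newly initiated intravenous antibiotic within +/- 2
calendar days of a blood culture, with IV antibiotic coverage on at least
4 consecutive days — **and** at least one organ-dysfunction marker during
the stay (vasopressor, respiratory support, kidney injury, liver injury,
thrombocytopenia, or metabolic acidosis).

Day indices are 1-based within the stay.  "Newly initiated" means the
agent was not administered on any of the ``lookback_days`` days before the
initiation day; the 4-day run may switch agents, only day-level IV
coverage matters.  The +/- window is symmetric, so no ordering between
culture and antibiotic initiation is enforced; the initiation day anchors
the episode.

Site-of-infection assignment collapses multi-code admissions to
``multiple``; an admission with no recorded code is ``missing`` and is
excluded from the analysis cohort (the only source of missingness in the
extract).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import SITE_CODES, UNKNOWN_CODE

CULTURE_WINDOW_DAYS = 2
MIN_RUN_DAYS = 4
DEFAULT_LOOKBACK_DAYS = 2
DEFAULT_AGE_THRESHOLD = 20

#: event types feeding each organ-dysfunction flag
DYSFUNCTION_GROUPS: dict[str, tuple[str, ...]] = {
    "vasopressor": ("vasopressor",),
    "respiratory_support": ("mechanical_ventilation", "oxygen_supplementation"),
    "kidney_injury": (
        "diuretic",
        "renal_dysfunction_code",
        "renal_replacement_therapy",
    ),
    "liver_injury": ("liver_dysfunction_code",),
    "thrombocytopenia": ("thrombocytopenia_code",),
    "metabolic_acidosis": ("metabolic_acidosis_code",),
}

EXCLUSION_REASONS = (
    "below_age_threshold",
    "no_presumed_infection",
    "no_organ_dysfunction",
    "missing_site",
)


@dataclass(frozen=True)
class InfectionEpisode:
    """A qualifying presumed-serious-infection episode."""

    initiation_day: int
    culture_day: int
    run_length: int


@dataclass(frozen=True)
class OrganDysfunctionFlags:
    vasopressor: bool = False
    respiratory_support: bool = False
    kidney_injury: bool = False
    liver_injury: bool = False
    thrombocytopenia: bool = False
    metabolic_acidosis: bool = False

    @property
    def any_dysfunction(self) -> bool:
        return (
            self.vasopressor
            or self.respiratory_support
            or self.kidney_injury
            or self.liver_injury
            or self.thrombocytopenia
            or self.metabolic_acidosis
        )


def _check_single_sorted(events: pd.DataFrame) -> None:
    if events["admission_id"].nunique() > 1:
        raise ValueError(
            "events from multiple admissions passed to a single-admission "
            f"operation: {sorted(events['admission_id'].unique())}"
        )
    if not events["day_index"].is_monotonic_increasing:
        raise ValueError("events must be sorted by day_index")


def detect_infection_episode(
    events: pd.DataFrame,
    *,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
    length_of_stay: int | None = None,
    allow_censored_run: bool = False,
) -> InfectionEpisode | None:
    """Find the earliest qualifying infection episode of one admission.

    Parameters
    ----------
    events
        Events of a single admission, sorted by ``day_index``.
    lookback_days
        An antibiotic agent counts as newly initiated on day ``d`` iff it
        was not given on any of ``d - lookback_days .. d - 1``.
    length_of_stay, allow_censored_run
        With ``allow_censored_run=True``, a run truncated by the end of a
        stay shorter than ``initiation + 3`` days still qualifies provided
        coverage reaches the last day of the stay.  Off by default: the
        4-day requirement is enforced strictly.

    Returns ``None`` when no day satisfies all three clauses.
    """
    if len(events) == 0:
        return None
    _check_single_sorted(events)

    abx = events[events["event_type"] == "iv_antibiotic"]
    cultures = np.unique(
        events.loc[events["event_type"] == "blood_culture", "day_index"].to_numpy()
    )
    if len(abx) == 0 or len(cultures) == 0:
        return None

    days_by_agent: dict[str, set[int]] = defaultdict(set)
    covered: set[int] = set()
    for day, agent in zip(abx["day_index"].to_numpy(), abx["agent"]):
        days_by_agent[agent].add(int(day))
        covered.add(int(day))

    return _detect_from_sets(
        days_by_agent,
        covered,
        cultures,
        lookback_days=lookback_days,
        length_of_stay=length_of_stay,
        allow_censored_run=allow_censored_run,
    )


def _detect_from_sets(
    days_by_agent: dict[str, set[int]],
    covered: set[int],
    culture_days: np.ndarray,
    *,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
    length_of_stay: int | None = None,
    allow_censored_run: bool = False,
) -> InfectionEpisode | None:
    # candidate initiation days: some agent given on d, not in the lookback
    candidates: set[int] = set()
    for days in days_by_agent.values():
        for d in days:
            if not any((d - k) in days for k in range(1, lookback_days + 1)):
                candidates.add(d)

    for d in sorted(candidates):
        near = culture_days[np.abs(culture_days - d) <= CULTURE_WINDOW_DAYS]
        if len(near) == 0:
            continue
        run_end = d + MIN_RUN_DAYS - 1
        if (
            allow_censored_run
            and length_of_stay is not None
            and length_of_stay < run_end
        ):
            run_end = length_of_stay
        if not all(day in covered for day in range(d, run_end + 1)):
            continue
        # realized run length: consecutive covered days from initiation
        run = 0
        while (d + run) in covered:
            run += 1
        # report the culture closest to initiation, earliest on ties
        order = np.lexsort((near, np.abs(near - d)))
        return InfectionEpisode(
            initiation_day=int(d), culture_day=int(near[order[0]]), run_length=run
        )
    return None


def organ_dysfunction_flags(events: pd.DataFrame) -> OrganDysfunctionFlags:
    """Flag each organ-dysfunction group present anywhere in the stay."""
    if len(events) == 0:
        return OrganDysfunctionFlags()
    _check_single_sorted(events)
    present = set(events["event_type"])
    return OrganDysfunctionFlags(
        **{
            flag: any(t in present for t in types)
            for flag, types in DYSFUNCTION_GROUPS.items()
        }
    )


def assign_site(codes) -> str:
    """Collapse a set of recorded site codes to a cohort site label.

    No codes -> ``missing``; exactly the explicit unknown code ->
    ``unknown_explicit``; one site code -> that site; two or more distinct
    codes -> ``multiple``.
    """
    codes = frozenset(codes)
    bad = codes - set(SITE_CODES) - {UNKNOWN_CODE}
    if bad:
        raise ValueError(f"unrecognized site code(s): {sorted(bad)}")
    if not codes:
        return "missing"
    if len(codes) == 1:
        (only,) = codes
        return "unknown_explicit" if only == UNKNOWN_CODE else only
    return "multiple"


def classify_admission(
    admission,
    events: pd.DataFrame,
    *,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
    allow_censored_run: bool = False,
) -> dict:
    """Classify one admission; episode, flags and site are attached for audit."""
    episode = detect_infection_episode(
        events,
        lookback_days=lookback_days,
        length_of_stay=int(admission["length_of_stay"]),
        allow_censored_run=allow_censored_run,
    )
    flags = organ_dysfunction_flags(events)
    site = assign_site(admission["infection_site_codes"])
    return {
        "is_sepsis": episode is not None and flags.any_dysfunction,
        "episode": episode,
        "flags": flags,
        "site": site,
    }


@dataclass
class SepsisCohort:
    """Screened admissions with classification audit columns.

    ``frame`` has one row per screened admission: all admission columns
    plus ``site_label``, episode fields, the six dysfunction flags,
    ``any_dysfunction``, raw intervention indicators
    (``has_mechanical_ventilation``, ``has_vasopressor``, ``has_rrt``),
    ``is_sepsis``, ``included`` and ``exclusion_reason``.
    ``exclusions`` tallies the four exclusion reasons; included plus the
    tally total always equals the number screened.
    """

    frame: pd.DataFrame
    exclusions: dict[str, int] = field(default_factory=dict)
    age_threshold: int = DEFAULT_AGE_THRESHOLD

    @property
    def n_screened(self) -> int:
        return len(self.frame)

    @property
    def n_included(self) -> int:
        return int(self.frame["included"].sum())

    @property
    def included(self) -> pd.DataFrame:
        return self.frame[self.frame["included"]]


def build_cohort(
    admissions: pd.DataFrame,
    events: pd.DataFrame,
    *,
    age_threshold: int = DEFAULT_AGE_THRESHOLD,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
    allow_censored_run: bool = False,
) -> SepsisCohort:
    """Screen all admissions into a :class:`SepsisCohort`.

    Exclusions apply in order: age below threshold, no presumed serious
    infection, no organ dysfunction, missing site of infection.  The age
    rule is inclusive (``age >= age_threshold``): the cohort's youngest
    adult band starts at exactly 20 years.
    """
    ev = events.sort_values(["admission_id", "day_index"], kind="stable")
    grouped: dict[str, pd.DataFrame] = dict(tuple(ev.groupby("admission_id", sort=False)))
    empty = ev.iloc[0:0]

    n = len(admissions)
    init_day = np.full(n, -1)
    culture_day = np.full(n, -1)
    run_length = np.zeros(n, dtype=int)
    has_episode = np.zeros(n, dtype=bool)
    flag_cols: dict[str, np.ndarray] = {
        name: np.zeros(n, dtype=bool) for name in DYSFUNCTION_GROUPS
    }
    raw_flags = {
        "has_mechanical_ventilation": "mechanical_ventilation",
        "has_vasopressor": "vasopressor",
        "has_rrt": "renal_replacement_therapy",
    }
    raw_cols = {name: np.zeros(n, dtype=bool) for name in raw_flags}
    site_label = np.empty(n, dtype=object)

    ids = admissions["admission_id"].to_numpy()
    los_arr = admissions["length_of_stay"].to_numpy()
    sites = admissions["infection_site_codes"].to_numpy()

    for i in range(n):
        adm_events = grouped.get(ids[i], empty)
        if len(adm_events):
            abx = adm_events[adm_events["event_type"] == "iv_antibiotic"]
            cultures = np.unique(
                adm_events.loc[
                    adm_events["event_type"] == "blood_culture", "day_index"
                ].to_numpy()
            )
            episode = None
            if len(abx) and len(cultures):
                days_by_agent: dict[str, set[int]] = defaultdict(set)
                covered: set[int] = set()
                for day, agent in zip(abx["day_index"].to_numpy(), abx["agent"]):
                    days_by_agent[agent].add(int(day))
                    covered.add(int(day))
                episode = _detect_from_sets(
                    days_by_agent,
                    covered,
                    cultures,
                    lookback_days=lookback_days,
                    length_of_stay=int(los_arr[i]),
                    allow_censored_run=allow_censored_run,
                )
            if episode is not None:
                has_episode[i] = True
                init_day[i] = episode.initiation_day
                culture_day[i] = episode.culture_day
                run_length[i] = episode.run_length
            present = set(adm_events["event_type"])
            for name, types in DYSFUNCTION_GROUPS.items():
                flag_cols[name][i] = any(t in present for t in types)
            for col, etype in raw_flags.items():
                raw_cols[col][i] = etype in present
        site_label[i] = assign_site(sites[i])

    frame = admissions.copy().reset_index(drop=True)
    frame["site_label"] = site_label
    frame["initiation_day"] = init_day
    frame["culture_day"] = culture_day
    frame["run_length"] = run_length
    frame["has_episode"] = has_episode
    for name, col in flag_cols.items():
        frame[name] = col
    frame["any_dysfunction"] = np.logical_or.reduce(
        [flag_cols[name] for name in DYSFUNCTION_GROUPS]
    )
    for name, col in raw_cols.items():
        frame[name] = col
    frame["is_sepsis"] = frame["has_episode"] & frame["any_dysfunction"]

    of_age = frame["age"].to_numpy() >= age_threshold
    reason = np.empty(n, dtype=object)
    reason[:] = None
    reason[~of_age] = "below_age_threshold"
    sel = of_age & ~has_episode
    reason[sel] = "no_presumed_infection"
    sel = of_age & has_episode & ~frame["any_dysfunction"].to_numpy()
    reason[sel] = "no_organ_dysfunction"
    sel = (
        of_age
        & frame["is_sepsis"].to_numpy()
        & (frame["site_label"].to_numpy() == "missing")
    )
    reason[sel] = "missing_site"
    frame["exclusion_reason"] = reason
    frame["included"] = pd.isna(frame["exclusion_reason"])

    exclusions = {
        key: int((frame["exclusion_reason"] == key).sum())
        for key in EXCLUSION_REASONS
    }
    return SepsisCohort(frame=frame, exclusions=exclusions, age_threshold=age_threshold)
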