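import pandas as pd
import pytest

from sepsistrend import build_cohort, default_config, default_series_config, generate


@pytest.fixture(scope="session")
def small_data():
    """A desk-scale synthetic claims extract (~3.8k admissions, 8 years)."""
    cfg = default_config(scale=0.003, seed=7)
    return generate(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_data):
    admissions, events, _ = small_data
    return build_cohort(admissions, events)


@pytest.fixture(scope="session")
def series():
    return default_series_config()


def make_admission(**overrides) -> pd.DataFrame:
    """One-row admissions frame with sensible defaults."""
    row = {
        "admission_id": "A1",
        "patient_id": "P1",
        "admission_year": 2015,
        "age": 70,
        "sex": "female",
        "length_of_stay": 30,
        "discharge_status": "home",
        "icu_admission": False,
        "surgery": False,
        "chronic_disease_count": 1,
        "infection_site_codes": frozenset({"respiratory"}),
        "total_cost": 1_000_000.0,
    }
    row.update(overrides)
    return pd.DataFrame([row])


def make_events(rows, admission_id="A1") -> pd.DataFrame:
    """Events frame from (day, type[, agent]) tuples, sorted by day."""
    recs = []
    for row in rows:
        day, etype = row[0], row[1]
        agent = row[2] if len(row) > 2 else None
        recs.append(
            {
                "admission_id": admission_id,
                "day_index": day,
                "event_type": etype,
                "agent": agent,
            }
        )
    df = pd.DataFrame(
        recs, columns=["admission_id", "day_index", "event_type", "agent"]
    )
    return df.sort_values("day_index", kind="stable").reset_index(drop=True)
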