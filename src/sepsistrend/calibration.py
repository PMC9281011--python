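"""Published yearly aggregates of the Japanese nationwide DPC sepsis cohort
(2010-2017), used to calibrate the synthetic generator and as reference
inputs for printed-aggregate identity checks.

DPC (Diagnosis Procedure Combination) is Japan's bundled-payment acute-care
claims system.  The aggregates below describe the claims-defined adult
sepsis cohort drawn from it: yearly patient counts, in-hospital deaths
(repeat admissions removed), male counts, mean length of stay, and the
multiplicative effects of admission-level covariates on per-hospitalization
cost from the cohort's log-linear cost regression.
"""

from __future__ import annotations

STUDY_YEARS = list(range(2010, 2018))

#: Sepsis admissions per calendar year (included cohort).
PATIENTS_BY_YEAR = {
    2010: 67_318,
    2011: 100_060,
    2012: 126_414,
    2013: 141_670,
    2014: 181_813,
    2015: 197_388,
    2016: 228_190,
    2017: 233_825,
}

TOTAL_PATIENTS = 1_276_678

#: Unique sepsis patients after removing repeat hospitalizations.
TOTAL_UNIQUE_PATIENTS = 1_143_422

#: In-hospital deaths per year (among unique patients) and overall.
DEATHS_BY_YEAR = {
    2010: 15_620,
    2011: 20_108,
    2012: 24_848,
    2013: 25_405,
    2014: 30_348,
    2015: 31_152,
    2016: 34_801,
    2017: 34_325,
}
TOTAL_DEATHS = 216_607

#: Yearly in-hospital mortality, percent.
MORTALITY_PCT_BY_YEAR = {
    2010: 24.1,
    2011: 21.7,
    2012: 21.5,
    2013: 19.8,
    2014: 18.6,
    2015: 17.9,
    2016: 17.3,
    2017: 16.9,
}

MALE_BY_YEAR = {
    2010: 40_548,
    2011: 60_018,
    2012: 76_476,
    2013: 84_679,
    2014: 106_710,
    2015: 115_588,
    2016: 132_699,
    2017: 135_557,
}
TOTAL_MALE = 752_275
MALE_PCT = 58.9

#: Mean length of hospital stay per year, days.
MEAN_LOS_BY_YEAR = {
    2010: 50.3,
    2011: 51.6,
    2012: 51.0,
    2013: 47.3,
    2014: 44.2,
    2015: 43.0,
    2016: 41.2,
    2017: 41.1,
}

#: Median length of hospital stay per year, days.
MEDIAN_LOS_BY_YEAR = {
    2010: 34,
    2011: 33,
    2012: 33,
    2013: 30,
    2014: 28,
    2015: 28,
    2016: 26,
    2017: 26,
}

#: Exchange rate used for USD conversion of JPY costs.
JPY_PER_USD = 115.25

#: Exponentiated coefficients of the cohort's multivariable log-cost model
#: (multiplicative effect on per-hospitalization cost; abdominal site is the
#: reference category).
COST_MULTIPLIERS = {
    "age_per_year": 0.998,
    "male": 1.047,
    "per_chronic_disease": 1.078,
    "icu": 1.740,
    "surgery": 2.138,
    "per_los_day": 1.003,
    "per_year": 0.966,
    "site:respiratory": 1.096,
    "site:urogenital": 1.049,
    "site:abdominal": 1.0,
    "site:bone_soft_tissue": 1.186,
    "site:meninges_brain_spinal": 1.482,
    "site:heart": 1.620,
    "site:blood": 2.028,
    "site:multiple": 1.324,
    "site:unknown_explicit": 1.419,
}

#: Japan national consumer price index, all items (2015 = 100).
CPI_BY_YEAR = {
    2010: 96.5,
    2011: 96.3,
    2012: 96.2,
    2013: 96.6,
    2014: 99.2,
    2015: 100.0,
    2016: 99.9,
    2017: 100.4,
}

#: Synthetic yearly registrant counts for the claims system (increasing
#: coverage; the published total of screened adult registrants is ~50.5M
#: over the eight years).  Used only by the synthetic generator's default
#: series; real analyses supply their own.
SYNTHETIC_REGISTRANTS_BY_YEAR = {
    2010: 4_400_000,
    2011: 5_200_000,
    2012: 5_700_000,
    2013: 6_000_000,
    2014: 6_600_000,
    2015: 7_000_000,
    2016: 7_600_000,
    2017: 7_900_000,
}
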