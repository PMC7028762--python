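"""Published summary statistics of the evaluated outreach-clinic cohort.

These are the printed cohort-level margins of a German psychosocial
outreach-clinic evaluation (85 clients, pre-post design, payer perspective):
baseline demographics, per-category 12-month cost totals and user counts
before and after counseling, and the mean SF-6D utility trajectory. They
serve two purposes: calibration targets for the synthetic cohort generator,
and printed inputs for the arithmetic consistency checks of the reporting
layout (per-user means, annualization, difference column).

All monetary values are EUR. ``pre`` totals refer to the 12 months before
first contact (the surveyed 6 months extrapolated ×2), ``post`` to the 12
study months including the flat counseling fee.
"""

from __future__ import annotations

N_CLIENTS = 85
N_COMPLETERS = 73  # clients with the 12-month follow-up completed

FEMALE_PROP = 63 / 85  # 74.1%
AGE_MEAN = 45.7
AGE_SD = 17.0

EDUCATION_PROBS = {"lt_10th_grade": 47 / 85, "ge_10th_grade": 38 / 85}
LIVING_PROBS = {"alone": 44 / 85, "spouse_partner": 27 / 85, "parents_relatives_other": 14 / 85}
EMPLOYMENT_PROBS = {
    "self_employed": 16 / 85,
    "pensioned": 16 / 85,
    "unemployed": 35 / 85,
    "other": 18 / 85,
}
INCOME_SOURCE_PROBS = {"salary_pension": 39 / 85, "benefits_family": 46 / 85}
INCOME_MEAN = 669.0
INCOME_SD = 661.0

COUNSELING_FEE_EUR = 100.0

#: 12-month cost totals per service category (EUR), before counseling.
COST_TOTALS_PRE12M = {
    "inpatient": 213_774.0,
    "day_care": 54_121.0,
    "outpatient": 49_914.0,
    "medication": 61_866.0,
    "complementary": 92_276.0,
    "other": 23_733.0,
}

#: 12-month cost totals per service category (EUR), after counseling.
COST_TOTALS_POST12M = {
    "inpatient": 140_853.0,
    "day_care": 434.0,
    "outpatient": 68_204.0,
    "medication": 62_176.0,
    "complementary": 70_696.0,
    "other": 18_917.0,
    "counseling": 8_500.0,
}

#: Number of clients with any use of the category (printed per-user denominators).
N_USERS_PRE12M = {
    "inpatient": 22,
    "day_care": 4,
    "outpatient": 70,
    "medication": 53,
    "complementary": 75,
    "other": 31,
}
N_USERS_POST12M = {
    "inpatient": 20,
    "day_care": 1,
    "outpatient": 74,
    "medication": 67,
    "complementary": 73,
    "other": 44,
    "counseling": 85,
}

#: Printed per-client means (EUR per year).
MEAN_COST_PRE6M = 2_916.0
MEAN_COST_PRE12M = 5_832.0
MEAN_COST_POST12M = 4_350.0

#: Mean SF-6D utilities at baseline and the three follow-ups (LOCF-completed).
UTILITY_MEANS = (0.6051, 0.6535, 0.6602, 0.6927)
PCS_MEANS = (42.9, 43.7, 44.2, 44.6)
MCS_MEANS = (35.4, 40.3, 41.2, 44.2)

#: Printed period QALYs and their difference.
QALY_PRE = 0.6050
QALY_POST = 0.6618
QALY_GAIN = 0.0568

#: General-population reference for the mental component summary score.
POPULATION_MCS_REFERENCE = 49.3

#: Reported probability of cost-effectiveness at 50,000 EUR/QALY willingness to pay.
CEAC_AT_50K = 0.997
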