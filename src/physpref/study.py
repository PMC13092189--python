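"""Published summary tabulations of the reference outpatient survey.

The package ships the marginal counts reported by a cross-sectional survey of
324 adult neurosurgical outpatients at a German university hospital (respondent
demographics, symptom context, visit history, and per-scenario physician-gender
preference counts).  Respondent-level data were never deposited; these printed
margins are the calibration targets for the synthetic cohort generator and the
inputs to the operational fulfilment model.

Counts are stored as plain integers so that downstream percentages are derived,
never hard-coded.
"""

from __future__ import annotations

N_RESPONDENTS = 324

#: The five clinical scenarios, in fixed reporting order.
SCENARIOS = (
    "consultation",
    "examination",
    "intervention",
    "operation",
    "bad_news",
)

#: Per scenario: (respondents with any gender preference, of whom prefer a
#: female physician).  Denominator is N_RESPONDENTS for every scenario.
SCENARIO_COUNTS: dict[str, tuple[int, int]] = {
    "consultation": (116, 59),
    "examination": (137, 68),
    "intervention": (156, 78),
    "operation": (139, 67),
    "bad_news": (106, 57),
}

# ---------------------------------------------------------------------------
# Demographic / contextual marginals.  Categories are listed in codebook order;
# a separate *_MISSING count records item nonresponse where the survey
# reported any.
# ---------------------------------------------------------------------------

GENDER_COUNTS = {"female": 161, "male": 159, "diverse": 1}
GENDER_MISSING = 3

AGE_COUNTS = {"<20": 17, "20-39": 62, "40-59": 100, "60-79": 113, ">=80": 28}
AGE_MISSING = 4

DISEASE_COUNTS = {"tumour": 115, "spine": 148, "other": 59}
DISEASE_MISSING = 2

#: Education; "no_response" was reported as its own row, not as missing.
EDUCATION_COUNTS = {
    "primary": 26,
    "lower_secondary": 125,
    "upper_secondary": 93,
    "university": 68,
    "no_response": 12,
}

RELIGION_COUNTS = {
    "protestant": 65,
    "catholic": 26,
    "other_christian": 17,
    "muslim": 13,
    "jewish": 5,
    "other": 12,
    "none": 186,
}

IMMIGRATION_COUNTS = {"no": 279, "yes": 26, "no_response": 19}

FIRST_VISIT_COUNTS = {"no": 205, "yes": 119}

PRIOR_REQUEST_COUNTS = {"no": 290, "yes": 34}

LIMITS_COUNTS = {"no": 137, "yes": 187}
WORRYING_COUNTS = {"no": 156, "yes": 168}
PAINFUL_COUNTS = {"no": 140, "yes": 184}
EMBARRASSING_COUNTS = {"no": 280, "yes": 44}


def scenario_prevalence(scenario: str) -> float:
    """Any-preference probability for a scenario (count / 324)."""
    return SCENARIO_COUNTS[scenario][0] / N_RESPONDENTS


def scenario_direction(scenario: str) -> float:
    """Female-direction share among preferrers (p0) for a scenario."""
    any_n, female_n = SCENARIO_COUNTS[scenario]
    return female_n / any_n


def pref_column(scenario: str) -> str:
    """Name of the cohort-table column holding a scenario's response."""
    if scenario not in SCENARIOS:
        raise KeyError(f"unknown scenario: {scenario!r}")
    return f"pref_{scenario}"
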