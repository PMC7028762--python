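"""Observation-period model of the pre-post design.

Service use is recorded retrospectively: the 6 months before first contact
(``pre6m``) and three follow-up intervals covering the 12 months under
observation (baseline to 3 months, 3 to 6, 6 to 12). Visits are indexed 0..3
(baseline plus three follow-ups); follow-up interval ``fu{k}`` ends at visit k.
"""

from __future__ import annotations

PRE_PERIOD = "pre6m"
FOLLOWUP_PERIODS = ("fu1", "fu2", "fu3")
PERIODS = (PRE_PERIOD,) + FOLLOWUP_PERIODS

#: Interval lengths in months.
PERIOD_MONTHS = {"pre6m": 6.0, "fu1": 3.0, "fu2": 3.0, "fu3": 6.0}

#: Nominal visit times in years used for the QALY area under the curve.
VISIT_TIMES_YEARS = (0.0, 0.25, 0.5, 1.0)

PRE_WINDOW = "pre12m"
POST_WINDOW = "post12m"

#: Follow-up period covering visit k (k = 1..3).
PERIOD_FOR_VISIT = {1: "fu1", 2: "fu2", 3: "fu3"}


def followups_after(last_observed_visit: int) -> tuple[str, ...]:
    """Follow-up periods missing for a client last seen at the given visit."""
    if not 0 <= last_observed_visit <= 3:
        raise ValueError(f"last_observed_visit must be in 0..3, got {last_observed_visit}")
    return FOLLOWUP_PERIODS[last_observed_visit:]
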