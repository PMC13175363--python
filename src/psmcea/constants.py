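"""Time-axis constants shared across the engine.

The canonical time unit is the MONTH: the case-study survival parameters
are lognormal fits on a month axis (exp(meanlog) of the overall-survival
fits, 21.97 and 13.66 months, matches the trial's published medians of
22.1 and 14.2 months).  Cycles are 21 days, aligned with the 3-weekly
dosing schedule.
"""

DAYS_PER_YEAR = 365.25
MONTHS_PER_YEAR = 12.0
DAYS_PER_MONTH = DAYS_PER_YEAR / MONTHS_PER_YEAR  # 30.4375

CYCLE_LENGTH_DAYS = 21.0
CYCLE_MONTHS = CYCLE_LENGTH_DAYS / DAYS_PER_MONTH  # ~0.6899 months
CYCLE_YEARS = CYCLE_LENGTH_DAYS / DAYS_PER_YEAR    # ~0.05749 years
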