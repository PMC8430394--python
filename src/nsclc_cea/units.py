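"""Time-unit conversions shared by the whole model.

All survival curves are parameterised in months; the cohort model advances
in 6-week cycles; discounting is annual.  Keeping every conversion here
avoids the classic cycle-length bookkeeping bugs.
"""

DAYS_PER_MONTH: float = 30.4375
DAYS_PER_YEAR: float = 365.25
CYCLE_DAYS: float = 42.0  # one model cycle = 6 weeks

CYCLE_MONTHS: float = CYCLE_DAYS / DAYS_PER_MONTH
CYCLE_YEARS: float = CYCLE_DAYS / DAYS_PER_YEAR
MONTHS_PER_YEAR: float = DAYS_PER_YEAR / DAYS_PER_MONTH  # = 12 exactly


def months_to_years(months: float) -> float:
    return months / MONTHS_PER_YEAR


def years_to_months(years: float) -> float:
    return years * MONTHS_PER_YEAR


def cycles_to_months(cycles: float) -> float:
    return cycles * CYCLE_MONTHS


def cycles_to_years(cycles: float) -> float:
    return cycles * CYCLE_YEARS
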