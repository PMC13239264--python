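"""Fixed calendar conversions used throughout the package.

Clinical windows are specified in months/years; internally every time is a
signed float number of days relative to therapy start (day 0). A fixed
conversion (1 month = 30.4375 d, 1 year = 365.25 d) keeps window boundaries
exactly testable.
"""

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

#: follow-up horizon for event ascertainment: 6 years from therapy start
FOLLOWUP_DAYS = 6 * DAYS_PER_YEAR  # 2191.5

#: comorbidity ascertainment window: 5 years before therapy start
LOOKBACK_DAYS = 5 * DAYS_PER_YEAR  # 1826.25
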