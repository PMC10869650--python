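"""Follow-up schedule and time conventions shared by valuation and costing.

Two questionnaire schedules run in parallel: the generic instrument is
administered at baseline, 4 weeks and 3 months post-surgery, then 15, 24 and
36 months post-randomisation; the condition-specific instrument at baseline,
3, 15, 24 and 36 months.  Resource use is collected for the 3, 15, 24 and
36 month periods.  Days since randomisation is the integration axis.
"""

from __future__ import annotations

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0

#: questionnaire time-point labels, in schedule order
EQ5D_TIMEPOINTS = ("baseline", "4w", "3m", "15m", "24m", "36m")
ICIQ_TIMEPOINTS = ("baseline", "3m", "15m", "24m", "36m")

#: resource-use collection periods (labels shared with cost columns)
PERIODS = ("3m", "15m", "24m", "36m")

#: post-randomisation anchors (days); the 4w/3m points are surgery-anchored
FIXED_ANCHOR_DAYS = {"baseline": 0.0, "15m": 456.0, "24m": 730.0, "36m": 1096.0}
SURGERY_OFFSET_DAYS = {"4w": 28.0, "3m": 91.0}

#: horizon and annual discount-bucket boundaries (days)
HORIZON_DAYS = 36 * DAYS_PER_MONTH          # 1095.75
YEAR_BOUNDARIES = (DAYS_PER_YEAR, 2 * DAYS_PER_YEAR)

#: discount year index (1-based) per cost period: year 1 undiscounted,
#: year k discounted by (1+r)^-(k-1).  The 15-month period is treated as
#: year 1 (only costs accrued in the 24- and 36-month periods are
#: discounted).
PERIOD_DISCOUNT_YEAR = {"3m": 1, "15m": 1, "24m": 2, "36m": 3}


def anchor_day(timepoint: str, surgery_day: float | None) -> float | None:
    """Days since randomisation for a questionnaire time point.

    Surgery-anchored points return ``None`` when the patient never had
    surgery (the questionnaire was never administered).
    """
    if timepoint in FIXED_ANCHOR_DAYS:
        return FIXED_ANCHOR_DAYS[timepoint]
    if timepoint in SURGERY_OFFSET_DAYS:
        if surgery_day is None:
            return None
        return float(surgery_day) + SURGERY_OFFSET_DAYS[timepoint]
    raise KeyError(f"unknown time point: {timepoint!r}")


def discount_factor(year_index: int, rate: float) -> float:
    """Discount factor for QALYs/costs accrued in 1-based ``year_index``."""
    return (1.0 + rate) ** -(year_index - 1)
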