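"""Calendar arithmetic on integer day offsets.

All dates in the package are integer day offsets from an epoch
(2000-01-01) and all intervals are half-open ``[start, end)``, which
makes gap and overlap arithmetic unambiguous. Calendar phrases are
converted with 1 month = 30.44 days and 1 year = 365.25 days.
"""
from __future__ import annotations

import datetime as _dt

EPOCH = _dt.date(2000, 1, 1)
DAYS_PER_MONTH = 30.44
DAYS_PER_YEAR = 365.25


def to_day(value: int | str | _dt.date) -> int:
    """Convert an ISO date string, ``datetime.date`` or int to a day offset."""
    if isinstance(value, bool):
        raise TypeError("booleans are not dates")
    if isinstance(value, int):
        return value
    if isinstance(value, str):
        value = _dt.date.fromisoformat(value)
    if isinstance(value, _dt.date):
        return (value - EPOCH).days
    raise TypeError(f"cannot interpret {value!r} as a day offset")


def to_date(day: int) -> _dt.date:
    return EPOCH + _dt.timedelta(days=int(day))


def days_to_months(days):
    return days / DAYS_PER_MONTH


def days_to_years(days):
    return days / DAYS_PER_YEAR


def months_to_days(months):
    return months * DAYS_PER_MONTH
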