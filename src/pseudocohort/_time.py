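"""Calendar helpers shared across modules.

All event dates are numpy ``datetime64[D]``; exposure is evaluated on a
monthly grid of month-start dates.  The state for month *m* reflects events
dated on or before the first day of *m* (windowed looks-backs are inclusive
of the boundary day).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25


def as_date(x) -> np.datetime64:
    """Coerce an ISO string / Timestamp / datetime64 to datetime64[D]."""
    return np.datetime64(pd.Timestamp(x).date(), "D")


def month_starts(start, end) -> np.ndarray:
    """Month-start grid covering [start, end] (both clipped to month starts).

    The first element is the start of the month containing ``start``; the
    last is the start of the month containing ``end``.
    """
    s = pd.Timestamp(as_date(start)).to_period("M").to_timestamp()
    e = pd.Timestamp(as_date(end)).to_period("M").to_timestamp()
    return pd.date_range(s, e, freq="MS").values.astype("datetime64[D]")


def month_index(grid: np.ndarray, dates) -> np.ndarray:
    """Index of the month containing each date (-1 before grid, clipped after)."""
    d = np.asarray(dates, dtype="datetime64[D]")
    idx = np.searchsorted(grid, d, side="right") - 1
    return np.minimum(idx, len(grid) - 1)


def add_years(date, years: float) -> np.datetime64:
    return as_date(pd.Timestamp(as_date(date)) + pd.Timedelta(days=round(years * DAYS_PER_YEAR)))


def add_months(date, months: int) -> np.datetime64:
    return as_date(pd.Timestamp(as_date(date)) + pd.DateOffset(months=months))


def years_between(a, b) -> float:
    """(b - a) in years, using a 365.25-day year."""
    return float((as_date(b) - as_date(a)) / np.timedelta64(1, "D")) / DAYS_PER_YEAR
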