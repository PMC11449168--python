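"""Calendar-month assignment under the study timezone.

Detections are stored in UTC; behavioural months are calendar months at the
field site, so month binning shifts timestamps by a configurable offset
(default UTC+10) before reading off year and month.
"""

from __future__ import annotations

import pandas as pd

DEFAULT_TZ_OFFSET_HOURS = 10.0


def study_month(
    timestamps: pd.Series, tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS
) -> pd.DataFrame:
    """Return a frame with ``year`` and ``month`` columns for each timestamp."""
    local = timestamps + pd.Timedelta(hours=tz_offset_hours)
    return pd.DataFrame({"year": local.dt.year, "month": local.dt.month},
                        index=timestamps.index)


def study_date(
    timestamps: pd.Series, tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS
) -> pd.Series:
    local = timestamps + pd.Timedelta(hours=tz_offset_hours)
    return local.dt.date


def next_month(key: tuple[int, int]) -> tuple[int, int]:
    year, month = key
    return (year + 1, 1) if month == 12 else (year, month + 1)
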