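"""Monthly social environments, co-occurrence associations and sociability.

An individual's *social environment* in a calendar month is the set of
tagged conspecifics detected, during that month, at any receiver the focal
individual was also detected at. Two individuals *associate* when they
co-occur at the same receiver within a sampling window (default 4 min).
Sociability is the monthly proportion of the social environment the focal
actually associated with; it is undefined (missing, not zero) when the
environment is empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .movement_metrics import MonthlyUD
from .timeutil import DEFAULT_TZ_OFFSET_HOURS, study_month

DEFAULT_WINDOW_S = 240.0


@dataclass(frozen=True)
class MonthlySocial:
    individual_id: str
    year: int
    month: int
    potential_associates: frozenset
    observed_associates: frozenset
    sociability: float | None

    def __post_init__(self) -> None:
        if not self.observed_associates <= self.potential_associates:
            raise ValueError("observed associates must be a subset of potential")


def _with_month(
    detections: pd.DataFrame, tz_offset_hours: float
) -> pd.DataFrame:
    ym = study_month(detections["timestamp"], tz_offset_hours)
    return detections.assign(year=ym["year"], month=ym["month"])


def social_environment(
    focal: str,
    month: tuple[int, int],
    detections: pd.DataFrame,
    tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS,
) -> set[str] | None:
    """Potential associates of ``focal`` in calendar ``month`` (year, month).

    Conspecifics qualify through any detection during the month at a
    receiver the focal visited that month, regardless of timing within the
    month. Returns None (absent, not empty) if the focal itself was not
    detected that month.
    """
    df = _with_month(detections, tz_offset_hours)
    df = df[(df["year"] == month[0]) & (df["month"] == month[1])]
    focal_receivers = set(df.loc[df["tag_id"] == focal, "receiver_id"])
    if not focal_receivers:
        return None
    others = df[(df["tag_id"] != focal) & df["receiver_id"].isin(focal_receivers)]
    return set(others["tag_id"])


def detect_associations(
    detections: pd.DataFrame,
    window_s: float = DEFAULT_WINDOW_S,
    tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS,
    mode: str = "pairwise",
) -> pd.DataFrame:
    """Co-occurrence events at shared receivers.

    ``pairwise`` (default): an event for every pair of detections of two
    different individuals at the same receiver whose timestamps differ by at
    most ``window_s`` seconds (sliding window, no bin-boundary artefacts).
    ``binned``: both detections fall in the same fixed window-length bin.

    Returns one row per event with the pair stored canonically
    (individual_a < individual_b) and the study-month of the earlier
    detection; downstream sociability deduplicates to one associate
    relation per pair-month.
    """
    if mode not in {"pairwise", "binned"}:
        raise ValueError("mode must be 'pairwise' or 'binned'")
    rows = []
    df = detections.sort_values(["receiver_id", "timestamp"], kind="mergesort")
    for receiver, g in df.groupby("receiver_id", sort=False):
        times = g["timestamp"].to_numpy()
        tags = g["tag_id"].to_numpy()
        if mode == "binned":
            bins = g["timestamp"].dt.floor(pd.Timedelta(seconds=window_s)).to_numpy()
        t_ns = g["timestamp"].astype("int64").to_numpy()
        j = 0
        for i in range(len(g)):
            j = max(j, i + 1)
            while j < len(g) and t_ns[j] - t_ns[i] <= window_s * 1e9:
                j += 1
            for jj in range(i + 1, j):
                if tags[i] == tags[jj]:
                    continue
                if mode == "binned" and bins[i] != bins[jj]:
                    continue
                a, b = sorted((tags[i], tags[jj]))
                first = times[i] if times[i] <= times[jj] else times[jj]
                rows.append((a, b, receiver, times[i], times[jj], first))
    events = pd.DataFrame(
        rows,
        columns=[
            "individual_a", "individual_b", "receiver_id",
            "time_a", "time_b", "time_first",
        ],
    )
    if events.empty:
        events["year"] = pd.Series(dtype=int)
        events["month"] = pd.Series(dtype=int)
        return events
    ym = study_month(events["time_first"], tz_offset_hours)
    events["year"], events["month"] = ym["year"], ym["month"]
    return events.drop(columns="time_first")


def monthly_sociability(
    focal: str,
    month: tuple[int, int],
    detections: pd.DataFrame,
    window_s: float = DEFAULT_WINDOW_S,
    tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS,
    events: pd.DataFrame | None = None,
) -> MonthlySocial | None:
    """Sociability of ``focal`` in ``month``: |observed| / |potential|.

    ``events`` may carry precomputed output of :func:`detect_associations`
    over the same detections to avoid recomputation. Returns None if the
    focal was undetected that month; sociability is None when the social
    environment is empty (the ratio is undefined).
    """
    potential = social_environment(focal, month, detections, tz_offset_hours)
    if potential is None:
        return None
    if events is None:
        events = detect_associations(detections, window_s, tz_offset_hours)
    ev = events[
        (events["year"] == month[0])
        & (events["month"] == month[1])
        & ((events["individual_a"] == focal) | (events["individual_b"] == focal))
    ]
    partners = set(ev["individual_a"]) | set(ev["individual_b"])
    partners.discard(focal)
    observed = partners & potential
    sociability = len(observed) / len(potential) if potential else None
    return MonthlySocial(
        individual_id=focal,
        year=month[0],
        month=month[1],
        potential_associates=frozenset(potential),
        observed_associates=frozenset(observed),
        sociability=sociability,
    )


def monthly_associate_counts(
    detections: pd.DataFrame,
    uds: dict[tuple[str, int, int], MonthlyUD],
    window_s: float = DEFAULT_WINDOW_S,
    tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS,
    channel_width_km: float | None = None,
) -> pd.DataFrame:
    """Potential/observed associate counts with home-range size.

    Two rows per individual-month (type ``potential`` and ``observed``)
    restricted to individual-months that have a home-range estimate;
    ``hr_size`` is linear km, or km^2 when ``channel_width_km`` is given.
    """
    events = detect_associations(detections, window_s, tz_offset_hours)
    rows = []
    for (ind, year, month), ud in sorted(uds.items()):
        social = monthly_sociability(
            ind, (year, month), detections, window_s, tz_offset_hours, events=events
        )
        if social is None:
            continue
        hr = ud.hr_size_km2(channel_width_km) if channel_width_km else ud.hr_size_km
        rows.append((ind, year, month, hr, "potential", len(social.potential_associates)))
        rows.append((ind, year, month, hr, "observed", len(social.observed_associates)))
    return pd.DataFrame(
        rows,
        columns=["individual_id", "year", "month", "hr_size", "type", "count"],
    )
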