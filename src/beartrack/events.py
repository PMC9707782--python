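"""Detection-event processing for camera-trap records.

Raw camera records are collapsed into independent detection events (records
separated by at least a quiet period, 30 minutes by default), classified as
diurnal or nocturnal from local sunrise/sunset, and aggregated into the
site x month count/effort table that the count models consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .solar import sun_times

__all__ = [
    "DetectionEvent",
    "season_of",
    "independent_events",
    "classify_diel",
    "classify_events",
    "monthly_counts",
    "detection_rate",
]

SEASONS = {
    2: "spring", 3: "spring", 4: "spring",
    5: "summer", 6: "summer", 7: "summer",
    8: "autumn", 9: "autumn", 10: "autumn",
    11: "winter", 12: "winter", 1: "winter",
}

STRATA = ("urban", "rural", "wild")


@dataclass(frozen=True)
class DetectionEvent:
    site_id: str
    event_time: datetime
    diel: str | None = None
    stratum: str | None = None


def season_of(month: int) -> str:
    """Season of a calendar month: spring Feb-Apr, summer May-Jul,
    autumn Aug-Oct, winter Nov-Jan."""
    if month not in SEASONS:
        raise ValueError(f"invalid month {month!r}")
    return SEASONS[month]


def independent_events(
    records: pd.DataFrame,
    gap_minutes: float = 30.0,
    *,
    from_event_start: bool = False,
) -> pd.DataFrame:
    """Collapse time-sorted records at one site into independent events.

    A record opens a new event iff it is separated from the immediately
    preceding record by >= ``gap_minutes`` (a gap of exactly the threshold
    counts as independent).  With ``from_event_start=True`` the gap is
    measured from the opening record of the current event instead.

    Parameters
    ----------
    records
        DataFrame with columns ``site_id`` and ``timestamp`` (tz-aware),
        sorted by timestamp, all from one site (and one species).
    gap_minutes
        Quiet period in minutes, default 30.

    Returns
    -------
    DataFrame with one row per event: ``site_id``, ``event_time`` (the
    opening record's timestamp), ``n_records``.
    """
    if gap_minutes <= 0:
        raise ValueError("gap_minutes must be positive")
    if records.empty:
        return pd.DataFrame(columns=["site_id", "event_time", "n_records"])
    sites = records["site_id"].unique()
    if len(sites) > 1:
        raise ValueError(f"records from mixed sites: {sorted(map(str, sites))}")
    ts = pd.to_datetime(records["timestamp"])
    if not ts.is_monotonic_increasing:
        raise ValueError("records must be sorted by timestamp")

    t = ts.to_numpy()
    gap = np.timedelta64(int(round(gap_minutes * 60)), "s")
    if from_event_start:
        opens = np.zeros(len(t), dtype=bool)
        opens[0] = True
        anchor = t[0]
        for i in range(1, len(t)):
            if t[i] - anchor >= gap:
                opens[i] = True
                anchor = t[i]
    else:
        opens = np.empty(len(t), dtype=bool)
        opens[0] = True
        opens[1:] = (t[1:] - t[:-1]) >= gap
    event_id = np.cumsum(opens) - 1
    n_records = np.bincount(event_id)
    return pd.DataFrame(
        {
            "site_id": sites[0],
            "event_time": ts.to_numpy()[opens],
            "n_records": n_records,
        }
    )


def classify_diel(event_time: datetime, latitude: float, longitude: float,
                  utc_offset: float = -8.0) -> str:
    """Label an event diurnal or nocturnal: day iff sunrise <= t < sunset.

    The civil date is taken in the configured offset, so labels do not
    depend on the offset the timestamp happened to be stored in.
    """
    if event_time.tzinfo is None:
        raise ValueError("event_time must be timezone-aware")
    local = event_time.astimezone(timezone(timedelta(hours=utc_offset)))
    st = sun_times(latitude, longitude, local.date(), utc_offset)
    return "day" if st.sunrise <= event_time < st.sunset else "night"


def classify_events(events: pd.DataFrame, deployments: pd.DataFrame,
                    utc_offset: float = -8.0) -> pd.DataFrame:
    """Attach ``diel`` and ``stratum`` columns to an event table.

    ``deployments`` needs one row per site with ``site_id``, ``lat``, ``lon``
    and ``stratum`` (extra per-month rows are collapsed).
    """
    site_info = deployments.drop_duplicates("site_id").set_index("site_id")
    missing = set(events["site_id"]) - set(site_info.index)
    if missing:
        raise ValueError(f"events at sites absent from deployments: {sorted(missing)}")
    out = events.copy()
    diel = []
    for site, t in zip(out["site_id"], pd.to_datetime(out["event_time"])):
        row = site_info.loc[site]
        diel.append(classify_diel(t.to_pydatetime(), float(row["lat"]), float(row["lon"]), utc_offset))
    out["diel"] = diel
    out["stratum"] = out["site_id"].map(site_info["stratum"]).to_numpy()
    return out


def monthly_counts(events: pd.DataFrame, deployments: pd.DataFrame,
                   utc_offset: float = -8.0) -> pd.DataFrame:
    """Build the site x month modelling table.

    Parameters
    ----------
    events
        Independent events with ``site_id`` and ``event_time``.
    deployments
        Long table with ``site_id``, ``month`` (YYYY-MM), ``active_days``,
        and per-site ``stratum``.

    Returns
    -------
    One row per deployment site-month: ``site_id``, ``month``, ``count``,
    ``effort``, ``season``, ``stratum``.  An event in a month with zero
    active days is a data inconsistency and raises.
    """
    dep = deployments.copy()
    dep["month"] = dep["month"].astype(str)
    base = dep[["site_id", "month", "active_days"]].rename(columns={"active_days": "effort"})
    if base.duplicated(["site_id", "month"]).any():
        raise ValueError("duplicate site-month rows in deployments")

    if len(events):
        ev_time = pd.to_datetime(events["event_time"])
        if ev_time.dt.tz is not None:
            # month boundaries in the site's civil time, not the storage offset
            ev_time = ev_time.dt.tz_convert(timezone(timedelta(hours=utc_offset)))
        ev_month = ev_time.dt.strftime("%Y-%m")
        counts = (
            pd.DataFrame({"site_id": events["site_id"], "month": ev_month})
            .groupby(["site_id", "month"])
            .size()
            .rename("count")
            .reset_index()
        )
    else:
        counts = pd.DataFrame(columns=["site_id", "month", "count"])

    out = base.merge(counts, on=["site_id", "month"], how="left")
    out["count"] = out["count"].fillna(0).astype(int)

    stray = counts.merge(base, on=["site_id", "month"], how="left", indicator=True)
    bad = stray[(stray["_merge"] == "left_only") | (stray["effort"].fillna(0) == 0)]
    if len(bad):
        pairs = list(bad[["site_id", "month"]].itertuples(index=False, name=None))
        raise ValueError(f"events outside any active site-month interval: {pairs}")

    out["season"] = [season_of(int(m[5:7])) for m in out["month"]]
    if "stratum" in dep.columns:
        strat = dep.drop_duplicates("site_id").set_index("site_id")["stratum"]
        out["stratum"] = out["site_id"].map(strat).to_numpy()
    return out.sort_values(["site_id", "month"]).reset_index(drop=True)


def detection_rate(count: float, effort: float, days_in_month: int) -> float:
    """Monthly detection rate: (count / active days) * days in month.

    Undefined (NaN) when effort is zero; a rate is not the same as a count
    unless the camera was active the whole month.
    """
    if effort == 0:
        return float("nan")
    return count / effort * days_in_month
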