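"""Sleep features: mid-sleep, social jet lag (ΔMS), and timing regularity.

Clock times live on a 24-hour dial, so all location and spread statistics
here are circular: a mid-sleep of 23:30 and one of 00:30 are an hour apart,
not 23.  Mid-sleep is the clock time halfway between sleep onset and wake.
Per participant, MSW and MSF are the circular medians of workday and
free-day mid-sleeps, and social jet lag is their circular distance

    ΔMS = min(|MSW − MSF|, 1440 − |MSW − MSF|)   [minutes, 0–720]

— a behavioural proxy for circadian misalignment.  The circular median is
computed by re-expressing each observation in the half-open 24 h window
centred on the group's circular mean and taking the ordinary median there;
the circular range is the shortest arc containing every observation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .day_labeling import assign_work_status

__all__ = [
    "MINUTES_PER_DAY",
    "mid_sleep",
    "clock_distance",
    "circular_mean",
    "circular_median",
    "circular_range",
    "sleep_profile",
    "sleep_regularity_summary",
]

MINUTES_PER_DAY = 1440.0


def _clock_minutes(ts) -> np.ndarray:
    ts = pd.Series(pd.to_datetime(ts))
    return (
        ts.dt.hour * 60 + ts.dt.minute + ts.dt.second / 60.0 + ts.dt.microsecond / 6e7
    ).to_numpy()


def mid_sleep(onset, offset) -> float | np.ndarray:
    """Clock time (minutes past midnight, [0, 1440)) of the sleep midpoint."""
    onset = pd.to_datetime(onset)
    offset = pd.to_datetime(offset)
    scalar = not isinstance(onset, (pd.Series, pd.DatetimeIndex))
    onset_s = pd.Series([onset]) if scalar else pd.Series(onset)
    offset_s = pd.Series([offset]) if scalar else pd.Series(offset)
    if (offset_s <= onset_s).any():
        raise ValueError("sleep offset must be after onset")
    mid = onset_s + (offset_s - onset_s) / 2
    out = _clock_minutes(mid) % MINUTES_PER_DAY
    return float(out[0]) if scalar else out


def clock_distance(a: float, b: float) -> float:
    """Shortest distance between two clock times, in minutes (0–720)."""
    d = abs(float(a) - float(b)) % MINUTES_PER_DAY
    return min(d, MINUTES_PER_DAY - d)


def circular_mean(minutes) -> float:
    """Circular mean of clock times in minutes, in [0, 1440)."""
    m = np.asarray(minutes, dtype=float)
    if m.size == 0:
        raise ValueError("circular_mean of empty set")
    theta = 2 * np.pi * m / MINUTES_PER_DAY
    ang = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    return float((ang * MINUTES_PER_DAY / (2 * np.pi)) % MINUTES_PER_DAY)


def _recentre(minutes: np.ndarray, centre: float) -> np.ndarray:
    """Re-express clock times in the 24 h window [centre−720, centre+720)."""
    return (minutes - centre + MINUTES_PER_DAY / 2) % MINUTES_PER_DAY - MINUTES_PER_DAY / 2 + centre


def circular_median(minutes) -> float:
    """Median clock time after re-centring on the circular mean, in [0, 1440)."""
    m = np.asarray(minutes, dtype=float)
    if m.size == 0:
        raise ValueError("circular_median of empty set")
    centre = circular_mean(m)
    return float(np.median(_recentre(m, centre)) % MINUTES_PER_DAY)


def circular_range(minutes) -> float:
    """Length of the shortest arc containing all clock times (minutes).

    Equal to 1440 minus the largest gap between circularly adjacent
    observations; 0 for a single observation.
    """
    m = np.sort(np.asarray(minutes, dtype=float) % MINUTES_PER_DAY)
    if m.size == 0:
        raise ValueError("circular_range of empty set")
    if m.size == 1:
        return 0.0
    gaps = np.diff(np.concatenate([m, [m[0] + MINUTES_PER_DAY]]))
    return float(MINUTES_PER_DAY - gaps.max())


def _session_statuses(sessions: pd.DataFrame, labels: pd.DataFrame) -> pd.Series:
    return assign_work_status(sessions["onset"], sessions["participant_id"], labels)


def sleep_profile(
    sessions: pd.DataFrame,
    labels: pd.DataFrame,
    min_sessions: int = 5,
    min_session_min: float = 0.0,
) -> pd.DataFrame:
    """Per-participant sleep profile with MSW, MSF, and ΔMS.

    Sessions are assigned the work status of the analysis day containing
    their onset.  MSW / MSF are circular medians of the per-session
    mid-sleeps; ΔMS is their circular distance.  Duration and efficiency are
    ordinary means.  A participant is eligible for a status with at least
    ``min_sessions`` sessions of it; ΔMS is reported only when both flags
    hold.  Sessions shorter than ``min_session_min`` minutes are dropped
    before anything else (default keeps naps).
    """
    df = sessions.copy()
    if min_session_min > 0:
        df = df[df["duration_min"] >= min_session_min]
    if df.empty:
        return pd.DataFrame(
            columns=[
                "participant_id", "msw", "msf", "delta_ms",
                "duration_workday", "duration_offday",
                "efficiency_workday", "efficiency_offday",
                "n_workday", "n_offday", "eligible_workday", "eligible_offday",
            ]
        )
    df["status"] = _session_statuses(df, labels).to_numpy()
    df = df[df["status"].isin(["workday", "offday"])].copy()
    df["mid"] = mid_sleep(df["onset"], df["offset"])

    rows = []
    for pid, grp in df.groupby("participant_id", sort=True):
        row: dict = {"participant_id": pid}
        mids = {}
        for status in ("workday", "offday"):
            sub = grp[grp["status"] == status]
            n = len(sub)
            row[f"n_{status}"] = n
            row[f"eligible_{status}"] = n >= min_sessions
            row[f"duration_{status}"] = sub["duration_min"].mean() if n else np.nan
            row[f"efficiency_{status}"] = sub["efficiency_pct"].mean() if n else np.nan
            mids[status] = circular_median(sub["mid"].to_numpy()) if n else np.nan
        row["msw"] = mids["workday"]
        row["msf"] = mids["offday"]
        if row["eligible_workday"] and row["eligible_offday"]:
            row["delta_ms"] = clock_distance(row["msw"], row["msf"])
        else:
            row["delta_ms"] = np.nan
        rows.append(row)
    cols = [
        "participant_id", "msw", "msf", "delta_ms",
        "duration_workday", "duration_offday",
        "efficiency_workday", "efficiency_offday",
        "n_workday", "n_offday", "eligible_workday", "eligible_offday",
    ]
    return pd.DataFrame(rows)[cols]


def sleep_regularity_summary(
    sessions: pd.DataFrame, labels: pd.DataFrame
) -> pd.DataFrame:
    """Circular median and range of onset / offset clock times per status.

    One row per status present in the data (statuses with no sessions are
    omitted), mirroring the distribution summaries used to contrast sleep
    timing regularity between groups.
    """
    df = sessions.copy()
    df["status"] = _session_statuses(df, labels).to_numpy()
    df = df[df["status"].isin(["workday", "offday"])]
    rows = []
    for status, grp in df.groupby("status", sort=True):
        onset = _clock_minutes(grp["onset"])
        offset = _clock_minutes(grp["offset"])
        rows.append(
            {
                "status": status,
                "n": len(grp),
                "onset_median": circular_median(onset),
                "onset_range": circular_range(onset),
                "offset_median": circular_median(offset),
                "offset_range": circular_range(offset),
            }
        )
    return pd.DataFrame(rows)
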