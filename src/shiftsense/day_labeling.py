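"""Workday / off-day inference and the 23:00-anchored analysis-day window.

A nurse's "day" does not align with the calendar: the first diurnal bin used
for activity profiles spans 23:00–03:00, so the analysis day for date *d*
runs from 23:00 on *d−1* to 23:00 on *d*.  Every timestamp maps to exactly
one analysis day, and a sleep session belongs to the analysis day containing
its onset (a night nurse's post-shift morning sleep therefore counts toward
the workday it follows).

Work status is inferred per participant-day from three evidence sources
with a fixed precedence — daily survey confirmation, then garment-sensor
presence, then badge-proximity hits in the unit — because the roster itself
is not observed.  Days with no evidence stay ``unknown`` and are excluded
from all status-conditional aggregates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ANALYSIS_DAY_START_HOUR",
    "DIURNAL_BIN_LABELS",
    "analysis_date",
    "diurnal_bin",
    "label_days",
    "assign_work_status",
]

ANALYSIS_DAY_START_HOUR = 23

#: 4-hour diurnal bins, in analysis-day order.
DIURNAL_BIN_LABELS = ("23-3", "3-7", "7-11", "11-15", "15-19", "19-23")

_SHIFT = pd.Timedelta(hours=24 - ANALYSIS_DAY_START_HOUR)


def analysis_date(timestamps) -> pd.Series:
    """Map timestamps to their analysis-day date (window 23:00 → 23:00)."""
    ts = pd.Series(pd.to_datetime(timestamps))
    return (ts + _SHIFT).dt.normalize()


def diurnal_bin(timestamps) -> np.ndarray:
    """4-hour diurnal bin index 0–5 (bin 0 = 23:00–03:00)."""
    hours = pd.Series(pd.to_datetime(timestamps)).dt.hour.to_numpy()
    return ((hours + 1) % 24) // 4


def label_days(evidence: pd.DataFrame, proximity_min: int = 1) -> pd.DataFrame:
    """Label each participant-day workday / offday / unknown.

    Precedence: daily-survey answer > garment presence > proximity hits.
    The highest-precedence *available* source decides; a day is a workday iff
    that source indicates work (survey "yes", garment present, or at least
    ``proximity_min`` proximity hits).  All-missing evidence yields
    ``unknown`` with source ``none``.

    Parameters
    ----------
    evidence : DataFrame
        ``evidence`` schema rows, deduplicated per participant-date.
        Missing values (NaN / empty) mean the source produced no data.
    proximity_min : int
        Minimum badge hits that count as work evidence.

    Returns
    -------
    DataFrame with columns participant_id, date, status, source.
    """
    if evidence.duplicated(["participant_id", "date"]).any():
        raise ValueError("evidence must be deduplicated per participant-date")
    ev = evidence.copy()
    survey = ev["survey_at_work"].astype("string").str.lower()
    survey = survey.where(survey.isin(["yes", "no"]))
    garment = ev["garment_present"]
    if garment.dtype != object and str(garment.dtype) != "boolean":
        garment = garment.astype("boolean")
    else:
        garment = garment.map({True: True, False: False, "True": True, "False": False}).astype(
            "boolean"
        )
    prox = pd.to_numeric(ev["proximity_hits"], errors="coerce")

    status = np.full(len(ev), "unknown", dtype=object)
    source = np.full(len(ev), "none", dtype=object)

    has_prox = prox.notna().to_numpy()
    status[has_prox] = np.where(prox[has_prox] >= proximity_min, "workday", "offday")
    source[has_prox] = "proximity"

    has_garment = garment.notna().to_numpy()
    status[has_garment] = np.where(garment[has_garment].to_numpy(dtype=bool), "workday", "offday")
    source[has_garment] = "garment"

    has_survey = survey.notna().to_numpy()
    status[has_survey] = np.where(survey[has_survey] == "yes", "workday", "offday")
    source[has_survey] = "survey"

    return pd.DataFrame(
        {
            "participant_id": ev["participant_id"].to_numpy(),
            "date": pd.to_datetime(ev["date"]).dt.normalize().to_numpy(),
            "status": status,
            "source": source,
        }
    )


def assign_work_status(
    timestamps,
    participant_ids,
    labels: pd.DataFrame,
) -> pd.Series:
    """Work status of the analysis day containing each timestamp.

    Records whose (participant, analysis day) has no label — including any
    record outside the labelled study window — come back ``unknown``.
    """
    df = pd.DataFrame(
        {
            "participant_id": np.asarray(participant_ids),
            "date": analysis_date(timestamps).to_numpy(),
        }
    )
    lab = labels[["participant_id", "date", "status"]].copy()
    lab["date"] = pd.to_datetime(lab["date"]).dt.normalize()
    merged = df.merge(lab, on=["participant_id", "date"], how="left")
    return merged["status"].fillna("unknown")
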