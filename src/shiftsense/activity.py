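"""Heart-rate intensity zones, daily activity summaries, and aggregation.

Minute-level heart rate is expressed as a fraction of the age-predicted
maximum (HRmax = 220 − age) and classified into rest (< 50%), moderate
([50%, 70%)), and vigorous ([70%, 85%)) zones; readings at or above 85% of
HRmax are excluded from the zone ratios (they are rare and dominated by
device artefact).  The walk-activity ratio is the fraction of recorded
minutes with a positive step count.  Daily summaries are computed per
23:00-anchored analysis day, overall and within six 4-hour diurnal bins,
then averaged per participant separately over labelled workdays and
off-days.  Participants need at least ``min_days`` days of a status to be
eligible for that status's aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .day_labeling import DIURNAL_BIN_LABELS, analysis_date, diurnal_bin

__all__ = [
    "ZoneConfig",
    "ZONE_NAMES",
    "hr_max",
    "classify_minute_zone",
    "classify_zones",
    "daily_summaries",
    "daily_activity_summary",
    "aggregate_activity",
    "moderate_redundancy_check",
]

ZONE_NAMES = ("rest", "moderate", "vigorous", "excluded")

_BIN_COLS = [f"walk_bin{i}" for i in range(6)] + [f"rest_bin{i}" for i in range(6)]
_FEATURES = ["rest_ratio", "moderate_ratio", "vigorous_ratio", "walk_ratio", "vigorous_min"]


@dataclass(frozen=True)
class ZoneConfig:
    """Zone cut points (fractions of HRmax) and day-level filters."""

    rest_upper: float = 0.50
    moderate_upper: float = 0.70
    vigorous_upper: float = 0.85
    min_valid_minutes: int = 480
    min_days: int = 5

    def __post_init__(self):
        if not (0 < self.rest_upper < self.moderate_upper < self.vigorous_upper):
            raise ValueError("zone bounds must be strictly increasing in (0, 1)")

    @property
    def cuts(self) -> np.ndarray:
        return np.array([self.rest_upper, self.moderate_upper, self.vigorous_upper])


def hr_max(age) -> float:
    """Age-predicted maximum heart rate, 220 − age (bpm)."""
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < 18) or np.any(age_arr > 100):
        raise ValueError("age must be in [18, 100] years")
    out = 220.0 - age_arr
    return float(out) if np.isscalar(age) or out.ndim == 0 else out


def classify_minute_zone(hr: float, hrmax: float, config: ZoneConfig | None = None) -> str:
    """Classify one minute-averaged heart rate into an intensity zone."""
    if hr <= 0 or hrmax <= 0:
        raise ValueError("heart rate and HRmax must be positive")
    config = config or ZoneConfig()
    return ZONE_NAMES[int(np.searchsorted(config.cuts, hr / hrmax, side="right"))]


def classify_zones(hr, hrmax, config: ZoneConfig | None = None) -> np.ndarray:
    """Vectorised zone codes (0=rest .. 3=excluded); NaN heart rate -> -1."""
    config = config or ZoneConfig()
    hr = np.asarray(hr, dtype=float)
    ratio = hr / np.asarray(hrmax, dtype=float)
    codes = np.searchsorted(config.cuts, ratio, side="right").astype(np.int8)
    codes[~np.isfinite(ratio)] = -1
    return codes


def daily_summaries(
    minutes: pd.DataFrame,
    participants: pd.DataFrame,
    config: ZoneConfig | None = None,
) -> pd.DataFrame:
    """Per participant-day activity summary over analysis days.

    Zone ratios are taken over minutes with a valid (non-excluded-by-absence)
    heart-rate reading; the walk ratio over minutes with a step observation.
    Days with fewer than ``config.min_valid_minutes`` valid heart-rate
    minutes are dropped.

    Returns one row per retained participant-day with overall and per-bin
    ratios (bins in :data:`~shiftsense.day_labeling.DIURNAL_BIN_LABELS`
    order).
    """
    config = config or ZoneConfig()
    if minutes.empty:
        return pd.DataFrame(
            columns=["participant_id", "date", "valid_minutes", "excluded_ratio"]
            + _FEATURES
            + _BIN_COLS
        )
    hrmax_map = dict(
        zip(participants["participant_id"], hr_max(participants["age"].to_numpy()))
    )
    pid_codes, pid_uniques = pd.factorize(minutes["participant_id"], sort=False)
    hrmax_per_row = np.array([hrmax_map[p] for p in pid_uniques])[pid_codes]

    zones = classify_zones(minutes["heart_rate"].to_numpy(), hrmax_per_row, config)
    steps = minutes["steps"].to_numpy(dtype=float)
    has_step = np.isfinite(steps)
    walking = has_step & (steps > 0)
    bins = diurnal_bin(minutes["timestamp"])
    dates = analysis_date(minutes["timestamp"]).to_numpy()

    # dense day-group key: participant x analysis day (filtered to observed
    # days after aggregation)
    day_ord_abs = dates.astype("datetime64[D]").astype(np.int64)
    day_min = day_ord_abs.min()
    day_ord = day_ord_abs - day_min
    span = int(day_ord.max()) + 1
    day_codes = pid_codes.astype(np.int64) * span + day_ord
    n_groups = len(pid_uniques) * span
    group_pid = np.arange(n_groups) // span
    group_date = (np.arange(n_groups) % span + day_min).astype("datetime64[D]")

    def gsum(mask):
        return np.bincount(day_codes, weights=mask, minlength=n_groups)

    has_hr = zones >= 0
    total = np.bincount(day_codes, minlength=n_groups)
    valid = gsum(has_hr & (zones < 3))  # minutes contributing to zone ratios
    excluded = gsum(zones == 3)
    rest = gsum(zones == 0)
    moderate = gsum(zones == 1)
    vigorous = gsum(zones == 2)
    step_obs = gsum(has_step)
    walk = gsum(walking)

    with np.errstate(invalid="ignore", divide="ignore"):
        out = pd.DataFrame(
            {
                "participant_id": np.asarray(pid_uniques)[group_pid],
                "date": pd.to_datetime(group_date),
                "valid_minutes": valid,
                "rest_ratio": rest / valid,
                "moderate_ratio": moderate / valid,
                "vigorous_ratio": vigorous / valid,
                "excluded_ratio": excluded / np.maximum(valid + excluded, 1),
                "vigorous_min": vigorous,
                "walk_ratio": np.where(step_obs > 0, walk / np.maximum(step_obs, 1), np.nan),
            }
        )
    key = day_codes * 6 + bins
    nk = n_groups * 6

    def bsum(mask):
        return np.bincount(key, weights=mask, minlength=nk).reshape(n_groups, 6)

    bin_walk = bsum(walking)
    bin_step = bsum(has_step)
    bin_rest = bsum(zones == 0)
    bin_valid = bsum(has_hr & (zones < 3))
    for b in range(6):
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"walk_bin{b}"] = np.where(
                bin_step[:, b] > 0, bin_walk[:, b] / np.maximum(bin_step[:, b], 1), np.nan
            )
            out[f"rest_bin{b}"] = np.where(
                bin_valid[:, b] > 0, bin_rest[:, b] / np.maximum(bin_valid[:, b], 1), np.nan
            )

    out = out[(total > 0) & (out["valid_minutes"] >= config.min_valid_minutes)].reset_index(
        drop=True
    )
    return out


def daily_activity_summary(
    day_minutes: pd.DataFrame,
    hrmax: float,
    config: ZoneConfig | None = None,
) -> dict | None:
    """Summary for a single participant's single analysis day (or ``None``).

    Thin per-day wrapper over :func:`daily_summaries`; returns ``None`` when
    the day has fewer valid heart-rate minutes than the configured floor.
    """
    config = config or ZoneConfig()
    if day_minutes.empty:
        return None
    dates = analysis_date(day_minutes["timestamp"])
    if dates.nunique() > 1:
        raise ValueError("minutes span more than one analysis day")
    pid = day_minutes["participant_id"].iloc[0]
    participants = pd.DataFrame({"participant_id": [pid], "age": [220.0 - hrmax]})
    rows = daily_summaries(day_minutes, participants, config)
    if rows.empty:
        return None
    return rows.iloc[0].to_dict()


def aggregate_activity(
    summaries: pd.DataFrame,
    labels: pd.DataFrame,
    config: ZoneConfig | None = None,
) -> pd.DataFrame:
    """Per-participant activity profile: status-wise means + eligibility.

    Unknown-status days are ignored.  A participant is eligible for a status
    when they contribute at least ``config.min_days`` labelled days of it.

    Returns one row per participant with columns ``<feature>_workday`` /
    ``<feature>_offday``, day counts, and eligibility flags.
    """
    config = config or ZoneConfig()
    lab = labels[["participant_id", "date", "status"]].copy()
    lab["date"] = pd.to_datetime(lab["date"]).dt.normalize()
    df = summaries.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    df = df.merge(lab, on=["participant_id", "date"], how="left")
    df["status"] = df["status"].fillna("unknown")
    df = df[df["status"].isin(["workday", "offday"])]

    value_cols = _FEATURES + _BIN_COLS
    grouped = df.groupby(["participant_id", "status"], sort=True)
    means = grouped[value_cols].mean()
    counts = grouped.size().rename("n_days")
    wide = means.join(counts).unstack("status")
    wide.columns = [f"{feat}_{status}" for feat, status in wide.columns]

    out = wide.reset_index()
    for status in ("workday", "offday"):
        n_col = f"n_days_{status}"
        if n_col not in out:
            out[n_col] = 0
        out[n_col] = out[n_col].fillna(0).astype(int)
        out[f"eligible_{status}"] = out[n_col] >= config.min_days
        for feat in value_cols:
            col = f"{feat}_{status}"
            if col not in out:
                out[col] = np.nan
    return out


def moderate_redundancy_check(
    profiles: pd.DataFrame, threshold: float = -0.7
) -> dict[str, dict]:
    """Spearman correlation between moderate and rest ratios, per status.

    Flags a status as redundant when the moderate-activity ratio is strongly
    anti-correlated with the rest-activity ratio (ρ below ``threshold``),
    the condition under which the moderate ratio carries no additional
    signal and is dropped from between-group models.
    """
    out = {}
    for status in ("workday", "offday"):
        sub = profiles[profiles[f"eligible_{status}"]] if f"eligible_{status}" in profiles else profiles
        pair = sub[[f"moderate_ratio_{status}", f"rest_ratio_{status}"]].dropna()
        if len(pair) < 3:
            raise ValueError(f"need at least 3 eligible profiles for status {status!r}")
        rho, p = sps.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
        out[status] = {"rho": float(rho), "p": float(p), "flagged": bool(rho < threshold)}
    return out
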