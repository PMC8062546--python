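"""Data model, delimited-text schemas, record validation, and survey scoring.

Every table in the pipeline is a plain-text CSV with an explicit header,
UTF-8, ISO-8601 timestamps at minute resolution (naive local wall clock),
and empty strings for missing values.  The canonical in-memory container is
a :class:`pandas.DataFrame` with the column sets declared in ``SCHEMAS``.

Survey instruments
------------------
Baseline instruments are scored from raw item responses:

* STAI — 20 items, each 1–4 (reverse-keyed items pre-coded), summed to 20–80.
* PANAS — 10 positive-affect and 10 negative-affect items, each 1–5,
  summed per subscale to 10–50.
* SWLS — 5 items rated 1–7, scored as the item mean (1–7).
* BFI-2 — per-trait item mean, 1–5.
* PSQI — seven component scores 0–3, summed to 0–21 (components are stored
  directly; the 19-item-to-component mapping is upstream of this package).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMAS",
    "BFI_TRAITS",
    "CohortBundle",
    "SchemaError",
    "InstrumentError",
    "read_table",
    "write_table",
    "read_minutes",
    "write_minutes",
    "read_bundle",
    "write_bundle",
    "score_stai",
    "score_panas",
    "score_swls",
    "score_bfi",
    "score_psqi",
    "score_baseline",
    "validate_bundle",
]

BFI_TRAITS = (
    "neuroticism",
    "conscientiousness",
    "extraversion",
    "agreeableness",
    "openness",
)

#: table name -> (columns, timestamp columns)
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "participants": (
        ("participant_id", "shift", "age", "gender", "degree", "native_english"),
        (),
    ),
    "minutes": (("participant_id", "timestamp", "heart_rate", "steps"), ("timestamp",)),
    "sleep": (
        ("participant_id", "onset", "offset", "duration_min", "efficiency_pct"),
        ("onset", "offset"),
    ),
    "ema": (
        ("participant_id", "delivery", "stress", "anxiety", "pa_short", "na_short"),
        ("delivery",),
    ),
    "baseline": (
        ("participant_id", "stai", "pa", "na", "swls")
        + tuple(f"bfi_{t}" for t in BFI_TRAITS)
        + ("psqi",),
        (),
    ),
    "evidence": (
        ("participant_id", "date", "proximity_hits", "garment_present", "survey_at_work"),
        (),
    ),
}

HEART_RATE_RANGE = (30.0, 220.0)


class SchemaError(ValueError):
    """A file does not match its declared column schema."""


class InstrumentError(ValueError):
    """A survey instrument received the wrong items or out-of-range values."""


@dataclass
class CohortBundle:
    """All tables for one cohort, plus optional simulator ground truth.

    ``schedules`` (participant_id, date, shift_start, shift_end) exists only
    for simulated cohorts; real ingests carry work evidence instead.
    """

    participants: pd.DataFrame
    minutes: pd.DataFrame
    sleep: pd.DataFrame
    ema: pd.DataFrame
    baseline: pd.DataFrame
    evidence: pd.DataFrame
    schedules: pd.DataFrame | None = None
    ground_truth: object | None = None
    start_date: pd.Timestamp | None = None
    n_days: int | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "participants": self.participants,
            "minutes": self.minutes,
            "sleep": self.sleep,
            "ema": self.ema,
            "baseline": self.baseline,
            "evidence": self.evidence,
        }


# ---------------------------------------------------------------------------
# Generic table reading / writing


def _check_header(df: pd.DataFrame, name: str) -> None:
    cols, _ = SCHEMAS[name]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required columns {missing}")


def read_table(path, name: str) -> pd.DataFrame:
    """Read one schema table; raises :class:`SchemaError` on a bad header."""
    cols, ts_cols = SCHEMAS[name]
    df = pd.read_csv(path)
    _check_header(df, name)
    df = df[list(cols)]
    for c in ts_cols:
        df[c] = pd.to_datetime(df[c], format="ISO8601")
    if name == "evidence":
        df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    return df


def write_table(df: pd.DataFrame, path, name: str) -> None:
    cols, _ = SCHEMAS[name]
    _check_header(df, name)
    df[list(cols)].to_csv(path, index=False)


def read_minutes(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a minute-stream CSV.

    Returns ``(records, rejects)``.  Rows with unparseable timestamps or a
    heart rate outside [30, 220] are moved to the rejects report with a
    ``reject_reason`` column.  Duplicate participant-minutes are collapsed by
    averaging heart rate and summing steps (with a warning).
    """
    cols, _ = SCHEMAS["minutes"]
    df = pd.read_csv(path)
    _check_header(df, "minutes")
    df = df[list(cols)]
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    reason = pd.Series(pd.NA, index=df.index, dtype="string")
    reason[ts.isna()] = "unparseable timestamp"
    hr = pd.to_numeric(df["heart_rate"], errors="coerce")
    bad_hr = hr.notna() & ((hr < HEART_RATE_RANGE[0]) | (hr > HEART_RATE_RANGE[1]))
    reason[bad_hr & reason.isna()] = "heart rate out of range"
    rejects = df[reason.notna()].assign(reject_reason=reason[reason.notna()])
    df = df[reason.isna()].assign(timestamp=ts[reason.isna()], heart_rate=hr[reason.isna()])
    df["steps"] = pd.to_numeric(df["steps"], errors="coerce")

    dup = df.duplicated(["participant_id", "timestamp"], keep=False)
    if dup.any():
        warnings.warn(
            f"collapsed {int(dup.sum())} duplicate participant-minute rows",
            stacklevel=2,
        )
        df = (
            df.groupby(["participant_id", "timestamp"], as_index=False, sort=False)
            .agg(heart_rate=("heart_rate", "mean"), steps=("steps", "sum"))
        )[list(cols)]
    return df.reset_index(drop=True), rejects.reset_index(drop=True)


def write_minutes(df: pd.DataFrame, path) -> None:
    write_table(df, path, "minutes")


def read_bundle(directory) -> CohortBundle:
    """Read the six-table cohort directory written by :func:`write_bundle`."""
    from pathlib import Path

    d = Path(directory)
    minutes, _ = read_minutes(d / "minutes.csv")
    return CohortBundle(
        participants=read_table(d / "participants.csv", "participants"),
        minutes=minutes,
        sleep=read_table(d / "sleep.csv", "sleep"),
        ema=read_table(d / "ema.csv", "ema"),
        baseline=read_table(d / "baseline.csv", "baseline"),
        evidence=read_table(d / "evidence.csv", "evidence"),
    )


def write_bundle(bundle: CohortBundle, directory) -> None:
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables().items():
        write_table(df, d / f"{name}.csv", name)


# ---------------------------------------------------------------------------
# Survey scoring


def _check_items(items, n: int, lo: float, hi: float, instrument: str) -> np.ndarray:
    arr = np.asarray(items, dtype=float)
    if arr.shape != (n,):
        raise InstrumentError(f"{instrument}: expected {n} items, got {arr.shape}")
    if np.any(arr < lo) or np.any(arr > hi) or np.any(~np.isfinite(arr)):
        raise InstrumentError(f"{instrument}: item responses must be in [{lo}, {hi}]")
    return arr


def score_stai(items) -> float:
    """Sum of 20 anxiety items (each 1–4, reverse-keyed items pre-coded)."""
    return float(_check_items(items, 20, 1, 4, "STAI").sum())


def score_panas(pa_items, na_items) -> tuple[float, float]:
    """Positive- and negative-affect sums from 10 items each, 1–5."""
    pa = _check_items(pa_items, 10, 1, 5, "PANAS-PA").sum()
    na = _check_items(na_items, 10, 1, 5, "PANAS-NA").sum()
    return float(pa), float(na)


def score_swls(items) -> float:
    """Mean of five life-satisfaction items rated 1–7."""
    return float(_check_items(items, 5, 1, 7, "SWLS").mean())


def score_bfi(trait_items: dict) -> dict[str, float]:
    """Per-trait item means (1–5) for the five BFI-2 traits."""
    unknown = set(trait_items) - set(BFI_TRAITS)
    if unknown or set(trait_items) != set(BFI_TRAITS):
        raise InstrumentError(f"BFI-2: expected traits {BFI_TRAITS}, got {sorted(trait_items)}")
    out = {}
    for trait, items in trait_items.items():
        arr = np.asarray(items, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise InstrumentError(f"BFI-2 {trait}: need a non-empty item vector")
        if np.any(arr < 1) or np.any(arr > 5):
            raise InstrumentError(f"BFI-2 {trait}: item responses must be in [1, 5]")
        out[trait] = float(arr.mean())
    return out


def score_psqi(components) -> float:
    """Sum of the seven sleep-quality component scores (each 0–3)."""
    return float(_check_items(components, 7, 0, 3, "PSQI").sum())


def score_baseline(
    participant_id: str,
    stai_items,
    panas_pa_items,
    panas_na_items,
    swls_items,
    bfi_trait_items: dict,
    psqi_components,
) -> dict:
    """Score one participant's full baseline battery into a ``baseline`` row."""
    pa, na = score_panas(panas_pa_items, panas_na_items)
    row = {
        "participant_id": participant_id,
        "stai": score_stai(stai_items),
        "pa": pa,
        "na": na,
        "swls": score_swls(swls_items),
        "psqi": score_psqi(psqi_components),
    }
    for trait, value in score_bfi(bfi_trait_items).items():
        row[f"bfi_{trait}"] = value
    return row


# ---------------------------------------------------------------------------
# Bundle validation


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)
    coverage: pd.DataFrame | None = None

    @property
    def n_violations(self) -> int:
        return len(self.violations)


def validate_bundle(
    bundle: CohortBundle,
    study_start: pd.Timestamp | None = None,
    study_days: int | None = None,
) -> ValidationReport:
    """Cross-reference checks plus per-participant recording coverage.

    Violations collected (never raised): streams/sessions/EMAs referencing an
    unknown participant, and sleep sessions starting outside the study window
    when the window is known.  Coverage counts calendar days with at least one
    minute record, as a percentage of the study duration.
    """
    report = ValidationReport()
    known = set(bundle.participants["participant_id"])
    for name in ("minutes", "sleep", "ema", "baseline", "evidence"):
        df = getattr(bundle, name)
        orphans = sorted(set(df["participant_id"]) - known)
        for pid in orphans:
            report.violations.append((name, pid, "unknown participant"))

    start = study_start if study_start is not None else bundle.start_date
    n_days = study_days if study_days is not None else bundle.n_days
    if start is not None and n_days is not None and len(bundle.sleep):
        # the first analysis day opens at 23:00 the evening before the study start
        lo = start - pd.Timedelta(hours=1)
        end = start + pd.Timedelta(days=n_days)
        outside = bundle.sleep[(bundle.sleep["onset"] < lo) | (bundle.sleep["onset"] >= end)]
        for _, row in outside.iterrows():
            report.violations.append(("sleep", row["participant_id"], "onset outside study window"))

    if len(bundle.minutes):
        days = (
            bundle.minutes.assign(day=bundle.minutes["timestamp"].dt.normalize())
            .groupby("participant_id", sort=True)["day"]
            .nunique()
            .rename("days_recorded")
            .reset_index()
        )
    else:
        days = pd.DataFrame({"participant_id": sorted(known), "days_recorded": 0})
    if n_days:
        days["days_total"] = n_days
        days["coverage_pct"] = 100.0 * days["days_recorded"] / n_days
    report.coverage = days
    return report
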