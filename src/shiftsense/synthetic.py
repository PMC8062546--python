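"""Synthetic shift-work cohort generator with recorded ground truth.

Emulates a 10-week wearable study of hospital nurses on fixed 12-hour
shifts (day 07:00–19:00, night 19:00–07:00): minute-level heart rate and
step streams, device-detected sleep sessions, daily momentary surveys
(EMAs), baseline questionnaires, and the three per-day work-evidence
sources the labelling stage consumes.  Every distributional choice is
recorded in a :class:`GroundTruth` object embedded in the returned bundle,
so downstream feature extraction and statistics can be tested as
parameter-recovery problems.

Generative model, in brief
--------------------------
* A participant's scheduled shifts mark ground-truth workdays; for night
  nurses a shift starting on date *d* makes both *d* and *d+1* workdays
  (the 23:00-anchored windows of both contain worked hours).
* Minute heart rate: each minute draws an intensity zone from the
  participant's shift × status cell occupancy (rest propensity gets a
  participant-level offset and a diurnal-bin offset); rest minutes follow a
  24 h sinusoidal baseline, higher zones draw uniformly within their band.
  Steps are positive exactly on walking minutes (Bernoulli per minute with
  participant and diurnal-bin structure).
* Sleep: one candidate session per date; onset clock time is the cell mean
  plus a participant chronotype offset plus day-to-day noise, duration and
  efficiency are Gaussian; the off-day cell mean is positioned so the
  implied mid-sleep gap equals the configured social jet lag.
* EMAs follow a linear model with participant random intercepts and
  shift / work-status / interaction fixed effects, rounded and clipped to
  the instrument scale.
* Missingness: whole-day wear dropout, i.i.d. minute dropout, per-day
  sleep-recording and EMA-response propensities, and occasional days with
  no work evidence at all.

Determinism: one root seed; per-participant child streams are spawned from
it, so adding a participant never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .io import CohortBundle

__all__ = [
    "ActivityCell",
    "SleepCell",
    "EmaEffects",
    "GroundTruth",
    "CohortConfig",
    "ConfigError",
    "default_ground_truth",
    "null_ground_truth",
    "schedule_day_status",
    "generate_minute_stream",
    "generate_sleep_sessions",
    "generate_ema_responses",
    "generate_evidence",
    "generate_cohort",
]

MINUTES_PER_DAY = 1440

DAY_SHIFT_HOURS = (7, 19)  # 07:00 -> 19:00
NIGHT_SHIFT_HOURS = (19, 7)  # 19:00 -> 07:00 next day

EMA_SLOTS = {"day": (6, 12, 18), "night": (18, 0, 6)}


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class ActivityCell:
    """Zone occupancy and walking targets for one shift × status cell."""

    rest_ratio: float  # of valid (non-excluded) HR minutes
    vigorous_min: float  # expected vigorous minutes per recorded day
    walk_ratio: float  # fraction of recorded minutes with steps > 0
    excluded_frac: float = 0.004  # HR >= 85% HRmax, dropped from ratios


@dataclass(frozen=True)
class SleepCell:
    """Sleep-timing distribution for one shift × status cell."""

    onset_clock_min: float  # mean onset clock time, minutes past midnight
    onset_sd: float  # day-to-day onset SD (min)
    duration_mean: float  # device sleep duration (min)
    duration_sd: float
    efficiency_mean: float  # percent
    efficiency_sd: float


@dataclass(frozen=True)
class EmaEffects:
    """Linear-model parameters for one EMA outcome.

    ``value = intercept + shift_night*[night] + workday*[workday]
    + interaction*[night & workday] + participant intercept + noise``,
    rounded to the nearest integer and clipped to ``(lo, hi)``.
    """

    intercept: float
    shift_night: float
    workday: float
    interaction: float
    intercept_sd: float
    resid_sd: float
    lo: int
    hi: int


@dataclass(frozen=True)
class BaselineGroup:
    """Mean (SD) of each baseline instrument for one shift group."""

    age: tuple[float, float]
    stai: tuple[float, float]
    pa: tuple[float, float]
    na: tuple[float, float]
    swls: tuple[float, float]
    bfi: dict[str, tuple[float, float]]
    psqi: tuple[float, float]
    n_female: int
    n_graduate: int
    n_native_english: int


@dataclass(frozen=True)
class GroundTruth:
    """Every generator parameter, keyed by (shift, status) where relevant."""

    activity: dict[tuple[str, str], ActivityCell]
    walk_bin_offsets: dict[tuple[str, str], tuple[float, ...]]
    sleep: dict[tuple[str, str], SleepCell]
    jet_lag: dict[str, float]  # shift -> configured |MSW - MSF| (min)
    chronotype_sd: float  # between-participant onset offset SD (min)
    jet_lag_sd: float  # between-participant jet-lag SD (min)
    rest_between_sd: float  # between-participant rest-propensity SD
    walk_between_sd: float
    vigorous_shape: float  # gamma shape of the participant vigorous multiplier
    ema: dict[str, EmaEffects]
    baseline: dict[str, BaselineGroup]
    swls_walk_beta: float  # std-β of walk propensity on SWLS (night reference)
    swls_walk_interaction: float  # additional std-β for day shift
    hr_mesor_frac: float = 0.40  # resting HR sinusoid, as fractions of HRmax
    hr_amplitude_frac: float = 0.04
    hr_acrophase_hour: dict[str, float] = field(
        default_factory=lambda: {"day": 15.0, "night": 3.0}
    )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["activity"] = {f"{k[0]}/{k[1]}": v for k, v in d["activity"].items()}
        d["walk_bin_offsets"] = {f"{k[0]}/{k[1]}": list(v) for k, v in d["walk_bin_offsets"].items()}
        d["sleep"] = {f"{k[0]}/{k[1]}": v for k, v in d["sleep"].items()}
        return d


def _offday_sleep_cell(
    workday: SleepCell,
    jet_lag: float,
    direction: int,
    onset_sd: float,
    duration_mean: float,
    duration_sd: float,
    efficiency_mean: float,
    efficiency_sd: float,
) -> SleepCell:
    """Off-day cell whose implied mid-sleep sits ``jet_lag`` minutes from the
    workday cell's (``direction`` +1 = later on off-days, −1 = earlier)."""
    interval_wd = workday.duration_mean / (workday.efficiency_mean / 100.0)
    mid_wd = workday.onset_clock_min + interval_wd / 2.0
    mid_off = mid_wd + direction * jet_lag
    interval_off = duration_mean / (efficiency_mean / 100.0)
    onset_off = (mid_off - interval_off / 2.0) % MINUTES_PER_DAY
    return SleepCell(
        onset_clock_min=onset_off,
        onset_sd=onset_sd,
        duration_mean=duration_mean,
        duration_sd=duration_sd,
        efficiency_mean=efficiency_mean,
        efficiency_sd=efficiency_sd,
    )


def default_ground_truth(
    jet_lag_day: float = 52.5, jet_lag_night: float = 425.0
) -> GroundTruth:
    """Study-conditions ground truth.

    Activity-cell occupancies and sleep durations/efficiencies sit at the
    published group-level estimates for this population; night-shift workday
    sleep is anchored at the observed post-shift onset (09:52) and each
    off-day cell is placed so the implied mid-sleep gap equals the
    configured social jet lag (day nurses drift later on off-days, night
    nurses earlier — back toward a diurnal schedule).
    """
    day_wd = SleepCell(1430.0, 45.0, 410.4, 60.0, 92.3, 2.5)
    night_wd = SleepCell(592.0, 40.0, 330.4, 45.0, 93.8, 2.5)
    sleep = {
        ("day", "workday"): day_wd,
        ("day", "offday"): _offday_sleep_cell(day_wd, jet_lag_day, +1, 60.0, 437.0, 65.0, 91.8, 2.8),
        ("night", "workday"): night_wd,
        ("night", "offday"): _offday_sleep_cell(
            night_wd, jet_lag_night, -1, 110.0, 408.2, 70.0, 93.7, 2.8
        ),
    }
    activity = {
        ("day", "workday"): ActivityCell(0.730, 4.1, 0.313),
        ("day", "offday"): ActivityCell(0.765, 7.5, 0.253),
        ("night", "workday"): ActivityCell(0.824, 3.2, 0.276),
        ("night", "offday"): ActivityCell(0.835, 5.3, 0.213),
    }
    walk_bin_offsets = {
        ("day", "workday"): (-0.25, -0.18, 0.18, 0.15, 0.15, -0.05),
        ("night", "workday"): (0.15, 0.10, -0.18, -0.20, -0.10, 0.23),
        ("day", "offday"): (-0.22, -0.20, 0.15, 0.15, 0.17, -0.05),
        ("night", "offday"): (-0.10, -0.15, 0.08, 0.06, 0.08, 0.03),
    }
    ema = {
        "stress": EmaEffects(2.0, 0.0, 0.35, 0.0, 0.5, 0.9, 1, 5),
        "anxiety": EmaEffects(1.8, 0.0, 0.25, 0.0, 0.5, 0.9, 1, 5),
        "pa_short": EmaEffects(14.0, 0.0, -0.5, 0.0, 2.5, 3.5, 5, 25),
        "na_short": EmaEffects(8.5, 0.5, 0.0, 0.33, 2.0, 3.0, 5, 25),
    }
    baseline = {
        "day": BaselineGroup(
            age=(39.4, 8.9),
            stai=(32.9, 7.6),
            pa=(37.0, 6.4),
            na=(14.9, 3.7),
            swls=(5.4, 1.1),
            bfi={
                "neuroticism": (2.1, 0.7),
                "conscientiousness": (4.2, 0.6),
                "extraversion": (3.6, 0.7),
                "agreeableness": (4.2, 0.5),
                "openness": (3.7, 0.6),
            },
            psqi=(7.0, 2.0),
            n_female=51,
            n_graduate=10,
            n_native_english=39,
        ),
        "night": BaselineGroup(
            age=(35.2, 7.5),
            stai=(35.4, 9.1),
            pa=(37.3, 6.6),
            na=(16.5, 4.9),
            swls=(4.8, 1.4),
            bfi={
                "neuroticism": (2.3, 0.7),
                "conscientiousness": (4.1, 0.6),
                "extraversion": (3.5, 0.8),
                "agreeableness": (4.2, 0.4),
                "openness": (3.9, 0.6),
            },
            psqi=(8.4, 2.5),
            n_female=31,
            n_graduate=11,
            n_native_english=25,
        ),
    }
    return GroundTruth(
        activity=activity,
        walk_bin_offsets=walk_bin_offsets,
        sleep=sleep,
        jet_lag={"day": jet_lag_day, "night": jet_lag_night},
        chronotype_sd=25.0,
        jet_lag_sd=25.0,
        rest_between_sd=0.12,
        walk_between_sd=0.07,
        vigorous_shape=2.0,
        ema=ema,
        baseline=baseline,
        swls_walk_beta=0.26,
        swls_walk_interaction=-0.62,
    )


def null_ground_truth() -> GroundTruth:
    """Ground truth with every shift effect removed (for calibration tests).

    Both shift groups share the day-shift cells, the same jet lag, equal
    baseline means, and zero EMA shift / interaction effects; only work
    status and individual noise remain.
    """
    gt = default_ground_truth(jet_lag_day=52.5, jet_lag_night=52.5)
    sleep = {
        ("day", "workday"): gt.sleep[("day", "workday")],
        ("day", "offday"): gt.sleep[("day", "offday")],
        ("night", "workday"): gt.sleep[("day", "workday")],
        ("night", "offday"): gt.sleep[("day", "offday")],
    }
    activity = {
        (shift, status): gt.activity[("day", status)]
        for shift in ("day", "night")
        for status in ("workday", "offday")
    }
    walk_bins = {
        (shift, status): gt.walk_bin_offsets[("day", status)]
        for shift in ("day", "night")
        for status in ("workday", "offday")
    }
    ema = {
        name: replace(eff, shift_night=0.0, interaction=0.0)
        for name, eff in gt.ema.items()
    }
    baseline = {"day": gt.baseline["day"], "night": gt.baseline["day"]}
    return replace(
        gt,
        sleep=sleep,
        activity=activity,
        walk_bin_offsets=walk_bins,
        ema=ema,
        baseline=baseline,
        jet_lag={"day": 52.5, "night": 52.5},
        swls_walk_interaction=0.0,
        hr_acrophase_hour={"day": 15.0, "night": 15.0},
    )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, schedule pattern, seed, and missingness rates."""

    n_day: int = 69
    n_night: int = 44
    weeks: int = 10
    shifts_per_week: int = 3
    seed: int = 0
    start_date: str = "2018-03-05"
    minute_missing: float = 0.05  # i.i.d. minute dropout within worn days
    day_missing: float = 0.30  # whole-day wear dropout
    sleep_day_prob: float = 0.65  # P(a sleep session is recorded on a date)
    ema_response_prob: float = 0.80
    evidence_missing: float = 0.08  # P(no work evidence at all for a date)
    survey_response_prob: float = 0.70
    garment_wear_prob: float = 0.92
    truth: GroundTruth = field(default_factory=default_ground_truth)

    @property
    def n_days(self) -> int:
        return self.weeks * 7

    def validate(self) -> None:
        if self.n_day < 0 or self.n_night < 0:
            raise ConfigError("participant counts must be non-negative")
        if self.weeks < 0:
            raise ConfigError("weeks must be non-negative")
        if not 0 <= self.shifts_per_week <= 7:
            raise ConfigError("shifts_per_week must be in [0, 7]")
        for name in (
            "minute_missing",
            "day_missing",
            "sleep_day_prob",
            "ema_response_prob",
            "evidence_missing",
            "survey_response_prob",
            "garment_wear_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# Schedules and ground-truth day status


def _scheduled_shift_dates(rng: np.random.Generator, config: CohortConfig) -> np.ndarray:
    """Day indices (0-based) of scheduled shifts across the study."""
    days = []
    for week in range(config.weeks):
        chosen = rng.choice(7, size=config.shifts_per_week, replace=False)
        days.extend(week * 7 + int(d) for d in sorted(chosen))
    return np.array(days, dtype=int)


def schedule_day_status(shift_days: np.ndarray, shift: str, n_days: int) -> np.ndarray:
    """Ground-truth workday flags per analysis day.

    A day nurse's shift (07:00–19:00 on day *d*) falls inside day *d*'s
    window only.  A night nurse's shift (19:00 *d* → 07:00 *d+1*) overlaps
    the windows of both *d* and *d+1*.
    """
    work = np.zeros(n_days, dtype=bool)
    for d in shift_days:
        if 0 <= d < n_days:
            work[d] = True
        if shift == "night" and 0 <= d + 1 < n_days:
            work[d + 1] = True
    return work


# ---------------------------------------------------------------------------
# Stream generators (one participant at a time, vectorised over minutes)


def _minute_bin(tod_minutes: np.ndarray) -> np.ndarray:
    return (((tod_minutes // 60) + 1) % 24) // 4


def generate_minute_stream(
    participant: dict,
    workday: np.ndarray,
    truth: GroundTruth,
    rng: np.random.Generator,
    config: CohortConfig,
    walk_offset: float | None = None,
) -> pd.DataFrame:
    """Minute-level heart-rate / step stream for one participant.

    ``workday`` is the boolean ground-truth status per analysis day; its
    length sets the study duration.  ``walk_offset`` optionally injects a
    pre-drawn participant walking propensity (the cohort assembler shares
    it with the baseline-survey coupling).  Returns ``minutes``-schema rows.
    """
    n_days = len(workday)
    if n_days == 0:
        return pd.DataFrame(columns=["participant_id", "timestamp", "heart_rate", "steps"])
    shift = participant["shift"]
    hrmax = 220.0 - float(participant["age"])
    n = n_days * MINUTES_PER_DAY
    t = np.arange(n, dtype=np.int64)
    tod = t % MINUTES_PER_DAY
    aday = np.minimum((t + 60) // MINUTES_PER_DAY, n_days - 1)
    status_idx = (~workday[aday]).astype(np.int8)  # 0 = workday, 1 = offday
    bins = _minute_bin(tod)

    # participant-level latent propensities (shared across statuses)
    rest_off = rng.normal(0.0, truth.rest_between_sd)
    walk_off = (
        walk_offset if walk_offset is not None else rng.normal(0.0, truth.walk_between_sd)
    )
    vig_mult = rng.gamma(truth.vigorous_shape, 1.0 / truth.vigorous_shape)

    expected_minutes = max(MINUTES_PER_DAY * (1.0 - config.minute_missing), 1.0)
    statuses = ("workday", "offday")
    p_rest_tab = np.empty((2, 6))
    p_walk_tab = np.empty((2, 6))
    p_vig = np.empty(2)
    p_excl = np.empty(2)
    for si, status in enumerate(statuses):
        cell = truth.activity[(shift, status)]
        wb = np.asarray(truth.walk_bin_offsets[(shift, status)])
        p_excl[si] = cell.excluded_frac
        p_vig[si] = min(cell.vigorous_min * vig_mult / expected_minutes, 0.05)
        base_rest = np.clip(cell.rest_ratio + rest_off, 0.02, 0.98)
        p_rest_tab[si] = np.clip(
            (base_rest - 0.6 * wb) * (1.0 - p_excl[si]) - p_vig[si] / 2,
            0.01,
            1.0 - p_vig[si] - p_excl[si] - 0.01,
        )
        p_walk_tab[si] = np.clip(cell.walk_ratio + walk_off + wb, 0.01, 0.95)

    pr = p_rest_tab[status_idx, bins]
    pv = p_vig[status_idx]
    pe = p_excl[status_idx]
    u = rng.random(n)
    # zone codes: [0, pr) rest | [pr, 1-pv-pe) moderate | vigorous | excluded
    zones = (u >= pr).astype(np.int8) + (u >= 1.0 - pv - pe) + (u >= 1.0 - pe)

    hr = np.empty(n)
    acro = truth.hr_acrophase_hour[shift] * 60.0
    baseline = hrmax * (
        truth.hr_mesor_frac
        + truth.hr_amplitude_frac * np.cos(2 * np.pi * (tod - acro) / MINUTES_PER_DAY)
    )
    rest_mask = zones == 0
    hr[rest_mask] = np.clip(
        baseline[rest_mask] + rng.normal(0.0, 2.0, rest_mask.sum()), 35.0, 0.497 * hrmax
    )
    for code, lo, hi in ((1, 0.50, 0.6999), (2, 0.70, 0.8499), (3, 0.85, 0.97)):
        mask = zones == code
        hr[mask] = hrmax * rng.uniform(lo, hi, mask.sum())
    hr = np.round(np.clip(hr, 30.0, 220.0), 1)

    walking = rng.random(n) < p_walk_tab[status_idx, bins]
    steps = np.where(walking, 1 + rng.poisson(54.0, n), 0)

    worn_day = rng.random(n_days) >= config.day_missing
    keep = worn_day[t // MINUTES_PER_DAY]
    if config.minute_missing > 0:
        keep &= rng.random(n) >= config.minute_missing
    t, hr, steps = t[keep], hr[keep], steps[keep]
    ts = pd.Timestamp(config.start_date) + pd.to_timedelta(t, unit="m")
    return pd.DataFrame(
        {
            "participant_id": participant["participant_id"],
            "timestamp": ts,
            "heart_rate": hr,
            "steps": steps.astype(np.int64),
        }
    )


def generate_sleep_sessions(
    participant: dict,
    workday: np.ndarray,
    truth: GroundTruth,
    rng: np.random.Generator,
    config: CohortConfig,
) -> pd.DataFrame:
    """Device sleep sessions for one participant (≤ one per analysis day).

    Onset clock time = cell mean + chronotype offset (+ jet-lag deviation on
    off-days) + day-to-day noise, expressed inside the 23:00-anchored window
    of the session's date.  ``duration ≤ offset − onset`` always, with
    efficiency = duration / interval.
    """
    n_days = len(workday)
    cols = ["participant_id", "onset", "offset", "duration_min", "efficiency_pct"]
    if n_days == 0:
        return pd.DataFrame(columns=cols)
    shift = participant["shift"]
    chronotype = rng.normal(0.0, truth.chronotype_sd)
    jet_dev = rng.normal(0.0, truth.jet_lag_sd)
    recorded = rng.random(n_days) < config.sleep_day_prob

    onset_list, offset_list = [], []
    durations, effs = [], []
    start = pd.Timestamp(config.start_date)
    direction = +1 if shift == "day" else -1
    for d in np.nonzero(recorded)[0]:
        status = "workday" if workday[d] else "offday"
        cell = truth.sleep[(shift, status)]
        onset_clock = cell.onset_clock_min + chronotype + rng.normal(0.0, cell.onset_sd)
        if status == "offday":
            onset_clock += direction * jet_dev
        duration = float(np.clip(rng.normal(cell.duration_mean, cell.duration_sd), 120.0, 720.0))
        eff = float(np.clip(rng.normal(cell.efficiency_mean, cell.efficiency_sd), 50.0, 99.5))
        interval = duration / (eff / 100.0)
        # window coordinate: minutes after 23:00 of date d-1
        win = (onset_clock + 60.0) % MINUTES_PER_DAY
        onset_ts = start + pd.Timedelta(minutes=(d - 1) * MINUTES_PER_DAY + 23 * 60 + round(win))
        onset_list.append(onset_ts)
        offset_list.append(onset_ts + pd.Timedelta(minutes=round(interval)))
        durations.append(round(duration, 1))
        effs.append(round(eff, 1))
    return pd.DataFrame(
        {
            "participant_id": participant["participant_id"],
            "onset": onset_list,
            "offset": offset_list,
            "duration_min": durations,
            "efficiency_pct": effs,
        },
        columns=cols,
    )


def generate_ema_responses(
    participant: dict,
    workday: np.ndarray,
    truth: GroundTruth,
    rng: np.random.Generator,
    config: CohortConfig,
) -> pd.DataFrame:
    """Daily EMA responses at shift-appropriate delivery slots."""
    n_days = len(workday)
    cols = ["participant_id", "delivery", "stress", "anxiety", "pa_short", "na_short"]
    if n_days == 0:
        return pd.DataFrame(columns=cols)
    shift = participant["shift"]
    slots = EMA_SLOTS[shift]
    is_night = 1.0 if shift == "night" else 0.0
    intercepts = {name: rng.normal(0.0, eff.intercept_sd) for name, eff in truth.ema.items()}

    answered = rng.random(n_days) < config.ema_response_prob
    start = pd.Timestamp(config.start_date)
    rows = []
    for d in np.nonzero(answered)[0]:
        hour = int(slots[rng.integers(len(slots))])
        delivery = start + pd.Timedelta(days=int(d), hours=hour)
        # status of the analysis day containing the delivery time
        aidx = min((d * MINUTES_PER_DAY + hour * 60 + 60) // MINUTES_PER_DAY, n_days - 1)
        is_work = 1.0 if workday[aidx] else 0.0
        row = {"participant_id": participant["participant_id"], "delivery": delivery}
        for name, eff in truth.ema.items():
            val = (
                eff.intercept
                + eff.shift_night * is_night
                + eff.workday * is_work
                + eff.interaction * is_night * is_work
                + intercepts[name]
                + rng.normal(0.0, eff.resid_sd)
            )
            row[name] = int(np.clip(round(val), eff.lo, eff.hi))
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def generate_evidence(
    participant: dict,
    workday: np.ndarray,
    rng: np.random.Generator,
    config: CohortConfig,
) -> pd.DataFrame:
    """Daily work-evidence rows (proximity hits, garment flag, survey)."""
    n_days = len(workday)
    start = pd.Timestamp(config.start_date)
    dates = [start + pd.Timedelta(days=int(d)) for d in range(n_days)]
    prox: list = []
    garment: list = []
    survey: list = []
    for d in range(n_days):
        if rng.random() < config.evidence_missing:
            prox.append(np.nan)
            garment.append(np.nan)
            survey.append(pd.NA)
            continue
        at_work = bool(workday[d])
        prox.append(int(rng.poisson(25.0)) if at_work else 0)
        garment.append(bool(at_work and rng.random() < config.garment_wear_prob))
        if rng.random() < config.survey_response_prob:
            survey.append("yes" if at_work else "no")
        else:
            survey.append(pd.NA)
    return pd.DataFrame(
        {
            "participant_id": participant["participant_id"],
            "date": dates,
            "proximity_hits": prox,
            "garment_present": pd.array(garment, dtype="boolean"),
            "survey_at_work": pd.array(survey, dtype="string"),
        }
    )


# ---------------------------------------------------------------------------
# Cohort assembly


def _exact_count_flags(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Boolean vector with exactly ``min(k, n)`` True, randomly placed."""
    flags = np.zeros(n, dtype=bool)
    if n:
        idx = rng.choice(n, size=min(k, n), replace=False)
        flags[idx] = True
    return flags


def _scale_count(k_ref: int, n_ref: int, n: int) -> int:
    return int(round(k_ref * n / n_ref)) if n_ref else 0


def _generate_group_roster(
    rng: np.random.Generator, shift: str, n: int, start_index: int, truth: GroundTruth
) -> pd.DataFrame:
    g = truth.baseline[shift]
    ref_n = 69 if shift == "day" else 44
    ages = np.round(np.clip(rng.normal(g.age[0], g.age[1], n), 23.0, 65.0), 1)
    female = _exact_count_flags(rng, n, _scale_count(g.n_female, ref_n, n))
    graduate = _exact_count_flags(rng, n, _scale_count(g.n_graduate, ref_n, n))
    native = _exact_count_flags(rng, n, _scale_count(g.n_native_english, ref_n, n))
    return pd.DataFrame(
        {
            "participant_id": [f"P{start_index + i:03d}" for i in range(n)],
            "shift": shift,
            "age": ages,
            "gender": np.where(female, "female", "male"),
            "degree": np.where(graduate, "graduate", "college"),
            "native_english": native,
        }
    )


def _generate_baseline_row(
    participant: dict, walk_latent_z: float, truth: GroundTruth, rng: np.random.Generator
) -> dict:
    g = truth.baseline[participant["shift"]]
    is_day = 1.0 if participant["shift"] == "day" else 0.0
    swls_sigma = 1.2  # pooled scale used to translate std-β couplings
    swls = (
        g.swls[0]
        + truth.swls_walk_beta * swls_sigma * walk_latent_z
        + truth.swls_walk_interaction * swls_sigma * walk_latent_z * is_day
        + rng.normal(0.0, 1.0)
    )
    row = {
        "participant_id": participant["participant_id"],
        "stai": float(np.clip(round(rng.normal(*g.stai)), 20, 80)),
        "pa": float(np.clip(round(rng.normal(*g.pa)), 10, 50)),
        "na": float(np.clip(round(rng.normal(*g.na)), 10, 50)),
        "swls": float(np.clip(round(swls, 1), 1.0, 7.0)),
        "psqi": float(np.clip(round(rng.normal(*g.psqi)), 0, 21)),
    }
    for trait, (mu, sd) in g.bfi.items():
        row[f"bfi_{trait}"] = float(np.clip(round(rng.normal(mu, sd), 1), 1.0, 5.0))
    return row


DEFAULT_STREAMS = frozenset({"minutes", "sleep", "ema"})


def generate_cohort(
    config: CohortConfig, streams: frozenset[str] | set[str] = DEFAULT_STREAMS
) -> CohortBundle:
    """Generate a full synthetic cohort bundle.

    ``streams`` selects which heavy streams to produce ("minutes", "sleep",
    "ema"); the roster, schedules, baseline surveys, and work evidence are
    always generated.  The same (config, streams) pair is bit-reproducible.
    """
    config.validate()
    truth = config.truth
    root = np.random.SeedSequence(config.seed)
    n_total = config.n_day + config.n_night
    children = root.spawn(n_total + 1)
    roster_rng = np.random.default_rng(children[0])

    roster = pd.concat(
        [
            _generate_group_roster(roster_rng, "day", config.n_day, 1, truth),
            _generate_group_roster(roster_rng, "night", config.n_night, config.n_day + 1, truth),
        ],
        ignore_index=True,
    )

    n_days = config.n_days
    start = pd.Timestamp(config.start_date)
    minutes_parts, sleep_parts, ema_parts, evidence_parts = [], [], [], []
    baseline_rows, schedule_rows = [], []
    for i, participant in enumerate(roster.to_dict("records")):
        # independent substreams so skipping one stream never perturbs others
        seqs = children[i + 1].spawn(6)
        sched_rng = np.random.default_rng(seqs[0])
        shift_days = _scheduled_shift_dates(sched_rng, config)
        workday = schedule_day_status(shift_days, participant["shift"], n_days)
        start_h, end_h = DAY_SHIFT_HOURS if participant["shift"] == "day" else NIGHT_SHIFT_HOURS
        for d in shift_days:
            shift_start = start + pd.Timedelta(days=int(d), hours=start_h)
            shift_end = shift_start + pd.Timedelta(hours=12)
            schedule_rows.append(
                {
                    "participant_id": participant["participant_id"],
                    "date": start + pd.Timedelta(days=int(d)),
                    "shift_start": shift_start,
                    "shift_end": shift_end,
                }
            )
        # walk latent shared between the minute stream and baseline coupling
        latent_rng = np.random.default_rng(seqs[1])
        walk_latent = latent_rng.normal(0.0, truth.walk_between_sd)
        if "minutes" in streams:
            minutes_parts.append(
                generate_minute_stream(
                    participant,
                    workday,
                    truth,
                    np.random.default_rng(seqs[2]),
                    config,
                    walk_offset=walk_latent,
                )
            )
        if "sleep" in streams:
            sleep_parts.append(
                generate_sleep_sessions(
                    participant, workday, truth, np.random.default_rng(seqs[3]), config
                )
            )
        if "ema" in streams:
            ema_parts.append(
                generate_ema_responses(
                    participant, workday, truth, np.random.default_rng(seqs[4]), config
                )
            )
        ev_rng = np.random.default_rng(seqs[5])
        evidence_parts.append(generate_evidence(participant, workday, ev_rng, config))
        baseline_rows.append(
            _generate_baseline_row(
                participant, walk_latent / truth.walk_between_sd, truth, ev_rng
            )
        )

    empty = {
        "minutes": pd.DataFrame(columns=["participant_id", "timestamp", "heart_rate", "steps"]),
        "sleep": pd.DataFrame(
            columns=["participant_id", "onset", "offset", "duration_min", "efficiency_pct"]
        ),
        "ema": pd.DataFrame(
            columns=["participant_id", "delivery", "stress", "anxiety", "pa_short", "na_short"]
        ),
    }

    def _concat(parts, key):
        return pd.concat(parts, ignore_index=True) if parts else empty[key]

    from .io import SCHEMAS

    baseline = pd.DataFrame(baseline_rows)
    if len(baseline):
        baseline = baseline[list(SCHEMAS["baseline"][0])]

    return CohortBundle(
        participants=roster,
        minutes=_concat(minutes_parts, "minutes"),
        sleep=_concat(sleep_parts, "sleep"),
        ema=_concat(ema_parts, "ema"),
        baseline=baseline,
        evidence=pd.concat(evidence_parts, ignore_index=True)
        if evidence_parts
        else pd.DataFrame(
            columns=["participant_id", "date", "proximity_hits", "garment_present", "survey_at_work"]
        ),
        schedules=pd.DataFrame(
            schedule_rows,
            columns=["participant_id", "date", "shift_start", "shift_end"],
        ),
        ground_truth=truth,
        start_date=start,
        n_days=n_days,
    )


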