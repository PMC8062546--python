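"""Synthetic cohort generator: determinism, contracts, and target recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest
from scipy import stats as sps

from shiftsense.day_labeling import label_days
from shiftsense.sleep import sleep_profile
from shiftsense.synthetic import (
    CohortConfig,
    ConfigError,
    EMA_SLOTS,
    default_ground_truth,
    generate_cohort,
    generate_minute_stream,
    generate_sleep_sessions,
    null_ground_truth,
    schedule_day_status,
)


def _one_participant(shift="night", age=35.0):
    return {"participant_id": "PX", "shift": shift, "age": age}


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_day": -1},
            {"weeks": -2},
            {"minute_missing": 1.5},
            {"sleep_day_prob": -0.1},
            {"shifts_per_week": 8},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            CohortConfig(**kwargs).validate()


class TestDeterminism:
    def test_same_seed_same_bundle(self):
        cfg = CohortConfig(n_day=4, n_night=3, weeks=2, seed=42)
        b1 = generate_cohort(cfg)
        b2 = generate_cohort(cfg)
        for name, t1 in b1.tables().items():
            pdt.assert_frame_equal(t1, getattr(b2, name))

    def test_adding_a_participant_preserves_existing_streams(self):
        small = generate_cohort(CohortConfig(n_day=3, n_night=2, weeks=2, seed=5))
        larger = generate_cohort(CohortConfig(n_day=3, n_night=3, weeks=2, seed=5))
        shared = small.participants["participant_id"]
        pdt.assert_frame_equal(
            small.sleep[small.sleep["participant_id"].isin(shared)].reset_index(drop=True),
            larger.sleep[larger.sleep["participant_id"].isin(shared)].reset_index(drop=True),
        )


class TestRosterAndSchedules:
    def test_shift_windows(self, small_cohort):
        sched = small_cohort.schedules.merge(
            small_cohort.participants[["participant_id", "shift"]], on="participant_id"
        )
        day = sched[sched["shift"] == "day"]
        night = sched[sched["shift"] == "night"]
        assert (day["shift_start"].dt.hour == 7).all()
        assert (day["shift_end"].dt.hour == 19).all()
        assert (night["shift_start"].dt.hour == 19).all()
        assert (night["shift_end"].dt.hour == 7).all()

    def test_night_shift_marks_both_overlapped_days(self):
        work = schedule_day_status(np.array([3]), "night", 7)
        assert work.tolist() == [False, False, False, True, True, False, False]
        work_day = schedule_day_status(np.array([3]), "day", 7)
        assert work_day.tolist() == [False, False, False, True, False, False, False]

    def test_roster_marginals_match_group_counts(self):
        b = generate_cohort(CohortConfig(seed=0), streams=set())
        day = b.participants[b.participants["shift"] == "day"]
        night = b.participants[b.participants["shift"] == "night"]
        assert (len(day), len(night)) == (69, 44)
        assert (day["gender"] == "female").sum() == 51
        assert (night["gender"] == "female").sum() == 31
        assert (day["degree"] == "graduate").sum() == 10
        assert (night["degree"] == "graduate").sum() == 11
        assert day["native_english"].sum() == 39
        assert night["native_english"].sum() == 25


class TestMinuteStream:
    def test_full_minute_missingness_gives_empty_stream(self):
        cfg = CohortConfig(minute_missing=1.0, weeks=2)
        stream = generate_minute_stream(
            _one_participant(), np.zeros(14, dtype=bool), cfg.truth,
            np.random.default_rng(0), cfg,
        )
        assert stream.empty

    def test_zero_days_gives_empty_stream(self):
        cfg = CohortConfig(weeks=0)
        stream = generate_minute_stream(
            _one_participant(), np.zeros(0, dtype=bool), cfg.truth,
            np.random.default_rng(0), cfg,
        )
        assert stream.empty

    def test_zero_vigorous_target_stays_below_threshold(self):
        truth = default_ground_truth()
        activity = {
            k: dataclasses.replace(v, vigorous_min=0.0, excluded_frac=0.0)
            for k, v in truth.activity.items()
        }
        truth = dataclasses.replace(truth, activity=activity)
        cfg = CohortConfig(weeks=4, minute_missing=0.0, day_missing=0.0)
        part = _one_participant(age=30.0)  # hrmax 190
        stream = generate_minute_stream(
            part, np.zeros(28, dtype=bool), truth, np.random.default_rng(1), cfg
        )
        vig_frac = (stream["heart_rate"] >= 0.70 * 190.0).mean()
        assert vig_frac < 0.01

    def test_walk_ratio_concentrates_on_target(self):
        truth = default_ground_truth()
        activity = {
            k: dataclasses.replace(v, walk_ratio=0.30) for k, v in truth.activity.items()
        }
        offsets = {k: (0.0,) * 6 for k in truth.walk_bin_offsets}
        truth = dataclasses.replace(
            truth, activity=activity, walk_bin_offsets=offsets, walk_between_sd=0.0
        )
        cfg = CohortConfig(weeks=10, minute_missing=0.0, day_missing=0.0)
        work = np.zeros(70, dtype=bool)
        work[::3] = True
        stream = generate_minute_stream(
            _one_participant(), work, truth, np.random.default_rng(2), cfg
        )
        assert (stream["steps"] > 0).mean() == pytest.approx(0.30, abs=0.02)

    def test_instrument_ranges(self, small_cohort):
        m = small_cohort.minutes
        assert m["heart_rate"].between(30, 220).all()
        assert (m["steps"] >= 0).all()
        e = small_cohort.ema
        assert e["stress"].between(1, 5).all() and e["anxiety"].between(1, 5).all()
        assert e["pa_short"].between(5, 25).all() and e["na_short"].between(5, 25).all()
        assert small_cohort.sleep["efficiency_pct"].between(0, 100, inclusive="right").all()


class TestSleepSessions:
    def test_zero_weeks_empty(self):
        cfg = CohortConfig(weeks=0)
        out = generate_sleep_sessions(
            _one_participant(), np.zeros(0, dtype=bool), cfg.truth,
            np.random.default_rng(0), cfg,
        )
        assert out.empty

    def test_zero_spread_recovers_configured_jet_lag_exactly(self):
        truth = default_ground_truth(jet_lag_day=52.5, jet_lag_night=425.0)
        sleep = {
            k: dataclasses.replace(v, onset_sd=0.0, duration_sd=0.0, efficiency_sd=0.0)
            for k, v in truth.sleep.items()
        }
        truth = dataclasses.replace(truth, sleep=sleep, chronotype_sd=0.0, jet_lag_sd=0.0)
        cfg = CohortConfig(
            n_day=2,
            n_night=2,
            weeks=4,
            seed=3,
            truth=truth,
            sleep_day_prob=1.0,
            evidence_missing=0.0,
            survey_response_prob=1.0,
        )
        bundle = generate_cohort(cfg, streams={"sleep"})
        labels = label_days(bundle.evidence)
        prof = sleep_profile(bundle.sleep, labels).merge(bundle.participants, on="participant_id")
        for _, row in prof.iterrows():
            target = 52.5 if row["shift"] == "day" else 425.0
            assert row["delta_ms"] == pytest.approx(target, abs=1.5)  # onset rounding to minutes

    def test_duration_never_exceeds_interval(self, small_cohort):
        s = small_cohort.sleep
        interval = (s["offset"] - s["onset"]).dt.total_seconds() / 60
        assert (s["duration_min"] <= interval + 1e-9).all()


class TestEma:
    def test_delivery_slots_match_shift(self, small_cohort):
        ema = small_cohort.ema.merge(
            small_cohort.participants[["participant_id", "shift"]], on="participant_id"
        )
        for shift, slots in EMA_SLOTS.items():
            hours = set(ema.loc[ema["shift"] == shift, "delivery"].dt.hour)
            assert hours <= set(slots)

    def test_null_effects_centre_on_intercepts(self):
        truth = null_ground_truth()
        ema_effects = {
            name: dataclasses.replace(e, shift_night=0.0, workday=0.0, interaction=0.0,
                                      intercept_sd=0.0)
            for name, e in truth.ema.items()
        }
        truth = dataclasses.replace(truth, ema=ema_effects)
        cfg = CohortConfig(n_day=10, n_night=10, weeks=6, seed=9, truth=truth)
        bundle = generate_cohort(cfg, streams={"ema"})
        ema = bundle.ema.merge(
            bundle.participants[["participant_id", "shift"]], on="participant_id"
        )
        by_shift = ema.groupby("shift")["stress"].mean()
        assert by_shift["day"] == pytest.approx(by_shift["night"], abs=0.1)


class TestNullAndRecovery:
    def test_null_truth_removes_group_differences(self):
        """With all shift effects zeroed, group comparisons behave as nulls."""
        pvals = []
        for seed in range(10):
            cfg = CohortConfig(
                n_day=20, n_night=20, weeks=4, seed=seed, truth=null_ground_truth()
            )
            b = generate_cohort(cfg, streams={"sleep"})
            prof = (
                sleep_profile(b.sleep, label_days(b.evidence), min_sessions=3)
                .merge(b.participants, on="participant_id")
            )
            day = prof.loc[prof["shift"] == "day", "duration_workday"].dropna()
            night = prof.loc[prof["shift"] == "night", "duration_workday"].dropna()
            pvals.append(sps.ttest_ind(day, night).pvalue)
        assert sum(p > 0.05 for p in pvals) >= 8

    def test_group_sleep_means_converge_to_targets(self):
        """Cell means approach the configured targets at n=200 (2 SE check)."""
        cfg = CohortConfig(n_day=100, n_night=100, weeks=10, seed=17)
        b = generate_cohort(cfg, streams={"sleep"})
        prof = sleep_profile(b.sleep, label_days(b.evidence)).merge(
            b.participants, on="participant_id"
        )
        truth = cfg.truth
        for shift in ("day", "night"):
            grp = prof[prof["shift"] == shift]
            for status in ("workday", "offday"):
                x = grp[f"duration_{status}"].dropna()
                target = truth.sleep[(shift, status)].duration_mean
                se = x.std(ddof=1) / np.sqrt(len(x))
                # mislabelled-evidence days mix a small share of the other cell in
                tol = 2 * se + 4.0
                assert abs(x.mean() - target) < tol, (shift, status, x.mean(), target)
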