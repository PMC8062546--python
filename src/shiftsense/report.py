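"""End-to-end study orchestration and report tables.

``run_study`` drives the full pipeline — simulate (or ingest) a cohort,
infer workdays, extract activity and sleep features, fit the statistical
battery — and emits the study's report products:

* ``table1_demographics`` — group counts/means with t-tests and Fisher ORs;
* ``table2_activity`` — activity estimated marginal means by shift × status
  with the three-way-ANOVA shift p-value;
* ``table3_regressions`` — standardized-β regressions of baseline scores on
  off-day activity features;
* ``table4_sleep`` — sleep duration/efficiency/ΔMS marginal means;
* ``table5_sleep_regressions`` — the same regressions for sleep features;
* ``fig1_ema_distributions`` — EMA summaries by shift × work status (plus
  the mixed-model fixed effects);
* ``fig2_diurnal_profiles`` — per-bin walk/rest means and the 2×6
  repeated-measures ANOVA;
* ``fig3_sleep_timing`` — circular medians/ranges of onset and wake times.

Text tables round to display precision (ratios and minutes 1 dp, odds
ratios and βs 2 dp); the accompanying ``stats.json`` keeps full precision,
and ``run_log.json`` records thresholds, exclusion counts, and the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity as act
from . import sleep as slp
from . import stats as st
from .day_labeling import DIURNAL_BIN_LABELS, assign_work_status, label_days
from .io import BFI_TRAITS, CohortBundle, read_bundle
from .synthetic import CohortConfig, generate_cohort

__all__ = [
    "StudyConfig",
    "StudyReport",
    "proportion_pct",
    "group_difference",
    "summarize_ema",
    "simulated_group_summary",
    "run_study",
]

BASELINE_VARS = ["stai", "pa", "na", "swls"] + [f"bfi_{t}" for t in BFI_TRAITS] + ["psqi"]
EMA_VARS = ("stress", "anxiety", "pa_short", "na_short")


@dataclass
class StudyConfig:
    """One study run: input mode, thresholds, seed, and output location."""

    mode: str = "simulate"  # "simulate" | "ingest"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_dir: str | Path | None = None  # ingest mode
    zone: act.ZoneConfig = field(default_factory=act.ZoneConfig)
    min_sleep_sessions: int = 5
    min_emas: int = 10
    proximity_min: int = 1
    out_dir: str | Path | None = None

    def validate(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if self.mode == "ingest" and self.input_dir is None:
            raise ValueError("ingest mode needs input_dir")


@dataclass
class StudyReport:
    tables: dict[str, pd.DataFrame]
    stats: dict
    log: dict
    bundle: CohortBundle
    activity_profiles: pd.DataFrame
    sleep_profiles: pd.DataFrame
    labels: pd.DataFrame


def proportion_pct(k: float, n: float) -> float:
    """Share of a group as a percentage (full precision)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * k / n


def group_difference(day_value: float, night_value: float, absolute: bool = False) -> float:
    """Day-minus-night difference of two group estimates."""
    d = day_value - night_value
    return abs(d) if absolute else d


# ---------------------------------------------------------------------------
# Table builders


def _analysis_frame(profiles: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    df = profiles.merge(participants, on="participant_id", how="left")
    df["age_group"] = np.where(df["age"] < 40, "<40", ">=40")
    return df


def table1_demographics(participants: pd.DataFrame, baseline: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    df = participants.merge(baseline, on="participant_id", how="left")
    day = df[df["shift"] == "day"]
    night = df[df["shift"] == "night"]
    n_day, n_night, n_all = len(day), len(night), len(df)
    rows: list = []
    stats: dict = {}

    def cat_row(name, day_k, night_k, table):
        fr = st.fisher_exact_2x2(table)
        stats[f"fisher_{name}"] = {
            "odds_ratio": fr.odds_ratio,
            "p": fr.p,
            "table": fr.table.tolist(),
        }
        rows.append(
            {
                "variable": name,
                "kind": "categorical",
                "day": f"{day_k} ({proportion_pct(day_k, n_day):.1f}%)",
                "night": f"{night_k} ({proportion_pct(night_k, n_night):.1f}%)",
                "all": f"{day_k + night_k} ({proportion_pct(day_k + night_k, n_all):.1f}%)",
                "statistic": round(fr.odds_ratio, 2),
                "p": round(fr.p, 3),
            }
        )

    fem_d = int((day["gender"] == "female").sum())
    fem_n = int((night["gender"] == "female").sum())
    cat_row("gender_female", fem_d, fem_n, [[fem_d, n_day - fem_d], [fem_n, n_night - fem_n]])
    col_d = int((day["degree"] == "college").sum())
    col_n = int((night["degree"] == "college").sum())
    cat_row("degree_college", col_d, col_n, [[col_d, n_day - col_d], [col_n, n_night - col_n]])
    nat_d = int(day["native_english"].sum())
    nat_n = int(night["native_english"].sum())
    cat_row("native_english", nat_d, nat_n, [[nat_d, n_day - nat_d], [nat_n, n_night - nat_n]])

    stats["composition"] = {
        "n_day": n_day,
        "n_night": n_night,
        "n_total": n_all,
        "pct_day": proportion_pct(n_day, n_all),
        "pct_female": proportion_pct(fem_d + fem_n, n_all),
    }

    for var in ["age"] + BASELINE_VARS:
        x = day[var].dropna()
        y = night[var].dropna()
        tt = st.two_sample_ttest(x, y)
        stats[f"ttest_{var}"] = dataclasses.asdict(tt)
        rows.append(
            {
                "variable": var,
                "kind": "continuous",
                "day": f"{tt.mean1:.1f} ± {tt.sd1:.1f}",
                "night": f"{tt.mean2:.1f} ± {tt.sd2:.1f}",
                "all": f"{df[var].mean():.1f} ± {df[var].std(ddof=1):.1f}",
                "statistic": round(tt.t, 2),
                "p": round(tt.p, 3),
            }
        )
    return pd.DataFrame(rows), stats


_ACTIVITY_TABLE_FEATURES = (
    ("rest_ratio", "Rest activity ratio (%)", 100.0),
    ("walk_ratio", "Walk activity ratio (%)", 100.0),
    ("vigorous_min", "Vigorous activity (min)", 1.0),
)


def _emm_table(
    analysis: pd.DataFrame, features, statuses=("workday", "offday")
) -> tuple[pd.DataFrame, dict]:
    rows, stats = [], {}
    for feat, label, scale in features:
        for status in statuses:
            col = f"{feat}_{status}"
            if col not in analysis:
                continue
            sub = analysis[analysis[f"eligible_{status}"]] if f"eligible_{status}" in analysis else analysis
            sub = sub.dropna(subset=[col]).copy()
            sub["_outcome"] = sub[col] * scale
            res = st.three_way_anova(sub, "_outcome")
            stats[f"anova3_{col}"] = {
                "terms": res.terms,
                "emmeans": res.emmeans,
                "n": res.nobs,
            }
            emm_d = res.emmeans["shift"]["day"]
            emm_n = res.emmeans["shift"]["night"]
            rows.append(
                {
                    "variable": label,
                    "status": status,
                    "day_emm": round(emm_d[0], 1),
                    "day_se": round(emm_d[1], 1),
                    "day_lower_cl": round(emm_d[2], 1),
                    "day_upper_cl": round(emm_d[3], 1),
                    "night_emm": round(emm_n[0], 1),
                    "night_se": round(emm_n[1], 1),
                    "night_lower_cl": round(emm_n[2], 1),
                    "night_upper_cl": round(emm_n[3], 1),
                    "difference": round(emm_d[0], 1) - round(emm_n[0], 1),
                    "p_shift": round(res.terms["shift"][3], 3),
                    "n": res.nobs,
                }
            )
    return pd.DataFrame(rows), stats


def table2_activity(profiles: pd.DataFrame, participants: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    analysis = _analysis_frame(profiles, participants)
    return _emm_table(analysis, _ACTIVITY_TABLE_FEATURES)


def table4_sleep(sleep_profiles: pd.DataFrame, participants: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    analysis = _analysis_frame(sleep_profiles, participants)
    features = (
        ("duration", "Sleep duration (min)", 1.0),
        ("efficiency", "Sleep efficiency (%)", 1.0),
    )
    table, stats = _emm_table(analysis, features)
    both = analysis[analysis["eligible_workday"] & analysis["eligible_offday"]].dropna(
        subset=["delta_ms"]
    )
    res = st.three_way_anova(both.assign(_outcome=both["delta_ms"]), "_outcome")
    stats["anova3_delta_ms"] = {"terms": res.terms, "emmeans": res.emmeans, "n": res.nobs}
    emm_d, emm_n = res.emmeans["shift"]["day"], res.emmeans["shift"]["night"]
    table = pd.concat(
        [
            table,
            pd.DataFrame(
                [
                    {
                        "variable": "Delta MS (min)",
                        "status": "both",
                        "day_emm": round(emm_d[0], 1),
                        "day_se": round(emm_d[1], 1),
                        "day_lower_cl": round(emm_d[2], 1),
                        "day_upper_cl": round(emm_d[3], 1),
                        "night_emm": round(emm_n[0], 1),
                        "night_se": round(emm_n[1], 1),
                        "night_lower_cl": round(emm_n[2], 1),
                        "night_upper_cl": round(emm_n[3], 1),
                        "difference": round(emm_d[0], 1) - round(emm_n[0], 1),
                        "p_shift": round(res.terms["shift"][3], 3),
                        "n": res.nobs,
                    }
                ]
            ),
        ],
        ignore_index=True,
    )
    return table, stats


def _regression_table(
    analysis: pd.DataFrame, features: dict[str, str], outcomes=("swls", "stai", "psqi", "pa", "na")
) -> tuple[pd.DataFrame, dict]:
    rows, stats = [], {}
    for feat_col, feat_label in features.items():
        for outcome in outcomes:
            sub = analysis.dropna(subset=[feat_col, outcome])
            try:
                res = st.std_regression(sub, outcome, feat_col)
            except ValueError:
                continue
            stats[f"regression_{outcome}_{feat_col}"] = {
                "terms": res.terms,
                "adj_r2": res.adj_r2,
                "f": res.f,
                "df_model": res.df_model,
                "df_resid": res.df_resid,
                "n": res.n,
            }
            for term, (beta, t, p) in res.terms.items():
                rows.append(
                    {
                        "feature": feat_label,
                        "outcome": outcome,
                        "term": term.replace(feat_col, feat_label),
                        "std_beta": round(beta, 2),
                        "t": round(t, 2),
                        "p": round(p, 3),
                        "adj_r2": round(res.adj_r2, 3),
                        "n": res.n,
                    }
                )
    return pd.DataFrame(rows), stats


def table3_regressions(profiles: pd.DataFrame, participants: pd.DataFrame, baseline: pd.DataFrame):
    analysis = _analysis_frame(profiles, participants).merge(baseline, on="participant_id")
    analysis = analysis[analysis["eligible_offday"]]
    features = {
        "rest_ratio_offday": "rest-activity ratio (off-day)",
        "walk_ratio_offday": "walk-activity ratio (off-day)",
    }
    return _regression_table(analysis, features)


def table5_sleep_regressions(
    sleep_profiles: pd.DataFrame, participants: pd.DataFrame, baseline: pd.DataFrame
):
    analysis = _analysis_frame(sleep_profiles, participants).merge(baseline, on="participant_id")
    analysis = analysis[analysis["eligible_offday"]]
    features = {
        "duration_offday": "sleep duration (off-day)",
        "efficiency_offday": "sleep efficiency (off-day)",
    }
    return _regression_table(analysis, features)


def summarize_ema(
    ema: pd.DataFrame, labels: pd.DataFrame, participants: pd.DataFrame
) -> pd.DataFrame:
    """Distribution summaries of each EMA outcome per shift × work status."""
    df = ema.merge(participants[["participant_id", "shift"]], on="participant_id")
    df["status"] = assign_work_status(df["delivery"], df["participant_id"], labels).to_numpy()
    df = df[df["status"].isin(["workday", "offday"])]
    rows = []
    for (shift, status), grp in df.groupby(["shift", "status"], sort=True):
        for var in EMA_VARS:
            x = grp[var].dropna()
            rows.append(
                {
                    "shift": shift,
                    "status": status,
                    "outcome": var,
                    "n": len(x),
                    "mean": x.mean(),
                    "sd": x.std(ddof=1),
                    "q25": x.quantile(0.25),
                    "median": x.quantile(0.5),
                    "q75": x.quantile(0.75),
                }
            )
    return pd.DataFrame(rows)


def fig2_diurnal(profiles: pd.DataFrame, participants: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-bin group means plus the 2×6 repeated-measures ANOVA per measure."""
    analysis = _analysis_frame(profiles, participants)
    rows, stats = [], {}
    for measure, prefix in (("walk", "walk_bin"), ("rest", "rest_bin")):
        for status in ("workday", "offday"):
            cols = [f"{prefix}{b}_{status}" for b in range(6)]
            sub = analysis[analysis[f"eligible_{status}"]].dropna(subset=cols)
            long = sub.melt(
                id_vars=["participant_id", "shift"],
                value_vars=cols,
                var_name="bin_col",
                value_name="value",
            )
            long["bin"] = long["bin_col"].str.extract(rf"{prefix}(\d)").astype(int)
            try:
                res = st.rm_anova_2x6(long)
            except ValueError:
                continue
            stats[f"rm_anova_{measure}_{status}"] = {
                "terms": res.terms,
                "mauchly_w": res.mauchly_w,
                "mauchly_p": res.mauchly_p,
                "gg_epsilon": res.gg_epsilon,
                "corrected": res.corrected,
                "sphericity_met": res.sphericity_met,
                "pairwise_p": {b: r.p for b, r in res.pairwise.items()},
                "n_per_group": res.n_per_group,
            }
            for shift, grp in long.groupby("shift"):
                means = grp.groupby("bin")["value"].mean()
                for b in range(6):
                    rows.append(
                        {
                            "measure": measure,
                            "status": status,
                            "shift": shift,
                            "bin": DIURNAL_BIN_LABELS[b],
                            "mean_pct": round(100.0 * means.get(b, np.nan), 1),
                            "p_pairwise": round(res.pairwise[str(b)].p, 3),
                        }
                    )
    return pd.DataFrame(rows), stats


def fig3_sleep_timing(sleep: pd.DataFrame, labels: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for shift in ("day", "night"):
        pids = participants.loc[participants["shift"] == shift, "participant_id"]
        sub = sleep[sleep["participant_id"].isin(pids)]
        if sub.empty:
            continue
        summary = slp.sleep_regularity_summary(sub, labels)
        summary.insert(0, "shift", shift)
        rows.append(summary)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    for col in ("onset_median", "onset_range", "offset_median", "offset_range"):
        if col in out:
            out[col] = out[col].round(1)
    return out


def simulated_group_summary(cohort_config: CohortConfig) -> dict[str, dict[str, float]]:
    """Raw group means of the headline features from one simulated run.

    Fast path for repeated-seed checks: generation, labelling, activity and
    sleep aggregation only (no model fitting).  Returns
    ``feature -> {"day": mean, "night": mean}``.
    """
    bundle = generate_cohort(cohort_config)
    labels = label_days(bundle.evidence)
    summaries = act.daily_summaries(bundle.minutes, bundle.participants)
    profiles = act.aggregate_activity(summaries, labels).merge(
        bundle.participants[["participant_id", "shift"]], on="participant_id"
    )
    sleep_prof = slp.sleep_profile(bundle.sleep, labels).merge(
        bundle.participants[["participant_id", "shift"]], on="participant_id"
    )
    out: dict[str, dict[str, float]] = {}
    for feat in (
        "rest_ratio_workday",
        "rest_ratio_offday",
        "walk_ratio_workday",
        "walk_ratio_offday",
        "vigorous_min_workday",
        "vigorous_min_offday",
    ):
        status = feat.rsplit("_", 1)[1]
        sub = profiles[profiles[f"eligible_{status}"]]
        out[feat] = sub.groupby("shift")[feat].mean().to_dict()
    for feat in ("duration_workday", "duration_offday", "delta_ms"):
        out[feat] = sleep_prof.groupby("shift")[feat].mean().to_dict()
    return out


# ---------------------------------------------------------------------------
# Orchestration


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full pipeline and build every report table.

    In simulate mode the cohort is generated from ``config.cohort``; in
    ingest mode the six-table CSV directory at ``config.input_dir`` is
    read.  When ``config.out_dir`` is set, tables are written as CSV along
    with ``stats.json`` (full precision) and ``run_log.json``.
    """
    config.validate()
    if config.mode == "simulate":
        bundle = generate_cohort(config.cohort)
    else:
        bundle = read_bundle(config.input_dir)

    labels = label_days(bundle.evidence, proximity_min=config.proximity_min)

    summaries = act.daily_summaries(bundle.minutes, bundle.participants, config.zone)
    profiles = act.aggregate_activity(summaries, labels, config.zone)
    sleep_profiles = slp.sleep_profile(bundle.sleep, labels, min_sessions=config.min_sleep_sessions)

    tables: dict[str, pd.DataFrame] = {}
    stats: dict = {}

    tables["table1_demographics"], s1 = table1_demographics(bundle.participants, bundle.baseline)
    stats.update(s1)
    if not profiles.empty:
        tables["table2_activity"], s2 = table2_activity(profiles, bundle.participants)
        stats.update(s2)
        tables["table3_regressions"], s3 = table3_regressions(
            profiles, bundle.participants, bundle.baseline
        )
        stats.update(s3)
        tables["fig2_diurnal_profiles"], sf2 = fig2_diurnal(profiles, bundle.participants)
        stats.update(sf2)
        try:
            stats["moderate_redundancy"] = act.moderate_redundancy_check(profiles)
        except ValueError:
            pass
    if not sleep_profiles.empty:
        tables["table4_sleep"], s4 = table4_sleep(sleep_profiles, bundle.participants)
        stats.update(s4)
        tables["table5_sleep_regressions"], s5 = table5_sleep_regressions(
            sleep_profiles, bundle.participants, bundle.baseline
        )
        stats.update(s5)
        tables["fig3_sleep_timing"] = fig3_sleep_timing(bundle.sleep, labels, bundle.participants)

    if not bundle.ema.empty:
        tables["fig1_ema_distributions"] = summarize_ema(
            bundle.ema, labels, bundle.participants
        ).round({"mean": 2, "sd": 2})
        ema_model = bundle.ema.merge(
            bundle.participants[["participant_id", "shift"]], on="participant_id"
        )
        ema_model["status"] = assign_work_status(
            ema_model["delivery"], ema_model["participant_id"], labels
        ).to_numpy()
        ema_model = ema_model[ema_model["status"].isin(["workday", "offday"])]
        for var in EMA_VARS:
            try:
                res = st.lmm_ema(ema_model, var, min_emas=config.min_emas)
            except ValueError:
                continue
            stats[f"lmm_{var}"] = {
                "fixed": res.fixed,
                "random_intercept_var": res.random_intercept_var,
                "resid_var": res.resid_var,
                "n_obs": res.n_obs,
                "n_participants": res.n_participants,
                "n_excluded": res.n_excluded,
                "converged": res.converged,
                "singular": res.singular,
            }

    log = {
        "mode": config.mode,
        "seed": config.cohort.seed if config.mode == "simulate" else None,
        "thresholds": {
            "min_valid_minutes": config.zone.min_valid_minutes,
            "min_activity_days": config.zone.min_days,
            "min_sleep_sessions": config.min_sleep_sessions,
            "min_emas": config.min_emas,
            "proximity_min": config.proximity_min,
        },
        "exclusions": {
            "activity_workday_ineligible": int((~profiles["eligible_workday"]).sum())
            if not profiles.empty
            else None,
            "activity_offday_ineligible": int((~profiles["eligible_offday"]).sum())
            if not profiles.empty
            else None,
            "sleep_workday_ineligible": int((~sleep_profiles["eligible_workday"]).sum())
            if not sleep_profiles.empty
            else None,
            "sleep_offday_ineligible": int((~sleep_profiles["eligible_offday"]).sum())
            if not sleep_profiles.empty
            else None,
            "ema_excluded_lt_min": stats.get("lmm_stress", {}).get("n_excluded"),
        },
        "n_participants": len(bundle.participants),
        "n_minutes": len(bundle.minutes),
        "n_sleep_sessions": len(bundle.sleep),
        "n_ema": len(bundle.ema),
        "label_counts": labels["status"].value_counts().to_dict(),
    }

    report = StudyReport(
        tables=tables,
        stats=_jsonify(stats),
        log=_jsonify(log),
        bundle=bundle,
        activity_profiles=profiles,
        sleep_profiles=sleep_profiles,
        labels=labels,
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        (out / "stats.json").write_text(json.dumps(report.stats, indent=2, sort_keys=True))
        (out / "run_log.json").write_text(json.dumps(report.log, indent=2, sort_keys=True))
        if config.mode == "simulate" and bundle.ground_truth is not None:
            (out / "ground_truth.json").write_text(
                json.dumps(_jsonify(bundle.ground_truth.to_dict()), indent=2, sort_keys=True)
            )
    return report
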