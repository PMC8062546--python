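"""Extract per-participant activity and sleep features.

Heart-rate zone ratios, walking ratios, and vigorous minutes per analysis
day (overall and per diurnal bin) averaged by work status; sleep duration,
efficiency, mid-sleep (MSW/MSF), and social jet lag ΔMS.  Writes
``results/activity_profiles.csv``, ``results/sleep_profiles.csv`` and the
sleep-timing regularity table ``results/sleep_regularity.csv``.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from shiftsense.activity import aggregate_activity, daily_summaries, moderate_redundancy_check
from shiftsense.io import read_bundle
from shiftsense.sleep import sleep_profile, sleep_regularity_summary

BASE = Path(__file__).resolve().parents[1]
SCRATCH = BASE / "scratch"
ROOT = BASE / "results"


def main() -> None:
    bundle = read_bundle(SCRATCH / "cohort")
    labels = pd.read_csv(SCRATCH / "labels.csv", parse_dates=["date"])

    summaries = daily_summaries(bundle.minutes, bundle.participants)
    profiles = aggregate_activity(summaries, labels)
    profiles.round(4).to_csv(ROOT / "activity_profiles.csv", index=False)

    sleep_prof = sleep_profile(bundle.sleep, labels)
    sleep_prof.round(2).to_csv(ROOT / "sleep_profiles.csv", index=False)

    regularity = []
    for shift in ("day", "night"):
        pids = bundle.participants.loc[
            bundle.participants["shift"] == shift, "participant_id"
        ]
        sub = bundle.sleep[bundle.sleep["participant_id"].isin(pids)]
        summary = sleep_regularity_summary(sub, labels)
        summary.insert(0, "shift", shift)
        regularity.append(summary)
    pd.concat(regularity, ignore_index=True).to_csv(
        ROOT / "sleep_regularity.csv", index=False
    )

    redundancy = moderate_redundancy_check(profiles)
    print(f"{len(summaries)} participant-days summarised; "
          f"{len(profiles)} activity profiles; {len(sleep_prof)} sleep profiles")
    for status, r in redundancy.items():
        print(
            f"moderate-vs-rest Spearman rho ({status}): {r['rho']:.3f}"
            + ("  -> moderate ratio dropped from group models" if r["flagged"] else "")
        )


if __name__ == "__main__":
    main()
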