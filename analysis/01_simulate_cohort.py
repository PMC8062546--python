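"""Simulate the default study cohort and write its raw tables.

Generates the 113-nurse, 10-week synthetic cohort (69 day shift, 44 night
shift; three 12-hour shifts per week) with minute-level wearables, sleep
sessions, daily EMAs, baseline surveys, and work evidence, then writes the
six CSV tables plus the generator's ground truth under ``scratch/cohort/``
(the raw minute stream runs to several hundred MB, so it stays out of
``results/``).
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from shiftsense.io import write_bundle
from shiftsense.report import _jsonify  # noqa: SLF001 - shared JSON encoder
from shiftsense.synthetic import CohortConfig, generate_cohort

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"


def main() -> None:
    config = CohortConfig(seed=SEED)
    bundle = generate_cohort(config)
    write_bundle(bundle, OUT)
    (OUT / "ground_truth.json").write_text(
        json.dumps(_jsonify(bundle.ground_truth.to_dict()), indent=2, sort_keys=True)
    )
    print(f"cohort written to {OUT}")
    print(f"  participants: {len(bundle.participants)}")
    print(f"  minute records: {len(bundle.minutes):,}")
    print(f"  sleep sessions: {len(bundle.sleep)}")
    print(f"  EMA responses: {len(bundle.ema)}")


if __name__ == "__main__":
    main()
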