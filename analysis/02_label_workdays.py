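"""Infer workday / off-day labels from the cohort's work evidence.

Reads ``scratch/cohort/evidence.csv``, applies the precedence
survey > garment > proximity, and writes ``scratch/labels.csv`` along with
a small summary of label counts and evidence sources.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from shiftsense.day_labeling import label_days
from shiftsense.io import read_table

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"


def main() -> None:
    evidence = read_table(SCRATCH / "cohort" / "evidence.csv", "evidence")
    labels = label_days(evidence, proximity_min=1)
    labels.to_csv(SCRATCH / "labels.csv", index=False)
    print(f"labels written to {SCRATCH / 'labels.csv'}")
    print(labels["status"].value_counts().to_string())
    print("evidence sources used:")
    print(labels["source"].value_counts().to_string())


if __name__ == "__main__":
    main()
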