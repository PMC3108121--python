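#!/usr/bin/env python
"""Rule-based classification of the simulated cohort.

Applies the three-branch decision rule (postural intensification + rest and
postural center frequency, thresholds 1.5 / 6.5 Hz / 6.5 Hz) to every
simulated subject and evaluates it against the true group labels.  Writes
results/classification.tsv and results/classifier_eval.json.

Note the honest caveat: with between-subject spreads derived from the
published SEMs, the three groups overlap heavily, so per-subject accuracy
is far from perfect even though the group-mean feature vectors separate
cleanly (see docs/methods.md).
"""

import json
from pathlib import Path

import pandas as pd

from tremorlab import io
from tremorlab.pipeline import classification_report

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    wide = io.read_table(RESULTS / "metrics_wide.tsv")
    report = classification_report(wide)
    io.write_table(
        pd.DataFrame(report["classifications"]), RESULTS / "classification.tsv"
    )
    (RESULTS / "classifier_eval.json").write_text(
        json.dumps(report["evaluation"], indent=2, default=float) + "\n"
    )
    ev = report["evaluation"]
    print(f"n={ev['n']}  accuracy={ev['accuracy']:.3f}")
    print("per-group recall:", {k: round(v, 3) for k, v in ev["recall"].items()})
    print("confusion (predicted -> {true: count}):")
    for predicted, col in ev["confusion"].items():
        print(f"  {predicted}: {col}")
    print(f"outputs -> {RESULTS}/classification.tsv, {RESULTS}/classifier_eval.json")


if __name__ == "__main__":
    main()
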