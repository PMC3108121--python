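#!/usr/bin/env python
"""Compute the five spectral tremor parameters for every simulated record.

Reads scratch/cohort/signals/, writes the long per-record metrics table to
results/metrics.tsv and the per-subject wide table (joined with the cohort
labels) to results/metrics_wide.tsv.
"""

from pathlib import Path

from tremorlab import io
from tremorlab.pipeline import analyze_signals, metrics_wide

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    metrics, skipped = analyze_signals(ROOT / "scratch" / "cohort" / "signals")
    if metrics.empty:
        raise SystemExit("no signals found; run analysis/01_simulate_cohort.py first")
    cohort = io.read_table(RESULTS / "cohort.tsv")
    wide = metrics_wide(metrics, cohort)
    io.write_table(metrics, RESULTS / "metrics.tsv")
    io.write_table(wide, RESULTS / "metrics_wide.tsv")
    print(f"{len(metrics)} records analyzed ({skipped} skipped)")
    for group in ("WELDER", "IPD", "ET"):
        sub = wide[wide.group == group]
        print(
            f"  {group:6s} rest-R intensity {sub.rest_R_intensity.mean():.3f} m/s^2, "
            f"rest-R Cf {sub.rest_R_cf.mean():.2f} Hz, "
            f"postural-R intensity {sub.postural_R_intensity.mean():.3f} m/s^2"
        )
    print(f"tables -> {RESULTS}/metrics.tsv, {RESULTS}/metrics_wide.tsv")


if __name__ == "__main__":
    main()
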