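#!/usr/bin/env python
"""Fisher exact panel over the printed welders-vs-IPD clinical-sign counts.

The published symptom/sign table is an input here: each row's 2×2 table
(affected/examined per group, complete-case denominators) gets an exact
two-sided Fisher test and an odds ratio.  Writes results/symptom_fisher.tsv.

No multiple-testing correction is applied (per-row reporting).
"""

from pathlib import Path

from tremorlab import io
from tremorlab.pipeline import symptom_panel_frame

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    panel = symptom_panel_frame()
    RESULTS.mkdir(exist_ok=True)
    io.write_table(panel, RESULTS / "symptom_fisher.tsv")
    print(f"{'sign':28s} {'welders':>9s} {'IPD':>7s} {'p':>8s}")
    for _, row in panel.iterrows():
        n1 = row.group1_affected + row.group1_unaffected
        n2 = row.group2_affected + row.group2_unaffected
        print(
            f"{row.sign:28s} {row.group1_affected:>4d}/{n1:<4d} "
            f"{row.group2_affected:>3d}/{n2:<3d} {row.p_value:8.4f}"
        )
    print(f"panel -> {RESULTS}/symptom_fisher.tsv")


if __name__ == "__main__":
    main()
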