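"""End-to-end pipeline stages: simulate → analyze → stats → classify → report.

Each stage is a plain function over files/DataFrames so the numbered
analysis drivers, the CLI and the tests share one code path.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .archetypes import ARCHETYPES, STUDY_N
from .classify import ClassifierRule, classify_cohort, evaluate_classifier
from .records import CONDITIONS, SIDES, SignalSpec
from .spectral import DEFAULT_CONFIG, SpectralConfig, metrics_for_record
from .simulate import simulate_cohort, cohort_frame
from .stats import (
    MULTIPLE_TESTING_NOTE,
    fold_change,
    regress_vs_covariate,
    summarize_groups,
    table2_report,
    two_way_anova,
)

log = logging.getLogger("tremorlab")


def run_simulate(
    out_dir: str | Path,
    n_per_group=STUDY_N,
    seed: int = 0,
    spec: SignalSpec | None = None,
    config: dict | None = None,
) -> tuple[pd.DataFrame, list[Path]]:
    """Simulate a cohort and write signals + cohort table + manifest."""
    out_dir = Path(out_dir)
    signals_dir = out_dir / "signals"
    signals_dir.mkdir(parents=True, exist_ok=True)
    if spec is None:
        spec = SignalSpec(seed=seed)
    profiles, records = simulate_cohort(tuple(n_per_group), spec, seed)
    paths = []
    for record in records:
        paths.append(io.write_signal(record, signals_dir / io.signal_filename(record)))
    cohort = cohort_frame(profiles)
    cohort_path = io.write_table(cohort, out_dir / "cohort.tsv")
    io.write_manifest(
        out_dir / "manifest.json",
        seed,
        config or {"n_per_group": list(n_per_group), "seed": seed},
        [str(p.name) for p in paths] + ["cohort.tsv"],
    )
    return cohort, paths


def analyze_signals(
    signals_dir: str | Path, config: SpectralConfig = DEFAULT_CONFIG
) -> tuple[pd.DataFrame, int]:
    """Batch tremor metrics over a directory of signal files.

    Malformed files are skipped with a logged warning; returns the per-record
    metrics table (stable, sorted row order) and the number of skipped files.
    """
    signals_dir = Path(signals_dir)
    rows = []
    skipped = 0
    for path in sorted(signals_dir.glob("*.tsv")):
        try:
            record = io.read_signal(path)
            metrics = metrics_for_record(record, config)
        except (ValueError, OSError) as exc:
            log.warning("skipping %s: %s", path.name, exc)
            skipped += 1
            continue
        rows.append(
            {
                "subject_id": record.subject_id,
                "condition": record.condition,
                "side": record.side,
                **metrics.as_dict(),
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(["subject_id", "condition", "side"]).reset_index(drop=True)
    return frame, skipped


def metrics_wide(metrics: pd.DataFrame, cohort: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pivot the long per-record metrics table to one row per subject with
    ``{condition}_{side}_{metric}`` columns, optionally joined to the cohort
    table (group labels, demographics)."""
    wide = metrics.pivot_table(
        index="subject_id",
        columns=["condition", "side"],
        values=[c for c in metrics.columns if c not in ("subject_id", "condition", "side")],
    )
    wide.columns = [f"{cond}_{side}_{name}" for name, cond, side in wide.columns]
    wide = wide.reset_index()
    if cohort is not None:
        wide = cohort.merge(wide, on="subject_id", how="inner")
    return wide


def stats_report(
    wide: pd.DataFrame,
    groups=("WELDER", "IPD", "ET"),
    normative: pd.DataFrame | None = None,
) -> dict:
    """Group summaries, fold changes, ANOVAs and age regressions as a
    JSON-serialisable report in the layout of the published group tables."""
    present = [g for g in groups if (wide["group"] == g).any()]
    if not present:
        raise ValueError("no recognised groups in cohort")
    report: dict = {"note": MULTIPLE_TESTING_NOTE}
    summaries = summarize_groups(wide, groups=tuple(present))
    report["group_summaries"] = summaries.to_dict(orient="records")
    report["fold_changes"] = []
    for g in present:
        for side in SIDES:
            try:
                report["fold_changes"].append(asdict(fold_change(wide, g, side)))
            except ValueError as exc:
                log.warning("fold change %s/%s: %s", g, side, exc)
    report["anova"] = []
    for g in present:
        try:
            res = two_way_anova(wide, g)
            report["anova"].append(
                {"group": g, "metric": res.metric, "factors": res.factors}
            )
        except ValueError as exc:
            log.warning("anova %s: %s", g, exc)
    report["regressions"] = []
    for g in present:
        for response in ("postural_R_intensity", "postural_R_cf"):
            if response not in wide.columns:
                continue
            try:
                report["regressions"].append(
                    asdict(regress_vs_covariate(wide, g, response, "age"))
                )
            except ValueError as exc:
                log.warning("regression %s ~ age in %s: %s", response, g, exc)
    if normative is not None:
        report["fold_of_control"] = fold_of_control(wide, normative, present)
    return report


def fold_of_control(
    wide: pd.DataFrame, normative: pd.DataFrame, groups
) -> list[dict]:
    """Postural intensity expressed as a multiple of the healthy-control mean
    from a user-supplied normative table (averaged over its decades)."""
    control = float(normative["postural_intensity"].mean())
    out = []
    for g in groups:
        sub = wide[wide["group"] == g]
        for side in SIDES:
            col = f"postural_{side}_intensity"
            if col in sub.columns and sub[col].notna().any():
                out.append(
                    {
                        "group": g,
                        "side": side,
                        "mean_intensity": float(sub[col].mean()),
                        "control_mean": control,
                        "fold_of_control": float(sub[col].mean() / control),
                    }
                )
    return out


def symptom_panel_frame(counts=None) -> pd.DataFrame:
    """Fisher panel over a clinical-sign count table (defaults to the
    built-in welders-vs-IPD panel)."""
    results = table2_report(counts)
    return pd.DataFrame(
        [
            {
                "sign": r.label,
                "group1_affected": r.a,
                "group1_unaffected": r.b,
                "group2_affected": r.c,
                "group2_unaffected": r.d,
                "odds_ratio": r.odds_ratio,
                "continuity_corrected": r.continuity_corrected,
                "p_value": r.p_value,
            }
            for r in results
        ]
    )


def classification_report(wide: pd.DataFrame, rule: ClassifierRule | None = None) -> dict:
    rule = rule or ClassifierRule()
    classified = classify_cohort(wide, rule)
    out: dict = {
        "rule": asdict(rule),
        "classifications": classified.to_dict(orient="records"),
    }
    if "group" in wide.columns:
        ev = evaluate_classifier(wide, rule)
        out["evaluation"] = {
            "accuracy": ev.accuracy,
            "recall": ev.recall,
            "n": ev.n,
            "confusion": ev.confusion.to_dict(),
        }
    return out
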