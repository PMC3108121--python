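"""Rule-based three-group tremor classifier.

Operationalises the qualitative discrimination pattern of the three cohorts
as an explicit decision tree over three per-subject features (each averaged
over the available sides):

1. postural/rest intensity ratio below ``postural_ratio_threshold`` AND
   postural Cf below ``cf_postural_threshold``  →  **IPD**
   (parkinsonian tremor does not intensify with the arms extended and
   oscillates slowly);
2. otherwise, rest Cf at or above ``cf_rest_threshold``  →  **WELDER**
   (manganese-exposed welders keep a fast rest tremor);
3. otherwise  →  **ET**
   (essential tremor intensifies posturally but rests slowly).

The default thresholds (6.5 Hz, 1.5, 6.5 Hz) sit in the gaps between the
published group means (ET rest Cf ≈ 5.8–6.0 Hz vs welders ≈ 7.0–7.6 Hz; IPD
postural Cf ≈ 6.1–6.3 Hz with a fold change near 1).  The three branches
partition feature space, so every subject with at least one complete side is
classified, and the fired branch is recorded in the trace.

This is a descriptive re-expression of group-level findings, not a
validated diagnostic: only the intensity *ratio* enters, so the decision is
invariant to a common rescaling of accelerations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import BAND, GROUPS, SIDES
from .spectral import TremorMetrics


@dataclass(frozen=True)
class ClassifierRule:
    cf_rest_threshold: float = 6.5  # Hz
    postural_ratio_threshold: float = 1.5
    cf_postural_threshold: float = 6.5  # Hz

    def __post_init__(self) -> None:
        for name in ("cf_rest_threshold", "cf_postural_threshold"):
            v = getattr(self, name)
            if not BAND[0] < v < BAND[1]:
                raise ValueError(f"{name} must lie inside the {BAND} Hz band")
        if self.postural_ratio_threshold <= 0:
            raise ValueError("postural_ratio_threshold must be positive")


DEFAULT_RULE = ClassifierRule()


@dataclass(frozen=True)
class Classification:
    subject_id: str
    features: dict[str, float]
    predicted: str
    trace: str


def subject_features(
    metrics: dict[tuple[str, str], "TremorMetrics | dict"],
) -> dict[str, float]:
    """Side-averaged classifier features from per-cell metrics.

    ``metrics`` maps (condition, side) to a TremorMetrics (or a mapping with
    ``intensity``/``cf`` entries); sides may be missing, but at least one
    side must carry both conditions.
    """

    def get(cell, name):
        m = metrics.get(cell)
        if m is None:
            return None
        v = getattr(m, name, None)
        if v is None and isinstance(m, dict):
            v = m.get(name)
        return v

    ratios, rest_cfs, post_cfs = [], [], []
    for side in SIDES:
        rest_i = get(("rest", side), "intensity")
        post_i = get(("postural", side), "intensity")
        if rest_i is not None and post_i is not None and rest_i > 0:
            ratios.append(post_i / rest_i)
        rc = get(("rest", side), "cf")
        if rc is not None:
            rest_cfs.append(rc)
        pc = get(("postural", side), "cf")
        if pc is not None:
            post_cfs.append(pc)
    if not ratios or not rest_cfs or not post_cfs:
        raise ValueError(
            "classification needs rest and postural metrics for at least one side"
        )
    return {
        "rest_cf": float(np.mean(rest_cfs)),
        "postural_cf": float(np.mean(post_cfs)),
        "intensity_ratio": float(np.mean(ratios)),
    }


def classify_features(
    features: dict[str, float], rule: ClassifierRule = DEFAULT_RULE, subject_id: str = ""
) -> Classification:
    ratio = features["intensity_ratio"]
    rest_cf = features["rest_cf"]
    post_cf = features["postural_cf"]
    if ratio < rule.postural_ratio_threshold and post_cf < rule.cf_postural_threshold:
        predicted = "IPD"
        trace = (
            f"ratio {ratio:.2f} < {rule.postural_ratio_threshold} and postural "
            f"Cf {post_cf:.2f} < {rule.cf_postural_threshold} Hz -> IPD"
        )
    elif rest_cf >= rule.cf_rest_threshold:
        predicted = "WELDER"
        trace = f"rest Cf {rest_cf:.2f} >= {rule.cf_rest_threshold} Hz -> WELDER"
    else:
        predicted = "ET"
        trace = f"rest Cf {rest_cf:.2f} < {rule.cf_rest_threshold} Hz -> ET"
    return Classification(
        subject_id=subject_id, features=dict(features), predicted=predicted, trace=trace
    )


def classify_subject(
    metrics: dict[tuple[str, str], "TremorMetrics | dict"],
    rule: ClassifierRule = DEFAULT_RULE,
    subject_id: str = "",
) -> Classification:
    """Classify one subject from per condition × side metrics."""
    return classify_features(subject_features(metrics), rule, subject_id)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationReport:
    confusion: pd.DataFrame  # rows true group, columns predicted
    accuracy: float
    recall: dict[str, float]
    n: int


def classify_cohort(
    cohort: pd.DataFrame, rule: ClassifierRule = DEFAULT_RULE, metric_prefix: str = ""
) -> pd.DataFrame:
    """Classify every row of a cohort metrics table.

    Expects columns ``{condition}_{side}_intensity`` and
    ``{condition}_{side}_cf`` (optionally with a prefix, e.g. ``target_``);
    returns a frame with features, prediction and trace per subject.
    """
    rows = []
    for _, row in cohort.iterrows():
        metrics = {}
        for condition in ("rest", "postural"):
            for side in SIDES:
                icol = f"{condition}_{side}_{metric_prefix}intensity"
                ccol = f"{condition}_{side}_{metric_prefix}cf"
                if icol in row.index and pd.notna(row[icol]):
                    metrics[(condition, side)] = {
                        "intensity": row[icol],
                        "cf": row[ccol] if ccol in row.index else None,
                    }
        cls = classify_subject(metrics, rule, subject_id=str(row.get("subject_id", "")))
        rows.append(
            {
                "subject_id": cls.subject_id,
                **cls.features,
                "predicted": cls.predicted,
                "trace": cls.trace,
                **({"group": row["group"]} if "group" in row.index else {}),
            }
        )
    return pd.DataFrame(rows)


def evaluate_classifier(
    cohort: pd.DataFrame, rule: ClassifierRule = DEFAULT_RULE, metric_prefix: str = ""
) -> EvaluationReport:
    """Confusion matrix, per-group recall and overall accuracy on a labelled
    cohort metrics table."""
    if "group" not in cohort.columns:
        raise ValueError("cohort must carry true labels in a 'group' column")
    classified = classify_cohort(cohort, rule, metric_prefix)
    confusion = pd.crosstab(
        classified["group"], classified["predicted"], dropna=False
    ).reindex(index=list(GROUPS), columns=list(GROUPS), fill_value=0)
    correct = sum(confusion.loc[g, g] for g in GROUPS if g in confusion.index)
    n = int(confusion.to_numpy().sum())
    recall = {}
    for g in GROUPS:
        row_total = int(confusion.loc[g].sum()) if g in confusion.index else 0
        recall[g] = float(confusion.loc[g, g] / row_total) if row_total else float("nan")
    return EvaluationReport(
        confusion=confusion,
        accuracy=float(correct / n) if n else float("nan"),
        recall=recall,
        n=n,
    )
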