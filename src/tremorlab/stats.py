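"""Cohort-level statistics for tremor metrics and clinical signs.

Covers the statistical layer of a three-group tremor study: group summaries
(mean ± SEM per metric × condition × side), rest-vs-postural fold changes
with paired t-tests, two-way fixed-effects ANOVA (arm position × side) with
percent-of-variance decomposition, exact two-sided Fisher tests on 2×2
clinical-sign tables, and ordinary least-squares regressions of tremor
metrics on age or exposure covariates.

No multiple-testing correction is applied: every contingency row and
regression is reported per-test, and reports carry a note saying so.

Cohort tables are pandas DataFrames with one row per subject, a ``group``
column, and metric columns named ``{condition}_{side}_{metric}`` (conditions
``rest``/``postural``, sides ``R``/``L``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .archetypes import SYMPTOM_COUNTS
from .records import CONDITIONS, SIDES

MULTIPLE_TESTING_NOTE = (
    "p-values are reported per test without multiple-comparison correction"
)


def _column(condition: str, side: str, metric: str) -> str:
    return f"{condition}_{side}_{metric}"


# ---------------------------------------------------------------------------
# group summaries


def summarize_groups(
    cohort: pd.DataFrame,
    metrics: tuple[str, ...] = ("intensity", "cf", "dispersion", "hi"),
    groups: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Mean ± SEM per metric × group × condition × side.

    SEM = sd/sqrt(n) (ddof=1); for n=1 the SEM is 0 by convention and the
    row is flagged in the ``degenerate`` column.
    """
    if groups is None:
        groups = tuple(pd.unique(cohort["group"]))
    rows = []
    for group in groups:
        sub = cohort[cohort["group"] == group]
        if sub.empty:
            raise ValueError(f"no subjects in group {group!r}")
        for metric in metrics:
            for condition in CONDITIONS:
                for side in SIDES:
                    col = _column(condition, side, metric)
                    if col not in cohort.columns:
                        continue
                    vals = sub[col].dropna()
                    n = len(vals)
                    if n == 0:
                        continue
                    sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
                    rows.append(
                        {
                            "metric": metric,
                            "group": group,
                            "condition": condition,
                            "side": side,
                            "n": n,
                            "mean": float(vals.mean()),
                            "sem": sem,
                            "degenerate": n == 1,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fold change


@dataclass(frozen=True)
class FoldChangeResult:
    group: str
    side: str
    rest_mean: float
    postural_mean: float
    ratio: float
    t_statistic: float
    p_value: float
    n_pairs: int


def fold_change_from_means(postural_mean: float, rest_mean: float) -> float:
    """Postural/rest ratio of group means (the published fold changes)."""
    if rest_mean <= 0:
        raise ValueError("rest mean must be positive")
    return postural_mean / rest_mean


def fold_change(
    cohort: pd.DataFrame, group: str, side: str, metric: str = "intensity"
) -> FoldChangeResult:
    """Ratio of group means (postural/rest) plus a paired t-test across
    subjects with both conditions recorded on that side."""
    sub = cohort[cohort["group"] == group]
    rest = sub[_column("rest", side, metric)]
    post = sub[_column("postural", side, metric)]
    ok = rest.notna() & post.notna()
    rest, post = rest[ok].to_numpy(float), post[ok].to_numpy(float)
    if len(rest) < 2:
        raise ValueError(
            f"fewer than 2 complete rest/postural pairs for {group} side {side}"
        )
    diffs = post - rest
    if np.allclose(diffs, 0.0):
        t, p = 0.0, 1.0  # identical conditions: no evidence of change
    else:
        t, p = sps.ttest_rel(post, rest)
    return FoldChangeResult(
        group=group,
        side=side,
        rest_mean=float(rest.mean()),
        postural_mean=float(post.mean()),
        ratio=fold_change_from_means(float(post.mean()), float(rest.mean())),
        t_statistic=float(t),
        p_value=float(p),
        n_pairs=len(rest),
    )


# ---------------------------------------------------------------------------
# two-way ANOVA (arm position × side)


@dataclass(frozen=True)
class AnovaResult:
    """Percent of total sum of squares, F and p per factor.

    ``factors`` maps {position, side, interaction, residual} to
    (percent_variance, F, p); F/p are NaN for the residual row.
    """

    group: str
    metric: str
    factors: dict[str, tuple[float, float, float]]

    @property
    def percent_total(self) -> float:
        return sum(v[0] for v in self.factors.values())


def two_way_anova(
    cohort: pd.DataFrame, group: str, metric: str = "intensity"
) -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction on the four
    condition × side observations per subject, pooled across subjects.

    Percent variance is each factor's share of the total sum of squares
    (eta-squared × 100); the shares, including the residual, sum to 100.
    """
    sub = cohort[cohort["group"] == group]
    if sub.empty:
        raise ValueError(f"no subjects in group {group!r}")
    cols = {
        (c, s): _column(c, s, metric) for c in CONDITIONS for s in SIDES
    }
    missing = [
        sid
        for sid, row in sub.iterrows()
        for col in cols.values()
        if pd.isna(row[col])
    ]
    if missing:
        raise ValueError(
            f"incomplete condition×side grid for subjects {sorted(set(missing))}"
        )
    long = pd.DataFrame(
        {
            "value": np.concatenate([sub[col].to_numpy(float) for col in cols.values()]),
            "position": np.repeat([c for c, _ in cols], len(sub)),
            "side": np.repeat([s for _, s in cols], len(sub)),
        }
    )
    model = smf.ols("value ~ C(position) * C(side)", data=long).fit()
    table = anova_lm(model, typ=2)
    ss = table["sum_sq"]
    total = float(ss.sum())
    if total == 0:
        raise ValueError("metric has zero total variance")
    name_map = {
        "C(position)": "position",
        "C(side)": "side",
        "C(position):C(side)": "interaction",
        "Residual": "residual",
    }
    factors = {}
    for raw, name in name_map.items():
        pct = 100.0 * float(ss[raw]) / total
        f = float(table.loc[raw, "F"]) if name != "residual" else float("nan")
        p = float(table.loc[raw, "PR(>F)"]) if name != "residual" else float("nan")
        factors[name] = (pct, f, p)
    return AnovaResult(group=group, metric=metric, factors=factors)


# ---------------------------------------------------------------------------
# Fisher's exact test (exact rational arithmetic)


@dataclass(frozen=True)
class ContingencyResult:
    """2×2 table [[a, b], [c, d]], odds ratio and two-sided Fisher p.

    When a cell is zero the odds ratio is computed with 0.5 added to every
    cell (flagged via ``continuity_corrected``); the p-value is never
    corrected.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    continuity_corrected: bool
    label: str = ""


def fisher_exact_2x2(a: int, b: int, c: int, d: int, label: str = "") -> ContingencyResult:
    """Two-sided Fisher's exact test with exact rational summation.

    p = sum of hypergeometric probabilities (margins fixed) of all tables
    whose point probability is <= that of the observed table.  Computed with
    integer binomials and a Fraction total, so ties are resolved exactly.
    """
    for v in (a, b, c, d):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError("counts must be non-negative integers")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        raise ValueError("Fisher test undefined for an all-zero margin")
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # numerators of the hypergeometric pmf over the common denominator C(n, c1)
    numerators = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    observed = numerators[a - lo]
    total = sum(numerators)
    p = Fraction(sum(w for w in numerators if w <= observed), total)
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = (v + 0.5 for v in (a, b, c, d))
        odds = (aa * dd) / (bb * cc)
        corrected = True
    else:
        odds = (a * d) / (b * c)
        corrected = False
    return ContingencyResult(
        a=int(a), b=int(b), c=int(c), d=int(d),
        odds_ratio=float(odds),
        p_value=float(p),
        continuity_corrected=corrected,
        label=label,
    )


def table2_report(
    counts: dict[str, tuple[int, int, int, int]] | None = None,
) -> list[ContingencyResult]:
    """Fisher results for a clinical-sign panel.

    ``counts`` maps sign -> (affected_1, examined_1, affected_2, examined_2);
    defaults to the built-in welders-vs-IPD symptom panel.  Per-sign
    denominators are honoured (complete-case per row).
    """
    if counts is None:
        counts = SYMPTOM_COUNTS
    results = []
    for sign, (a, n1, b, n2) in counts.items():
        if a > n1 or b > n2:
            raise ValueError(f"{sign}: affected exceeds examined")
        results.append(fisher_exact_2x2(a, n1 - a, b, n2 - b, label=sign))
    return results


# ---------------------------------------------------------------------------
# regression


@dataclass(frozen=True)
class RegressionResult:
    group: str
    response: str
    predictor: str
    slope: float  # response units per year
    intercept: float
    p_value: float  # two-sided, slope = 0
    r_squared: float
    n: int


def regress_vs_covariate(
    cohort: pd.DataFrame, group: str, response: str, predictor: str
) -> RegressionResult:
    """OLS of a tremor metric on a per-subject covariate, with the two-sided
    t-test of slope = 0 (the published age/exposure regressions)."""
    sub = cohort[cohort["group"] == group]
    x = sub[predictor]
    y = sub[response]
    ok = x.notna() & y.notna()
    x, y = x[ok].to_numpy(float), y[ok].to_numpy(float)
    if len(x) < 3 or len(np.unique(x)) < 3:
        raise ValueError(
            f"need >= 3 subjects with distinct {predictor!r} values in {group}"
        )
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {predictor!r} is constant")
    if np.ptp(y) == 0:
        # flat response: the fitted line is exactly horizontal
        return RegressionResult(
            group=group, response=response, predictor=predictor,
            slope=0.0, intercept=float(y[0]), p_value=1.0, r_squared=0.0,
            n=len(x),
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        group=group,
        response=response,
        predictor=predictor,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        p_value=float(model.pvalues[1]),
        r_squared=float(model.rsquared),
        n=len(x),
    )
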