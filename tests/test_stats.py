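"""Cohort statistics: summaries, fold changes, ANOVA, Fisher, regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import tremorlab as tl
from tremorlab.stats import (
    fisher_exact_2x2,
    fold_change,
    fold_change_from_means,
    regress_vs_covariate,
    summarize_groups,
    table2_report,
    two_way_anova,
)

from conftest import SUITE_SEED


def tiny_cohort():
    """Three hand-built subjects with known metric values."""
    rows = []
    for sid, group, vals in [
        ("A", "WELDER", (1.0, 2.0, 1.5, 2.5)),
        ("B", "WELDER", (2.0, 3.0, 2.5, 3.5)),
        ("C", "WELDER", (3.0, 4.0, 3.5, 4.5)),
    ]:
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "rest_R_intensity": vals[0],
                "postural_R_intensity": vals[1],
                "rest_L_intensity": vals[2],
                "postural_L_intensity": vals[3],
                "rest_R_cf": 7.0,
                "postural_R_cf": 7.0,
                "rest_L_cf": 7.0,
                "postural_L_cf": 7.0,
            }
        )
    return pd.DataFrame(rows)


class TestSummaries:
    def test_hand_computed_mean_and_sem(self):
        out = summarize_groups(tiny_cohort(), metrics=("intensity",))
        row = out[(out.condition == "rest") & (out.side == "R")].iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sem"] == pytest.approx(1.0 / np.sqrt(3))
        assert row["n"] == 3 and not row["degenerate"]

    def test_single_subject_sem_zero_flagged(self):
        out = summarize_groups(tiny_cohort().head(1), metrics=("intensity",))
        assert (out["sem"] == 0).all()
        assert out["degenerate"].all()

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError, match="ET"):
            summarize_groups(tiny_cohort(), groups=("ET",))


class TestFoldChange:
    def test_published_group_mean_ratios(self):
        assert fold_change_from_means(1.61, 0.774) == pytest.approx(2.08, abs=0.005)
        assert fold_change_from_means(0.599, 0.124) == pytest.approx(4.83, abs=0.01)

    def test_cohort_fold_change_and_paired_t(self):
        res = fold_change(tiny_cohort(), "WELDER", "R")
        assert res.ratio == pytest.approx(3.0 / 2.0)
        # constant +1 shift: paired t degenerate in variance -> huge t
        assert res.p_value < 0.05 or np.isnan(res.t_statistic)

    def test_identical_conditions_give_unity_and_p_one(self):
        df = tiny_cohort()
        df["postural_R_intensity"] = df["rest_R_intensity"]
        res = fold_change(df, "WELDER", "R")
        assert res.ratio == 1.0 and res.p_value == 1.0

    def test_ratio_scale_invariance(self):
        df = tiny_cohort()
        scaled = df.copy()
        for col in df.columns:
            if col.endswith("intensity"):
                scaled[col] = df[col] * 3.7
        assert fold_change(scaled, "WELDER", "L").ratio == pytest.approx(
            fold_change(df, "WELDER", "L").ratio, rel=1e-12
        )

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fold_change(tiny_cohort().head(1), "WELDER", "R")


class TestAnova:
    def make_cohort(self, n=40, pos_effect=0.0, side_effect=0.0, noise=1.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            base = rng.normal(0, noise)
            rows.append(
                {
                    "subject_id": f"S{i}",
                    "group": "WELDER",
                    "rest_R_intensity": base + rng.normal(0, noise),
                    "rest_L_intensity": base + side_effect + rng.normal(0, noise),
                    "postural_R_intensity": base + pos_effect + rng.normal(0, noise),
                    "postural_L_intensity": base + pos_effect + side_effect + rng.normal(0, noise),
                }
            )
        return pd.DataFrame(rows)

    def test_percent_variance_partition_sums_to_100(self):
        res = two_way_anova(self.make_cohort(pos_effect=1.0, side_effect=0.5), "WELDER")
        assert res.percent_total == pytest.approx(100.0, abs=0.01)

    def test_hand_computed_sum_of_squares(self):
        """Brute-force 2x2 decomposition on a balanced design."""
        df = self.make_cohort(n=25, pos_effect=2.0, seed=3)
        res = two_way_anova(df, "WELDER")
        y = np.concatenate(
            [
                df[f"{c}_{s}_intensity"].to_numpy()
                for c in ("rest", "postural")
                for s in ("R", "L")
            ]
        )
        pos = np.repeat([0, 0, 1, 1], len(df))
        side = np.repeat([0, 1, 0, 1], len(df))
        grand = y.mean()
        ss_total = np.sum((y - grand) ** 2)
        ss_pos = sum(
            (y[pos == v].mean() - grand) ** 2 * np.sum(pos == v) for v in (0, 1)
        )
        ss_side = sum(
            (y[side == v].mean() - grand) ** 2 * np.sum(side == v) for v in (0, 1)
        )
        cell_means = {
            (p, s): y[(pos == p) & (side == s)].mean() for p in (0, 1) for s in (0, 1)
        }
        ss_int = sum(
            len(df)
            * (
                cell_means[(p, s)]
                - y[pos == p].mean()
                - y[side == s].mean()
                + grand
            )
            ** 2
            for p in (0, 1)
            for s in (0, 1)
        )
        assert res.factors["position"][0] == pytest.approx(100 * ss_pos / ss_total, rel=1e-9)
        assert res.factors["side"][0] == pytest.approx(100 * ss_side / ss_total, rel=1e-9)
        assert res.factors["interaction"][0] == pytest.approx(100 * ss_int / ss_total, rel=1e-9)

    def test_null_case_small_factor_shares(self):
        res = two_way_anova(self.make_cohort(n=150, seed=5), "WELDER")
        for factor in ("position", "side", "interaction"):
            assert res.factors[factor][0] < 2.0

    def test_injected_position_effect_detected(self):
        res = two_way_anova(self.make_cohort(n=80, pos_effect=3.0, seed=6), "WELDER")
        assert res.factors["position"][2] < 1e-6
        assert res.factors["position"][0] > res.factors["side"][0]

    def test_missing_cells_listed(self):
        df = self.make_cohort(n=5)
        df.loc[2, "postural_L_intensity"] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            two_way_anova(df, "WELDER")


class TestFisher:
    def test_symmetric_table_p_is_one(self):
        assert fisher_exact_2x2(5, 10, 5, 10).p_value == pytest.approx(1.0)

    def test_matches_scipy_on_known_rows(self):
        res = fisher_exact_2x2(19, 12, 9, 7)
        ref = sps.fisher_exact([[19, 12], [9, 7]])[1]
        assert res.p_value == pytest.approx(ref, rel=1e-9)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_scipy_enumeration(self, a, b, c, d):
        """Exact rational two-sided p equals the library hypergeometric
        enumeration wherever the test is defined."""
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            with pytest.raises(ValueError):
                fisher_exact_2x2(a, b, c, d)
            return
        mine = fisher_exact_2x2(a, b, c, d).p_value
        ref = sps.fisher_exact([[a, b], [c, d]])[1]
        assert mine == pytest.approx(ref, rel=1e-8, abs=1e-12)

    def test_odds_ratio_continuity_flag(self):
        res = fisher_exact_2x2(7, 25, 0, 17)
        assert res.continuity_corrected
        assert res.odds_ratio == pytest.approx((7.5 * 17.5) / (25.5 * 0.5))
        plain = fisher_exact_2x2(19, 12, 9, 7)
        assert not plain.continuity_corrected

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 5)


class TestSymptomPanel:
    def test_builtin_panel_has_all_rows(self):
        results = table2_report()
        assert len(results) == len(tl.SYMPTOM_COUNTS) == 14
        by_label = {r.label: r for r in results}
        assert round(by_label["resting_tremor"].p_value, 2) == 0.76

    def test_symmetric_proportions_p_one(self):
        res = table2_report({"x": (5, 10, 10, 20)})
        assert res[0].p_value == pytest.approx(1.0)

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            table2_report({"x": (9, 5, 1, 5)})


class TestRegression:
    def make_cohort(self, x, y, group="WELDER"):
        return pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(len(x))],
                "group": group,
                "age": x,
                "postural_R_intensity": y,
            }
        )

    def test_noiseless_line_recovered_exactly(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = regress_vs_covariate(
            self.make_cohort(x, 2 * x + 1), "WELDER", "postural_R_intensity", "age"
        )
        assert res.slope == pytest.approx(2.0, abs=1e-10)
        assert res.intercept == pytest.approx(1.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(SUITE_SEED)
        x = rng.uniform(30, 70, 25)
        y = 0.01 * x + rng.normal(0, 0.3, 25)
        res = regress_vs_covariate(
            self.make_cohort(x, y), "WELDER", "postural_R_intensity", "age"
        )
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.intercept == pytest.approx(beta[0], rel=1e-9)
        assert res.slope == pytest.approx(beta[1], rel=1e-9)

    def test_constant_response_slope_zero(self):
        res = regress_vs_covariate(
            self.make_cohort(np.arange(5.0), np.full(5, 0.7)),
            "WELDER", "postural_R_intensity", "age",
        )
        assert res.slope == 0.0 and res.r_squared == 0.0

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            regress_vs_covariate(
                self.make_cohort(np.full(5, 50.0), np.arange(5.0)),
                "WELDER", "postural_R_intensity", "age",
            )
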