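"""Summary tables, ANOVA, Tukey/BH pairwise comparisons, robustness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tracheoguide import trial_stats as ts


def _two_group_df(a, b, labels=("A", "B"), outcome="y", factor="g"):
    return pd.DataFrame(
        {
            outcome: np.concatenate([a, b]),
            factor: [labels[0]] * len(a) + [labels[1]] * len(b),
        }
    )


class TestSummarize:
    def test_hand_computed_moments_and_iqr(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0], "g": ["a"] * 4})
        table = ts.summarize(df, "y", "g")
        row = table.iloc[0]
        assert row["count"] == 4
        assert row["mean"] == 2.5
        assert row["median"] == 2.5
        assert row["iqr"] == pytest.approx(1.5)  # linear-interpolation quartiles

    def test_identical_groups_zero_mean_difference(self):
        df = _two_group_df([1.0, 2, 3], [1.0, 2, 3])
        table = ts.summarize(df, "y", "g")
        assert table["mean_difference"].dropna().iloc[0] == 0.0

    def test_mean_difference_between_named_groups(self):
        df = _two_group_df([13.0, 14.0], [3.0, 3.96], labels=("NO", "YES"))
        table = ts.summarize(df, "y", "g", diff_between=("NO", "YES"))
        assert table["mean_difference"].dropna().iloc[0] == pytest.approx(
            13.5 - 3.48, abs=1e-12
        )

    def test_empty_group_flagged(self):
        df = pd.DataFrame({"y": [1.0], "g": ["a"]})
        df = pd.concat([df, pd.DataFrame({"y": [], "g": []})])
        table = ts.summarize(df, "y", "g")
        assert (table["count"] >= 1).all()  # empty levels simply absent

    def test_abandoned_attempts_excluded_from_time_summaries(self):
        df = pd.DataFrame(
            {
                "time_to_target": [10.0, 20.0, 300.0],
                "g": ["a", "a", "a"],
                "abandoned": [False, False, True],
            }
        )
        table = ts.summarize(df, "time_to_target", "g")
        assert table.iloc[0]["count"] == 2
        assert table.iloc[0]["mean"] == 15.0


class TestOmnibus:
    def test_balanced_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)
        res = ts.omnibus(_two_group_df(a, b), "y", "g")
        from scipy.stats import ttest_ind

        t, p = ttest_ind(a, b)
        assert res.statistic == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_three_group_hand_sums_of_squares(self):
        # small worked example: between/within sums of squares by hand
        groups = {"g1": [6.0, 8, 4, 5, 3, 4], "g2": [8.0, 12, 9, 11, 6, 8],
                  "g3": [13.0, 9, 11, 8, 7, 12]}
        df = pd.DataFrame(
            {
                "y": sum(groups.values(), []),
                "g": sum([[k] * 6 for k in groups], []),
            }
        )
        grand = np.mean(df["y"])
        ss_between = sum(6 * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(
            sum((x - np.mean(v)) ** 2 for x in v) for v in groups.values()
        )
        f_oracle = (ss_between / 2) / (ss_within / 15)
        res = ts.omnibus(df, "y", "g")
        assert res.statistic == pytest.approx(f_oracle, rel=1e-10)

    def test_type3_equals_classical_on_balanced_single_factor(self, rng):
        a, b, c = (rng.normal(m, 1, 9) for m in (0, 0.5, 1.0))
        df = pd.DataFrame(
            {"y": np.concatenate([a, b, c]), "g": ["a"] * 9 + ["b"] * 9 + ["c"] * 9}
        )
        classical = ts.omnibus(df, "y", "g")
        type3 = ts.type3_anova(df, "y", "g")
        assert type3.statistic == pytest.approx(classical.statistic, abs=1e-8)

    def test_unbalanced_data_takes_type3_branch(self, rng):
        df = _two_group_df(rng.normal(0, 1, 10), rng.normal(1, 1, 17))
        res = ts.omnibus(df, "y", "g")
        assert "type-III" in res.test_name
        assert res.note == "unbalanced groups"

    def test_degenerate_variance_names_group(self):
        df = _two_group_df([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="degenerate"):
            ts.omnibus(df, "y", "g")

    def test_too_few_groups_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "g": ["a", "a"]})
        with pytest.raises(ValueError):
            ts.omnibus(df, "y", "g")


def _bh_oracle(pvals):
    """Hand step-up: sort, p(i)*m/i, enforce monotonicity from the largest."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


class TestBenjaminiHochberg:
    def test_equally_spaced_pvalues_all_adjust_to_largest(self):
        adj = ts.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_comparison_unchanged(self):
        assert ts.bh_adjust([0.0123])[0] == pytest.approx(0.0123)

    @given(
        pvals=st.lists(st.floats(1e-6, 1.0, allow_nan=False), min_size=1, max_size=12)
    )
    def test_matches_hand_step_up_and_is_monotone(self, pvals):
        adj = ts.bh_adjust(pvals)
        assert np.allclose(adj, _bh_oracle(pvals), atol=1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0)

    @given(
        pvals=st.lists(st.floats(1e-6, 1.0, allow_nan=False), min_size=1, max_size=8)
    )
    def test_order_preserving(self, pvals):
        # step-up adjustment never reorders evidence
        raw = np.asarray(pvals)
        adj = ts.bh_adjust(pvals)
        idx = np.argsort(raw, kind="stable")
        assert np.all(np.diff(adj[idx]) >= -1e-12)


class TestPairwise:
    def test_all_pairs_present_with_adjustment(self, rng):
        df = pd.DataFrame(
            {
                "y": rng.normal(0, 1, 30),
                "g": ["a"] * 10 + ["b"] * 10 + ["c"] * 10,
            }
        )
        table = ts.pairwise(df, "y", "g")
        assert len(table) == 3
        assert (table["p_adjusted"] >= table["p_tukey"] - 1e-12).all()

    def test_identical_groups_not_significant(self, rng):
        vals = rng.normal(5, 1, 16)
        df = _two_group_df(vals, vals)
        table = ts.pairwise(df, "y", "g")
        assert table["p_adjusted"].iloc[0] > 0.05

    def test_single_group_empty_table(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "g": ["a", "a"]})
        assert ts.pairwise(df, "y", "g").empty


class TestRobustness:
    def test_heteroscedastic_groups_trigger_welch_branch(self, rng):
        # variance ratio 9:1 between groups
        df = _two_group_df(rng.normal(0, 3, 40), rng.normal(0, 1, 40))
        table, trace = ts.robustness(df, "y", "g")
        assert "Welch ANOVA" in set(table["test"])
        assert any("Welch" in line for line in trace)

    def test_homoscedastic_groups_skip_welch(self, rng):
        # equal spread by construction: same draws, shifted location
        vals = rng.normal(0, 1, 40)
        df = _two_group_df(vals, vals + 0.5)
        table, trace = ts.robustness(df, "y", "g")
        assert "Welch ANOVA" not in set(table["test"])
        assert any("not taken" in line for line in trace)

    def test_identical_groups_kruskal_h_near_zero(self):
        vals = np.arange(12.0)
        df = _two_group_df(vals, vals)
        table, _ = ts.robustness(df, "y", "g")
        h = float(table.loc[table["test"] == "Kruskal-Wallis", "statistic"].iloc[0])
        assert h == pytest.approx(0.0, abs=1e-6)

    def test_two_group_dataset_has_wilcoxon_row(self, rng):
        df = _two_group_df(rng.normal(0, 1, 10), rng.normal(0, 1, 10))
        table, _ = ts.robustness(df, "y", "g")
        assert "Wilcoxon rank-sum" in set(table["test"])

    def test_tiny_group_skips_shapiro_with_note(self):
        df = _two_group_df([1.0, 2.0], [1.0, 5.0, 3.0, 4.0])
        table, trace = ts.robustness(df, "y", "g")
        skipped = table[(table["test"] == "Shapiro-Wilk") & (table["note"] != "")]
        assert len(skipped) == 1
        assert any("skipped" in line for line in trace)

    def test_pipeline_detects_guidance_effect_on_simulated_data(self, small_trial_df):
        """Guided vs unguided accuracy difference should be detected by the
        omnibus test even on a tiny 2-participant trial."""
        df = small_trial_df.copy()
        df["guidance"] = np.where(df["guided"], "GUIDED", "UNGUIDED")
        res = ts.omnibus(df, "final_radial_distance", "guidance")
        assert res.p_value < 0.05
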