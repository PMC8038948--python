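import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from smlmpair import (
    aggregate_cells_to_replicates,
    generalized_omega_squared,
    rm_anova,
    windsorize,
)


class TestWindsorize:
    def test_sub_threshold_point_untouched(self):
        # z of 10 in [1,2,3,10] is (10-4)/4.0825 ~ 1.47 < 2.25
        out = windsorize(np.array([1.0, 2.0, 3.0, 10.0]))
        assert out.tolist() == [1.0, 2.0, 3.0, 10.0]

    def test_extreme_point_pulled_to_nearest_remaining(self):
        # z of 6 among nine 1s is ~2.85 >= 2.25
        sample = np.array([1.0] * 9 + [6.0])
        out = windsorize(sample)
        assert out.tolist() == [1.0] * 10

    def test_low_outlier_pulled_up(self):
        sample = np.array([10.0] * 9 + [-5.0])
        out = windsorize(sample)
        assert out.tolist() == [10.0] * 10

    def test_identical_sample_unchanged(self):
        out = windsorize(np.array([3.0, 3.0, 3.0, 3.0]))
        assert out.tolist() == [3.0] * 4

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            windsorize(np.array([1.0, 2.0]))

    @given(
        st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=3, max_size=30)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_never_widens_range_changes_at_most_one(self, values):
        arr = np.array(values)
        out = windsorize(arr)
        assert out.min() >= arr.min() and out.max() <= arr.max()
        assert (out != arr).sum() <= 1


def toy_table():
    return pd.DataFrame(
        {
            "replicate": [1, 2, 3] * 2,
            "cond": ["a"] * 3 + ["b"] * 3,
            "v": [1.0, 2.0, 3.0, 2.0, 4.0, 6.0],
        }
    )


class TestRmAnova:
    def test_null_effect_gives_zero_F(self):
        df = toy_table()
        df["v"] = [1.0, 2.0, 3.0] * 2  # identical per replicate across conditions
        res = rm_anova(df, "v", within=["cond"])
        row = res.table.set_index("term").loc["cond"]
        assert row["SS"] == pytest.approx(0.0)
        assert row["F"] == pytest.approx(0.0)

    def test_matches_reference_implementation(self):
        from statsmodels.stats.anova import AnovaRM

        df = toy_table()
        res = rm_anova(df, "v", within=["cond"])
        ref = AnovaRM(df, "v", "replicate", within=["cond"]).fit().anova_table
        row = res.table.set_index("term").loc["cond"]
        assert row["F"] == pytest.approx(ref.loc["cond", "F Value"], abs=1e-8)
        assert row["p"] == pytest.approx(ref.loc["cond", "Pr > F"], abs=1e-8)

    def test_omega_squared_matches_hand_derivation(self):
        # exact decomposition of the toy table: SS_cond=6, SS_rep=9, SS_err=1
        # sigma2_cond = (6-0.5)/6 = 11/12, sigma2_rep = (4.5-0.5)/2 = 2,
        # residual MS = 1/2 -> omega2_g = (11/12)/(11/12 + 2 + 1/2) = 11/41
        res = rm_anova(toy_table(), "v", within=["cond"])
        w = res.table.set_index("term").loc["cond", "omega2_g"]
        assert w == pytest.approx(11 / 41, abs=1e-12)

    def test_F_equals_squared_paired_t_for_two_levels(self, rng):
        vals = rng.random(10)
        df = pd.DataFrame(
            {
                "replicate": list(range(5)) * 2,
                "cond": ["a"] * 5 + ["b"] * 5,
                "v": vals,
            }
        )
        res = rm_anova(df, "v", within=["cond"])
        t = sps.ttest_rel(vals[:5], vals[5:]).statistic
        assert res.table.set_index("term").loc["cond", "F"] == pytest.approx(t**2)

    def test_two_within_factors_match_reference(self, rng):
        from statsmodels.stats.anova import AnovaRM

        reps, f1, f2 = 4, ["x", "y"], ["u", "v", "w"]
        rows = [
            {"replicate": r, "A": a, "B": b, "v": rng.random()}
            for r in range(reps)
            for a in f1
            for b in f2
        ]
        df = pd.DataFrame(rows)
        res = rm_anova(df, "v", within=["A", "B"])
        ref = AnovaRM(df, "v", "replicate", within=["A", "B"]).fit().anova_table
        got = res.table.set_index("term")
        for ours, theirs in [("A", "A"), ("B", "B"), ("A:B", "A:B")]:
            assert got.loc[ours, "F"] == pytest.approx(ref.loc[theirs, "F Value"], abs=1e-8)
            assert got.loc[ours, "p"] == pytest.approx(ref.loc[theirs, "Pr > F"], abs=1e-8)

    def test_between_factor_F_matches_oneway_on_subject_means(self, rng):
        rows = [
            {"replicate": r, "grp": g, "cond": c, "v": rng.random() + (1.0 if g == "g2" else 0)}
            for g in ["g1", "g2"]
            for r in range(4)
            for c in ["a", "b"]
        ]
        df = pd.DataFrame(rows)
        res = rm_anova(df, "v", within=["cond"], between="grp")
        subj_means = df.groupby(["grp", "replicate"])["v"].mean().reset_index()
        ref = sps.f_oneway(
            subj_means.loc[subj_means["grp"] == "g1", "v"],
            subj_means.loc[subj_means["grp"] == "g2", "v"],
        )
        got = res.table.set_index("term").loc["grp"]
        assert got["F"] == pytest.approx(ref.statistic, abs=1e-8)
        assert got["p"] == pytest.approx(ref.pvalue, abs=1e-8)

    def test_row_order_invariance(self, rng):
        df = toy_table()
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = rm_anova(df, "v", within=["cond"]).table
        b = rm_anova(shuffled, "v", within=["cond"]).table
        pd.testing.assert_frame_equal(a, b)

    def test_df_sum_to_n_minus_one(self, rng):
        rows = [
            {"replicate": r, "A": a, "B": b, "v": rng.random()}
            for r in range(3)
            for a in ["x", "y"]
            for b in ["u", "v"]
        ]
        res = rm_anova(pd.DataFrame(rows), "v", within=["A", "B"])
        assert res.table["df"].sum() == len(rows) - 1

    def test_unbalanced_table_rejected(self):
        df = toy_table().iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova(df, "v", within=["cond"])

    def test_single_replicate_rejected(self):
        df = pd.DataFrame(
            {"replicate": [1, 1], "cond": ["a", "b"], "v": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="replicates"):
            rm_anova(df, "v", within=["cond"])

    def test_zero_interaction_reports_infinite_F(self):
        df = toy_table()
        df["v"] = [1.0, 2.0, 3.0, 2.0, 3.0, 4.0]  # constant shift, zero interaction
        with pytest.warns(UserWarning, match="zero error mean square"):
            res = rm_anova(df, "v", within=["cond"])
        row = res.table.set_index("term").loc["cond"]
        assert np.isinf(row["F"]) and row["p"] == 0.0


class TestGeneralizedOmegaSquared:
    def test_null_effect_is_negative(self):
        # zero main effect but nonzero interaction: MS_effect < MS_error
        df = pd.DataFrame(
            {
                "replicate": [1, 2, 3] * 2,
                "cond": ["a"] * 3 + ["b"] * 3,
                "v": [0.0, 1.0, 0.5, 1.0, 0.0, 0.5],
            }
        )
        res = rm_anova(df, "v", within=["cond"])
        row = res.table.set_index("term").loc["cond"]
        assert row["F"] == pytest.approx(0.0)
        assert row["omega2_g"] < 0

    def test_huge_effect_approaches_one(self):
        df = pd.DataFrame(
            {
                "replicate": [1, 2, 3] * 2,
                "cond": ["a"] * 3 + ["b"] * 3,
                "v": [0.0, 1e-6, 2e-6, 100.0, 100.000001, 100.000002],
            }
        )
        res = rm_anova(df, "v", within=["cond"])
        assert res.table.set_index("term").loc["cond", "omega2_g"] > 0.99

    def test_recomputable_from_result(self):
        res = rm_anova(toy_table(), "v", within=["cond"])
        again = generalized_omega_squared(res)
        pd.testing.assert_series_equal(again, res.table["omega2_g"], check_names=False)


class TestAggregate:
    def test_means_per_replicate_condition(self):
        cells = pd.DataFrame(
            {
                "replicate": [1, 1, 1, 1],
                "cond": ["a", "a", "b", "b"],
                "v": [1.0, 3.0, 10.0, 20.0],
            }
        )
        out = aggregate_cells_to_replicates(cells, "v", factors=["cond"])
        assert out.set_index("cond")["v"].to_dict() == {"a": 2.0, "b": 15.0}

    def test_single_cell_groups_pass_through(self):
        cells = toy_table()
        out = aggregate_cells_to_replicates(cells, "v", factors=["cond"])
        assert len(out) == len(cells)

    def test_missing_condition_raises(self):
        cells = pd.DataFrame(
            {
                "replicate": [1, 1, 2],
                "cond": ["a", "b", "a"],
                "v": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(ValueError, match="unbalanced"):
            aggregate_cells_to_replicates(cells, "v", factors=["cond"])
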