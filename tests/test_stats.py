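"""Group-comparison statistics against hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lfpcoupling import (
    DataError,
    ParameterError,
    box_stats,
    compare_from_summary,
    one_way_anova_tukey,
    repeated_measures_anova,
    significance_stars,
)
from lfpcoupling.stats import pairwise_unadjusted


def group_table(groups: dict) -> pd.DataFrame:
    rows = []
    for g, values in groups.items():
        for i, v in enumerate(values):
            rows.append({"group": g, "subject": f"{g}{i}", "value": float(v)})
    return pd.DataFrame(rows)


class TestOneWayAnova:
    def test_identical_groups_f_zero_nothing_significant(self):
        table = group_table({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4],
                             "c": [1, 2, 3, 4]})
        result = one_way_anova_tukey(table)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert all(s == "ns" for s in result.pairwise["stars"])

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(0)
        table = group_table({"a": rng.normal(0, 0.01, 4),
                             "b": 10 + rng.normal(0, 0.01, 4)})
        assert one_way_anova_tukey(table).p_value < 0.001

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        table = group_table({"a": rng.normal(0, 1, 8),
                             "b": rng.normal(0.8, 1, 8)})
        result = one_way_anova_tukey(table)
        a = table.loc[table.group == "a", "value"]
        b = table.loc[table.group == "b", "value"]
        t, _ = sps.ttest_ind(a, b)
        assert result.statistic == pytest.approx(t**2, abs=1e-9)

    def test_tukey_adjusted_at_least_unadjusted(self):
        rng = np.random.default_rng(2)
        table = group_table({g: rng.normal(m, 1, 8)
                             for g, m in zip("abc", (0.0, 0.6, 1.0))})
        result = one_way_anova_tukey(table)
        unadj = pairwise_unadjusted(table)
        for (_, tk), (_, un) in zip(result.pairwise.iterrows(),
                                    unadj.iterrows()):
            assert tk["p-adj"] >= un["p"] - 1e-9

    def test_underpopulated_group_rejected(self):
        with pytest.raises(DataError):
            one_way_anova_tukey(group_table({"a": [1.0], "b": [1, 2, 3]}))


class TestRepeatedMeasures:
    def test_matches_hand_sums_of_squares(self):
        values = {"s1": [1.0, 2.0, 3.0], "s2": [2.0, 3.0, 5.0],
                  "s3": [0.0, 1.0, 2.0]}
        rows = [{"subject": s, "day": d, "value": v}
                for s, vv in values.items() for d, v in enumerate(vv)]
        result = repeated_measures_anova(pd.DataFrame(rows))
        X = np.array(list(values.values()))
        grand = X.mean()
        ss_time = X.shape[0] * ((X.mean(0) - grand) ** 2).sum()
        ss_subj = X.shape[1] * ((X.mean(1) - grand) ** 2).sum()
        ss_err = ((X - grand) ** 2).sum() - ss_time - ss_subj
        f_hand = (ss_time / 2) / (ss_err / 4)
        assert result.statistic == pytest.approx(f_hand, rel=1e-9)
        assert result.df == (2.0, 4.0)

    def test_flat_subjects_give_zero_f(self):
        rows = [{"subject": s, "day": d, "value": float(i)}
                for i, s in enumerate("abc") for d in range(3)]
        result = repeated_measures_anova(pd.DataFrame(rows))
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_single_subject_rejected(self):
        rows = [{"subject": "s1", "day": d, "value": float(d)}
                for d in range(3)]
        with pytest.raises(DataError):
            repeated_measures_anova(pd.DataFrame(rows))

    def test_missing_cell_names_subject_and_day(self):
        rows = [{"subject": s, "day": d, "value": 1.0}
                for s in ("s1", "s2") for d in range(3)][:-1]
        with pytest.raises(DataError, match="s2"):
            repeated_measures_anova(pd.DataFrame(rows))

    def test_group_by_time_effects_reported_for_mixed_design(self):
        rng = np.random.default_rng(3)
        rows = []
        for g, offset in (("wt", 0.0), ("ad", 2.0)):
            for s in range(4):
                for d in range(3):
                    rows.append({"group": g, "subject": f"{g}{s}", "day": d,
                                 "value": rng.normal(d + offset, 0.5)})
        result = repeated_measures_anova(pd.DataFrame(rows))
        assert result.test_name == "mixed_anova"
        assert "F_group" in result.extras


class TestCompareFromSummary:
    def test_water_maze_day1_wt_vs_ad_significant(self):
        # printed day-1 escape latencies: 44.34 +/- 7.98 vs 57.04 +/- 3.01, n=8
        result = compare_from_summary([44.34, 57.04], [7.98, 3.01], [8, 8])
        assert result.p_value < 0.01

    def test_identical_means_t_zero_p_one(self):
        result = compare_from_summary([5.0, 5.0], [1.0, 1.0], [8, 8])
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_doubling_sds_shrinks_t(self):
        r1 = compare_from_summary([0.0, 1.0], [1.0, 1.0], [8, 8])
        r2 = compare_from_summary([0.0, 1.0], [2.0, 2.0], [8, 8])
        assert abs(r2.statistic) < abs(r1.statistic)

    def test_matches_raw_data_pooled_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1.2, 12)
        result = compare_from_summary(
            [a.mean(), b.mean()], [a.std(ddof=1), b.std(ddof=1)], [10, 12])
        t_raw, _ = sps.ttest_ind(a, b)
        assert result.statistic == pytest.approx(t_raw, abs=1e-9)

    def test_three_group_f_matches_raw_anova(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(m, 1, 8) for m in (0.0, 0.5, 1.2)]
        result = compare_from_summary(
            [g.mean() for g in groups], [g.std(ddof=1) for g in groups],
            [8, 8, 8])
        f_raw, p_raw = sps.f_oneway(*groups)
        assert result.statistic == pytest.approx(f_raw, rel=1e-9)
        assert result.p_value == pytest.approx(p_raw, rel=1e-9)

    def test_small_n_rejected(self):
        with pytest.raises(ParameterError):
            compare_from_summary([1.0, 2.0], [1.0, 1.0], [1, 8])


class TestBoxStats:
    def test_one_to_nine_quartiles(self):
        b = box_stats(range(1, 10))
        assert (b.median, b.q1, b.q3, b.iqr) == (5.0, 3.0, 7.0, 4.0)
        assert (b.whisker_low, b.whisker_high) == (1.0, 9.0)
        assert b.outliers.size == 0

    def test_constant_values_degenerate(self):
        b = box_stats([2.5] * 6)
        assert b.median == b.whisker_low == b.whisker_high == 2.5
        assert b.iqr == 0.0
        assert b.outliers.size == 0

    def test_extreme_point_reported_as_outlier(self):
        b = box_stats(list(range(1, 10)) + [100])
        assert list(b.outliers) == [100.0]
        assert b.whisker_high == 9.0

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            box_stats([])


def test_star_thresholds():
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"
    assert significance_stars(0.2) == "ns"
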