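"""Descriptives, cross-tabulation, effect sizes and CV variability."""

import math

import numpy as np
import pandas as pd
import pytest

from pufftopo import (
    UndefinedStatisticError,
    cohen_d,
    crosstab,
    cv_table,
    demographic_puff_distribution,
    describe,
    effect_size_report,
    eta_squared,
    join_cohort,
    round_half_up,
    user_cv,
)
from pufftopo.fixtures import table1_fixture_cohort, table2_fixture_puffs

# Published percentage matrices used as frozen expectations for the
# cross-tabulation machinery (bins x power settings, and per-factor
# participant/puff shares).
TABLE2_PCT = pd.DataFrame(
    {"low": [3.90, 5.43, 2.48, 4.05],
     "medium": [0.43, 19.28, 10.39, 9.24],
     "high": [0.00, 30.36, 2.59, 11.84]},
    index=["zero", "low", "medium", "high"])

TABLE1_PCT = {
    "sex": {"female": (50.82, 49.21), "male": (47.54, 50.35),
            "prefer_not_to_say": (1.64, 0.45)},
    "age_band": {"18-25": (11.48, 4.64), "26-35": (26.23, 28.99),
                 "36-55": (54.10, 46.07), ">=56": (8.20, 20.30)},
    "smoking_history": {"yes": (37.70, 53.21), "no": (11.48, 13.78),
                        "missing": (50.82, 33.01)},
    "ends_years_band": {"6mo-1y": (6.56, 11.51), "1-5y": (42.62, 25.60),
                        "6-10y": (37.70, 47.36), ">10y": (9.84, 15.38),
                        "missing": (3.28, 0.14)},
}


class TestDescribe:
    def test_single_value(self):
        s = describe([3.44])
        assert (s["mean"], s["sd"], s["se"], s["n"]) == (3.44, 0.0, 0.0, 1)

    def test_hand_computed(self):
        s = describe([2, 4, 6])
        assert s["mean"] == 4 and s["sd"] == pytest.approx(2.0)
        assert s["se"] == pytest.approx(2 / math.sqrt(3))

    def test_empty_summary(self):
        assert describe([])["n"] == 0

    def test_generator_duration_contract(self, default_cohort):
        """Cohort-wide duration mean lands near the configured target."""
        s = describe(default_cohort.puffs["duration_s"])
        target = default_cohort.truth["duration_clipped_mean"]
        assert abs(s["mean"] - target) < 0.2  # adaptation ramp pulls it down


class TestCrossTab:
    def test_table2_reproduced_exactly(self):
        """The 12-cell power x concentration table reproduces at printed
        precision under half-up rounding."""
        xt = crosstab(table2_fixture_puffs(), "conc_bin", "power_setting")
        assert xt.grand_total == 118_947 and xt.n_excluded == 0
        pd.testing.assert_frame_equal(xt.pct(2), TABLE2_PCT, check_dtype=False,
                                      check_names=False)

    def test_counts_sum_to_grand_total(self):
        xt = crosstab(table2_fixture_puffs(), "conc_bin", "power_setting")
        assert int(xt.counts.to_numpy().sum()) == xt.grand_total

    def test_single_puff_is_100_percent(self):
        frame = pd.DataFrame({"power_setting": ["low"],
                              "nicotine_conc_mg_ml": [3.0]})
        xt = crosstab(frame, "conc_bin", "power_setting")
        assert xt.pct().loc["low", "low"] == 100.00

    def test_unresolvable_rows_excluded_and_counted(self):
        frame = pd.DataFrame({"power_setting": ["low", "high"],
                              "nicotine_conc_mg_ml": [3.0, np.nan]})
        xt = crosstab(frame, "conc_bin", "power_setting")
        assert xt.n_excluded == 1 and xt.grand_total == 1

    def test_denominator_all_uses_full_input(self):
        frame = pd.DataFrame({"power_setting": ["low", "high"],
                              "nicotine_conc_mg_ml": [3.0, np.nan]})
        xt = crosstab(frame, "conc_bin", denominator="all")
        assert xt.denominator_total == 2
        assert xt.pct().loc["low", "count"] == 50.00

    def test_percentages_sum_to_100_within_rounding(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame({
            "power_setting": rng.choice(["low", "medium", "high"], 500),
            "nicotine_conc_mg_ml": rng.choice([0, 3, 11, 18], 500)})
        xt = crosstab(frame, "conc_bin", "power_setting")
        n_cells = xt.counts.size
        assert abs(xt.pct().to_numpy().sum() - 100.0) <= 0.01 * n_cells

    def test_half_up_rounding_convention(self):
        assert round_half_up(3.895, 2) == 3.90
        assert round_half_up(46.4355, 2) == 46.44
        assert round_half_up(2.5, 0) == 3.0


def brute_force_eta_squared(values, groups):
    """Independent oracle: explicit sums of squares, no shortcuts."""
    pairs = list(zip(values, groups))
    grand = sum(v for v, _ in pairs) / len(pairs)
    ss_total = sum((v - grand) ** 2 for v, _ in pairs)
    ss_between = 0.0
    for g in set(groups):
        vals = [v for v, gg in pairs if gg == g]
        mean_g = sum(vals) / len(vals)
        ss_between += len(vals) * (mean_g - grand) ** 2
    return ss_between / ss_total


def brute_force_cohen_d(a, b):
    ma, mb = sum(a) / len(a), sum(b) / len(b)
    va = sum((x - ma) ** 2 for x in a) / (len(a) - 1)
    vb = sum((x - mb) ** 2 for x in b) / (len(b) - 1)
    pooled = math.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb)
                       / (len(a) + len(b) - 2))
    return (ma - mb) / pooled


class TestEtaSquared:
    def test_identical_group_means_give_zero(self):
        assert eta_squared([1, 2, 3, 1, 2, 3], list("aaabbb")) == pytest.approx(0.0)

    def test_hand_computed_two_groups(self):
        val = eta_squared([1, 2, 3, 4, 5, 6], list("aaabbb"))
        assert val == pytest.approx(13.5 / 17.5)

    def test_each_observation_own_group_gives_one(self):
        assert eta_squared([1, 2, 3], list("abc")) == pytest.approx(1.0)

    def test_single_group_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            eta_squared([1, 2, 3], list("aaa"))

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            eta_squared([5, 5, 5, 5], list("aabb"))

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = int(rng.integers(4, 20))
            vals = rng.normal(size=n)
            grp = rng.choice(list("abc"), size=n)
            if len(set(grp)) < 2:
                continue
            expected = brute_force_eta_squared(vals.tolist(), grp.tolist())
            assert eta_squared(vals, grp) == pytest.approx(expected, rel=1e-10)


class TestCohenD:
    def test_identical_groups_give_zero(self):
        assert cohen_d([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_hand_computed(self):
        assert cohen_d([2, 4], [5, 7]) == pytest.approx(-3 / math.sqrt(2))

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 15)
        assert cohen_d(a, b) == pytest.approx(-cohen_d(b, a))

    def test_zero_pooled_sd_with_different_means_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            cohen_d([1, 1], [2, 2])

    def test_hedges_correction_shrinks_d(self):
        a, b = [1.0, 2.0, 3.0], [3.0, 4.0, 5.0]
        assert abs(cohen_d(a, b, hedges_correction=True)) < abs(cohen_d(a, b))

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(13)
        for _ in range(300):
            a = rng.normal(size=int(rng.integers(2, 15)))
            b = rng.normal(1, 2, size=int(rng.integers(2, 15)))
            expected = brute_force_cohen_d(a.tolist(), b.tolist())
            assert cohen_d(a, b) == pytest.approx(expected, rel=1e-10)

    def test_recovery_of_known_standardized_shift(self):
        """Over 200 replicates cohen_d recovers the true shift within 3 SE."""
        rng = np.random.default_rng(17)
        delta = 0.6
        ests = np.array([cohen_d(rng.normal(delta, 1, 40), rng.normal(0, 1, 40))
                         for _ in range(200)])
        se = ests.std(ddof=1) / math.sqrt(len(ests))
        assert abs(ests.mean() - delta) <= 3 * se


class TestEffectSizeReport:
    def test_small_effects_suppressed_as_na(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0, 1, 200), rng.normal(0.1, 1, 200),
                               rng.normal(2.0, 1, 200)])
        grp = ["a"] * 200 + ["b"] * 200 + ["c"] * 200
        rep = effect_size_report(vals, grp, factor="toy")
        table = rep.table().set_index(["level_a", "level_b"])
        assert table.loc[("a", "b"), "cohen_d"] == "N/A"
        assert table.loc[("a", "c"), "cohen_d"] != "N/A"
        assert 0 <= rep.eta_squared <= 1


class TestUserCV:
    def test_constant_daily_counts_give_zero_cv(self):
        assert user_cv([100, 100, 100])[0] == pytest.approx(0.0)

    def test_hand_computed_cv(self):
        cv, _ = user_cv([1, 3])
        assert cv == pytest.approx(100 * math.sqrt(2) / 2)

    def test_single_active_day_undefined_with_reason(self):
        cv, reason = user_cv([42])
        assert np.isnan(cv) and "fewer than 2" in reason

    def test_duration_cv_concentrates_below_count_cv(self, default_cohort):
        """Daily duration varies far less within users than daily counts."""
        from pufftopo import add_emission, summarize_user_days

        summaries = summarize_user_days(add_emission(default_cohort.puffs))
        cvs = cv_table(summaries).dropna(subset=["count_cv_pct",
                                                 "duration_cv_pct"])
        assert cvs["duration_cv_pct"].median() < cvs["count_cv_pct"].median()
        assert (cvs["duration_cv_pct"] < 40).mean() > 0.8


class TestDemographicDistribution:
    @pytest.mark.parametrize("factor", list(TABLE1_PCT))
    def test_published_marginals_reproduced_exactly(self, factor):
        puffs, profiles = table1_fixture_cohort(factor)
        tables = demographic_puff_distribution(join_cohort(puffs, profiles),
                                               factors=(factor,))
        table = tables[factor]
        for level, (part_pct, puff_pct) in TABLE1_PCT[factor].items():
            assert table.loc[level, "participants_pct"] == part_pct, level
            assert table.loc[level, "puffs_pct"] == puff_pct, level

    def test_single_user_cohort_is_100_percent(self):
        puffs = pd.DataFrame({
            "device_id": ["u"] * 3,
            "timestamp": pd.Timestamp("2022-03-01"), "duration_s": 3.0,
            "power_setting": "low", "nicotine_conc_mg_ml": np.nan,
            "pg_vg_ratio": np.nan, "brand": np.nan})
        profiles = pd.DataFrame([{"device_id": "u", "sex": "female",
                                  "age_band": "36-55", "smoking_history": "yes",
                                  "ends_years_band": "6-10y"}])
        table = demographic_puff_distribution(
            join_cohort(puffs, profiles), factors=("sex",))["sex"]
        assert table.loc["female", "participants_pct"] == 100.00
        assert table.loc["female", "puffs_pct"] == 100.00
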