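"""Emission:burial ratios, biome comparisons and regional upscaling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lakecarbon.biome_stats import (
    compare_emissions_anova,
    compare_ratios_anova,
    compare_slopes_ancova,
    emission_burial_ratio,
    regress_emission_on_burial,
    upscale_emission,
)
from lakecarbon.synthetic import generate_biome_table


def table(boreal_pairs, arctic_pairs):
    rows = []
    for i, (e, b) in enumerate(boreal_pairs):
        rows.append({"lake_id": f"b{i}", "biome": "boreal",
                     "emission_gc_m2_yr": e, "burial_gc_m2_yr": b})
    for i, (e, b) in enumerate(arctic_pairs):
        rows.append({"lake_id": f"a{i}", "biome": "subarctic_arctic",
                     "emission_gc_m2_yr": e, "burial_gc_m2_yr": b})
    return pd.DataFrame(rows)


def brute_force_f(g1, g2):
    """Two-group one-way ANOVA from raw sums of squares."""
    allv = np.concatenate([g1, g2])
    grand = allv.mean()
    ssb = len(g1) * (g1.mean() - grand) ** 2 + len(g2) * (g2.mean() - grand) ** 2
    ssw = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
    dfw = len(allv) - 2
    return (ssb / 1) / (ssw / dfw)


class TestRatios:
    def test_equal_emission_and_burial_gives_unit_ratio(self):
        t = table([(5, 5), (8, 8)], [(3, 3), (4, 4)])
        _, summary = emission_burial_ratio(t)
        assert np.allclose(summary["mean"], 1.0)
        assert np.allclose(summary["sd"], 0.0)

    def test_mean_and_sd_hand_arithmetic(self):
        t = table([(4, 2), (16, 4)], [(1, 1), (1, 1)])  # boreal ratios 2 and 4
        _, summary = emission_burial_ratio(t)
        boreal = summary[summary["biome"] == "boreal"].iloc[0]
        assert boreal["mean"] == pytest.approx(3.0)
        assert boreal["sd"] == pytest.approx(np.sqrt(2.0))

    def test_zero_burial_excluded_not_infinite(self):
        t = table([(4, 2), (9, 0)], [(1, 1), (2, 1)])
        per_lake, _ = emission_burial_ratio(t)
        assert len(per_lake[per_lake["biome"] == "boreal"]) == 1

    def test_ratio_aggregation_is_per_lake_first(self):
        """Scaling one lake's emission must move only that lake's ratio
        (mean of ratios, never ratio of means)."""
        t1 = table([(4, 2), (6, 3)], [(1, 1), (2, 1)])
        t2 = table([(8, 2), (6, 3)], [(1, 1), (2, 1)])  # first lake doubled
        p1, _ = emission_burial_ratio(t1)
        p2, _ = emission_burial_ratio(t2)
        r1 = p1[p1["biome"] == "boreal"]["ratio"].to_numpy()
        r2 = p2[p2["biome"] == "boreal"]["ratio"].to_numpy()
        assert r2[0] == pytest.approx(2 * r1[0])
        assert r2[1] == pytest.approx(r1[1])

    def test_recovers_generated_target_means(self):
        df, truth = generate_biome_table(n_boreal=400, n_arctic=400, seed=5)
        _, summary = emission_burial_ratio(df)
        for _, row in summary.iterrows():
            target = truth["target_ratio_mean"][row["biome"]]
            sd = truth["target_ratio_sd"][row["biome"]]
            assert abs(row["mean"] - target) < 3 * sd / np.sqrt(row["n"])


class TestRatioAnova:
    def test_identical_groups_give_zero_f(self):
        t = table([(2, 1), (4, 1), (6, 1)], [(2, 1), (4, 1), (6, 1)])
        res = compare_ratios_anova(t, transform="none")
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_sums_of_squares(self):
        t = table([(1, 1), (2, 1), (3, 1)], [(7, 1), (8, 1), (9, 1)])
        res = compare_ratios_anova(t, transform="none")
        assert res.f_statistic == pytest.approx(
            brute_force_f(np.array([1.0, 2, 3]), np.array([7.0, 8, 9])), rel=1e-12
        )
        assert res.df_num == 1 and res.df_den == 4

    def test_f_equals_squared_pooled_t(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            g1 = rng.lognormal(1, 0.5, rng.integers(3, 10))
            g2 = rng.lognormal(2, 0.5, rng.integers(3, 10))
            t = table([(v, 1.0) for v in g1], [(v, 1.0) for v in g2])
            res = compare_ratios_anova(t, transform="none")
            tt = stats.ttest_ind(g1, g2, equal_var=True)
            assert res.f_statistic == pytest.approx(tt.statistic**2, rel=1e-9)

    def test_single_record_biome_rejected(self):
        t = table([(2, 1), (4, 1)], [(3, 1)])
        with pytest.raises(ValueError):
            compare_ratios_anova(t)


class TestRegression:
    def test_collinear_data_r2_one(self):
        t = table([(2, 1), (4, 2), (6, 3)], [(1, 1), (1, 1), (1, 1)])
        res = regress_emission_on_burial(t, "boreal")
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)

    def test_three_points_against_normal_equations(self):
        pts = [(3.0, 1.0), (4.5, 2.0), (9.0, 4.0)]
        t = table(pts, [(1, 1), (1, 1), (1, 1)])
        res = regress_emission_on_burial(t, "boreal")
        x = np.array([p[1] for p in pts])
        y = np.array([p[0] for p in pts])
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res["intercept"] == pytest.approx(beta[0], abs=1e-10)
        assert res["slope"] == pytest.approx(beta[1], abs=1e-10)

    def test_degenerate_predictor_rejected(self):
        t = table([(2, 1), (4, 1), (6, 1)], [(1, 1), (1, 1), (1, 1)])
        with pytest.raises(ValueError):
            regress_emission_on_burial(t, "boreal")


class TestAncova:
    def test_identical_slopes_are_not_flagged(self):
        rng = np.random.default_rng(6)
        x = np.linspace(1, 10, 20)
        t = table(
            list(zip(2 * x + 1 + rng.normal(0, 1, 20), x)),
            list(zip(2 * x + 5 + rng.normal(0, 1, 20), x)),
        )
        res = compare_slopes_ancova(t)
        assert res.p_value > 0.05
        assert res.group_means["boreal"] == pytest.approx(
            res.group_means["subarctic_arctic"], abs=0.3
        )

    def test_distinct_slopes_highly_significant(self):
        rng = np.random.default_rng(4)
        x = np.linspace(1, 10, 15)
        t = table(
            list(zip(3 * x + rng.normal(0, 0.01, 15), x)),
            list(zip(1 * x + rng.normal(0, 0.01, 15), x)),
        )
        res = compare_slopes_ancova(t)
        assert res.p_value < 1e-6
        assert res.group_means["boreal"] == pytest.approx(3.0, abs=0.01)

    def test_missing_biome_rejected(self):
        t = table([(2, 1), (4, 2), (6, 3)], [])
        with pytest.raises(ValueError):
            compare_slopes_ancova(t)


class TestEmissionAnova:
    def test_accepts_unpaired_records(self):
        t = table([(5, 1), (6, 1), (7, 1)], [(2, 1), (2.5, 1), (3, 1)])
        t.loc[0, "burial_gc_m2_yr"] = np.nan  # unpaired record still counts
        res = compare_emissions_anova(t)
        assert res.p_value < 0.05


class TestUpscaling:
    def test_unit_arithmetic(self):
        out = upscale_emission(15.0, 0.0, 2e12)
        assert out["flux_tg_c_yr"] == pytest.approx(30.0, rel=1e-12)

    def test_zero_area(self):
        assert upscale_emission(15.0, 5.0, 0.0)["flux_tg_c_yr"] == 0.0

    def test_linearity(self):
        a = upscale_emission(10.0, 5.0, 1e12)
        b = upscale_emission(20.0, 10.0, 2e12)
        assert b["flux_tg_c_yr"] == pytest.approx(4 * a["flux_tg_c_yr"], rel=1e-12)
        assert b["uncertainty_tg_c_yr"] == pytest.approx(4 * a["uncertainty_tg_c_yr"], rel=1e-12)

    def test_se_convention(self):
        out = upscale_emission(10.0, 8.0, 1e12, n=16, uncertainty="se")
        assert out["uncertainty_tg_c_yr"] == pytest.approx(2.0, rel=1e-12)
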