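"""Floating-chamber flux estimators and ebullition partitioning."""

import numpy as np
import pytest

from lakecarbon.chamber_flux import (
    ChamberDeployment,
    R_J,
    chamber_flux_mass_balance,
    chamber_flux_regression,
    lake_period_mean_flux,
    partition_ebullition,
    select_estimator,
)


def make_deployment(ppm, elapsed=None, volume=0.01, area=0.07, temp=20.0,
                    pressure=1013.25, ctype="total"):
    ppm = np.asarray(ppm, dtype=float)
    elapsed = np.linspace(0, 48, len(ppm)) if elapsed is None else np.asarray(elapsed)
    return ChamberDeployment(
        lake_id="L", chamber_id="c1", chamber_type=ctype, volume_m3=volume,
        area_m2=area, elapsed_h=elapsed, ch4_ppm=ppm, air_temp_c=temp,
        pressure_hpa=pressure,
    )


class TestRegressionEstimator:
    def test_flat_series_gives_zero(self):
        assert chamber_flux_regression(make_deployment([5.0] * 5)) == pytest.approx(0.0, abs=1e-12)

    def test_linear_rise_worked_example(self):
        # 10 ppm/h rise: flux = slope * P * V / (R * T * A), converted to per day
        elapsed = np.array([0.0, 12.0, 24.0, 36.0, 48.0])
        dep = make_deployment(2.0 + 10.0 * elapsed, elapsed=elapsed)
        slope_mol_h = 10e-6 * 101325.0 * 0.01 / (R_J * 293.15)
        expected = slope_mol_h * 24.0 / 0.07 * 1e3
        assert expected == pytest.approx(1.43, abs=0.01)
        assert chamber_flux_regression(dep) == pytest.approx(expected, rel=1e-10)

    def test_doubling_volume_doubles_flux(self):
        elapsed = np.linspace(0, 48, 5)
        f1 = chamber_flux_regression(make_deployment(10 * elapsed, elapsed=elapsed, volume=0.01))
        f2 = chamber_flux_regression(make_deployment(10 * elapsed, elapsed=elapsed, volume=0.02))
        assert f2 == pytest.approx(2 * f1, rel=1e-12)

    def test_two_points_fall_back_to_mass_balance(self):
        dep = make_deployment([2.0, 50.0], elapsed=[0.0, 48.0])
        assert chamber_flux_regression(dep) == pytest.approx(
            chamber_flux_mass_balance(dep), rel=1e-12
        )


class TestMassBalanceEstimator:
    def test_no_change_gives_zero(self):
        assert chamber_flux_mass_balance(make_deployment([7.0, 3.0, 7.0])) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_regression_on_exactly_linear_data(self):
        elapsed = np.linspace(0, 48, 6)
        dep = make_deployment(5 + 3.7 * elapsed, elapsed=elapsed)
        assert chamber_flux_mass_balance(dep) == pytest.approx(
            chamber_flux_regression(dep), rel=1e-10
        )

    def test_endpoint_difference_oracle_on_noisy_series(self):
        rng = np.random.default_rng(3)
        ppm = np.abs(rng.normal(50, 20, 5))
        dep = make_deployment(ppm)
        n = dep.moles()
        expected = (n[-1] - n[0]) / (0.07 * 48.0) * 24.0 * 1e3
        assert chamber_flux_mass_balance(dep) == pytest.approx(expected, rel=1e-12)


class TestEstimatorSelection:
    # water at 1e-3 mol/m3 CH4 ~ equilibrium headspace of a few hundred ppm
    WATER = 1e-3

    def test_chamber_below_equilibrium_uses_regression(self):
        dep = make_deployment([2, 50, 100, 150, 200])
        _, method = select_estimator(dep, self.WATER)
        assert method == "regression"

    def test_bubble_driven_chamber_uses_mass_balance(self):
        dep = make_deployment([2, 50, 100, 900, 950])
        _, method = select_estimator(dep, self.WATER)
        assert method == "mass_balance"

    def test_exact_equilibrium_keeps_regression(self):
        from lakecarbon.gas_physics import CH4, equilibrium_partial_pressure

        p_eq = equilibrium_partial_pressure(CH4, self.WATER, 20.0)
        dep = make_deployment([2.0, p_eq / 2, p_eq])
        _, method = select_estimator(dep, self.WATER)
        assert method == "regression"


class TestPartition:
    def test_equal_means_give_zero_ebullition(self):
        out = partition_ebullition([2.0, 2.0], [2.0])
        assert out["ebullitive"] == 0.0
        assert not out["floored"]

    def test_subtraction(self):
        out = partition_ebullition([4.0, 6.0], [1.0, 3.0])
        assert out["diffusive"] == pytest.approx(2.0)
        assert out["ebullitive"] == pytest.approx(3.0)

    def test_negative_difference_floored_and_flagged(self):
        out = partition_ebullition([1.0], [2.0])
        assert out["ebullitive"] == 0.0
        assert out["floored"]

    def test_no_shielded_chambers_leaves_partition_undefined(self):
        out = partition_ebullition([5.0], [])
        assert not out["ebullition_defined"]
        assert out["diffusive"] == pytest.approx(5.0)  # total passed through


class TestSpatialMean:
    def test_uniform_fluxes_under_any_weighting(self):
        zones = {"shallow": [3.0, 3.0], "deep": [3.0]}
        weights = {"shallow": 0.6, "deep": 0.4}
        assert lake_period_mean_flux(zones, weights, "area") == pytest.approx(3.0)
        assert lake_period_mean_flux(zones, weights, "arithmetic") == pytest.approx(3.0)

    def test_area_weighting_worked_example(self):
        zones = {"a": [2.0], "b": [6.0]}
        assert lake_period_mean_flux(zones, {"a": 0.75, "b": 0.25}, "area") == pytest.approx(3.0)

    def test_arithmetic_mean_on_same_input(self):
        zones = {"a": [2.0], "b": [6.0]}
        assert lake_period_mean_flux(zones, None, "arithmetic") == pytest.approx(4.0)

    def test_weighted_zone_without_chambers_errors(self):
        with pytest.raises(ValueError):
            lake_period_mean_flux({"a": [2.0]}, {"a": 0.5, "b": 0.5}, "area")


def test_partition_identity_total_equals_components():
    """total = diffusive + ebullitive holds up to the documented floor."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        totals = rng.uniform(0, 5, 4)
        shields = rng.uniform(0, 5, 2)
        out = partition_ebullition(totals, shields)
        if not out["floored"]:
            assert out["diffusive"] + out["ebullitive"] == pytest.approx(
                np.mean(totals), rel=1e-12
            )
        else:
            assert out["ebullitive"] == 0.0


def test_recovered_period_means_cover_truth_on_synthetic_deployments(noisy_lake):
    """With noise and Poisson bubbles, the recovered lake-period means stay
    within 2 standard errors of the generator truth."""
    from lakecarbon.pipeline import ch4_period_means, lake_hypsometry

    scenario, dataset, _ = noisy_lake
    hyps = lake_hypsometry(dataset)
    means, _ = ch4_period_means(dataset, hyps)
    # truth per period: diffusive + expected bubble load, area-weighted
    from lakecarbon.synthetic import basin_area_at_depth

    w_deep = basin_area_at_depth(
        scenario.shape, scenario.surface_area_m2, scenario.max_depth_m,
        scenario.zone_edge_depth_m,
    ) / scenario.surface_area_m2
    bubble_flux = (
        scenario.ebullition_events_per_day * scenario.bubble_moles
        / scenario.chamber_area_m2 * 1e3
    )
    expected = (
        (1 - w_deep) * scenario.ch4_diffusive_mmol_m2_d["shallow"]
        + w_deep * scenario.ch4_diffusive_mmol_m2_d["deep"]
        + bubble_flux
    )
    vals = np.array(list(means.values()))
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - expected) < 2 * max(se, 0.1 * expected)
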