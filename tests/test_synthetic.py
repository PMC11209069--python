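"""Synthetic-site generation, the time-stepping oracle, and parameter recovery."""

import numpy as np
import pytest

from hgbalance import build_d_values, solve_steady_state
from hgbalance.errors import DomainError, SteadyStateError
from hgbalance.synthetic import (
    DEFAULT_RANGES,
    generate_site,
    oracle_solve,
    oracle_steady_state,
    recovery_experiment,
    scenario_from_json,
    scenario_to_json,
)


def test_generation_is_deterministic_in_seed():
    a = generate_site(123)
    b = generate_site(123)
    assert a.site == b.site and a.inputs == b.inputs and a.params == b.params
    assert a.ground_truth.water_thg_ng_L == b.ground_truth.water_thg_ng_L
    c = generate_site(124)
    assert c.site != a.site


def test_generated_scenarios_satisfy_invariants():
    for seed in range(10):
        sc = generate_site(seed)
        assert sc.site.area_km2 > 0 and sc.site.mean_depth_m > 0
        assert 0 <= sc.site.resuspension_fraction <= 1
        assert sum(sc.params.species_ratios.water) == pytest.approx(1.0, abs=1e-12)
        gt = sc.ground_truth
        assert gt.water_thg_ng_L >= 0 and gt.sediment_thg_ng_g >= 0
        assert abs(gt.closure_residual_relative) < 1e-8


def test_point_mass_ranges_pin_parameters_to_the_azov_values(soa):
    site, _inputs, params = soa
    pinned = {
        "area_km2": (39_000.0, 39_000.0),
        "mean_depth_m": (7.0, 7.0),
        "outflow_velocity_m_yr": (site.seawater_outflow_km3_yr * 1e3 / 39_000.0,) * 2,
        "precipitation_mm_yr": (397.0, 397.0),
        "water_tss_mg_L": (19.1, 19.1),
        "sedimentation_rate_g_m2_day": (1.66, 1.66),
        "resuspension_fraction": (0.64, 0.64),
        "kd_L_g": (params.kd_L_g,) * 2,
        "k_vol_m_h": (params.k_vol_m_h,) * 2,
        "scavenging_ratio": (params.scavenging_ratio,) * 2,
        "f_hg0_water": (0.02, 0.02),
        "rain_thg_ng_L": (240.0, 240.0),
    }
    sc = generate_site(0, pinned)
    assert sc.site.area_km2 == 39_000.0
    assert sc.site.mean_depth_m == 7.0
    assert sc.site.seawater_outflow_km3_yr == pytest.approx(54.4, rel=1e-12)
    assert sc.site.water_tss_mg_L == 19.1
    assert sc.site.resuspension_fraction == 0.64
    assert sc.params.kd_L_g == params.kd_L_g
    assert sc.params.species_ratios.fraction_hg0_water == 0.02
    assert sc.inputs.atmospheric_thg_ng_m3 == pytest.approx(6.0, rel=1e-9)


def test_invalid_ranges_rejected():
    with pytest.raises(DomainError):
        generate_site(0, {"kd_L_g": (10.0, 1.0)})
    with pytest.raises(DomainError):
        generate_site(0, {"resuspension_fraction": (0.5, 1.5)})
    with pytest.raises(DomainError):
        generate_site(0, {"not_a_parameter": (0.0, 1.0)})


def test_oracle_matches_analytic_solver_on_the_azov_fixture(soa, soa_solution):
    site, _inputs, params = soa
    sol, loads, d = soa_solution
    oracle = oracle_solve(loads, d, site, params)
    assert oracle.water_thg_ng_L == pytest.approx(sol.water_thg_ng_L, rel=1e-3)
    assert oracle.sediment_thg_ng_g == pytest.approx(sol.sediment_thg_ng_g, rel=1e-3)


def test_oracle_dilution_box_limit():
    from hgbalance import ModelParameters
    from hgbalance.config import soa_site
    from hgbalance.loadings import LoadingBudget

    site = soa_site().model_copy(update={"sedimentation_rate_g_m2_day": 0.0})
    params = ModelParameters(kd_L_g=0.0, k_vol_m_h=0.0, scavenging_ratio=1.0)
    d = build_d_values(site, params)
    loads = LoadingBudget(wet_deposition_kg_yr=544.0, riverine_total_kg_yr=0.0)
    oracle = oracle_solve(loads, d, site, params)
    assert oracle.water_thg_ng_L == pytest.approx(10.0, rel=1e-6)


def test_oracle_zero_load_converges_to_zero(soa):
    site, _inputs, params = soa
    from hgbalance.loadings import LoadingBudget

    d = build_d_values(site, params)
    sol = oracle_solve(LoadingBudget(0.0, 0.0), d, site, params)
    assert sol.water_thg_ng_L == 0.0 and sol.sediment_thg_ng_g == 0.0


def test_oracle_detects_missing_steady_state():
    from hgbalance import ModelParameters
    from hgbalance.config import soa_site
    from hgbalance.loadings import LoadingBudget

    site = soa_site().model_copy(
        update={"sedimentation_rate_g_m2_day": 0.0, "seawater_outflow_km3_yr": 0.0}
    )
    params = ModelParameters(kd_L_g=0.0, k_vol_m_h=0.0, scavenging_ratio=1.0)
    with pytest.raises(SteadyStateError):
        oracle_solve(
            LoadingBudget(1.0, 0.0), build_d_values(site, params), site, params
        )


def test_oracle_agrees_with_solver_across_scenarios():
    for seed in range(25):
        sc = generate_site(seed)
        d = build_d_values(sc.site, sc.params)
        analytic = solve_steady_state(sc.loads, d, sc.site, sc.params)
        truth = sc.ground_truth
        assert analytic.water_thg_ng_L == pytest.approx(truth.water_thg_ng_L, rel=1e-3)
        assert analytic.sediment_thg_ng_g == pytest.approx(truth.sediment_thg_ng_g, rel=1e-3)


def test_oracle_steady_state_reproduces_ground_truth():
    sc = generate_site(5)
    again = oracle_steady_state(sc)
    assert again.water_thg_ng_L == sc.ground_truth.water_thg_ng_L


def test_recovery_is_exact_on_noise_free_data():
    table, summary = recovery_experiment(20, seed=11)
    assert summary["kd_L_g"] < 1e-6
    assert summary["k_vol_m_h"] < 1e-9
    assert summary["scavenging_ratio"] < 1e-9
    assert table.rel_error.max() < 1e-6


def test_recovery_degrades_gracefully_under_one_percent_noise():
    _table, summary = recovery_experiment(30, seed=11, noise_sd=0.01)
    for name, err in summary.items():
        assert err < 0.05, name


def test_recovery_requires_at_least_one_scenario():
    with pytest.raises(DomainError):
        recovery_experiment(0, seed=1)


def test_scenario_json_round_trip(tmp_path):
    sc = generate_site(42)
    path = tmp_path / "scenario.json"
    scenario_to_json(sc, path)
    back = scenario_from_json(path)
    assert back.seed == 42
    assert back.site == sc.site
    assert back.params.kd_L_g == sc.params.kd_L_g
    assert back.ground_truth.water_thg_ng_L == sc.ground_truth.water_thg_ng_L
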