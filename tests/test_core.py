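"""Partitioning, species multipliers, D-values and the closed-form solver."""

import dataclasses

import pytest
from hypothesis import given, strategies as st

from hgbalance import (
    DomainError,
    DValueSet,
    LoadingBudget,
    SpeciesRatios,
    SteadyStateError,
    apply_species_multipliers,
    build_d_values,
    partition_water,
    solve_steady_state,
)
from hgbalance.config import soa_site
from hgbalance.core import EXTERNAL_EFFLUXES, SPECIES


# ---------------------------------------------------------------- partition

def test_partition_reproduces_reported_sediment_concentration():
    state = partition_water(6.8, 9.69, 0.0191)
    assert state.particle_concentration_ng_g == pytest.approx(55.6, rel=1e-3)
    assert state.fraction_dissolved == pytest.approx(0.844, abs=1e-3)


def test_partition_limits():
    no_sorption = partition_water(123.0, 0.0, 0.5)
    assert no_sorption.fraction_dissolved == 1.0
    assert no_sorption.particle_concentration_ng_g == 0.0
    half = partition_water(10.0, 1.0, 1.0)
    assert half.fraction_dissolved == 0.5
    assert half.particle_concentration_ng_g == pytest.approx(5.0)


def test_partition_rejects_negative_inputs_naming_field():
    with pytest.raises(DomainError, match="kd_L_g"):
        partition_water(1.0, -1.0, 0.1)
    with pytest.raises(DomainError, match="tss_g_L"):
        partition_water(1.0, 1.0, -0.1)


@given(
    total=st.floats(min_value=0, max_value=1e4),
    kd=st.floats(min_value=0, max_value=1e3),
    tss=st.floats(min_value=0, max_value=10),
)
def test_partition_invariants(total, kd, tss):
    state = partition_water(total, kd, tss)
    assert state.fraction_dissolved + state.fraction_particulate == pytest.approx(1.0, abs=1e-12)
    # linear isotherm: particle concentration is Kd x dissolved concentration
    assert state.particle_concentration_ng_g == pytest.approx(
        kd * state.dissolved_concentration_ng_L, rel=1e-12, abs=1e-300
    )
    # dissolved + particulate mass recovers the total: C_d + C_p * TSS = C_t
    assert state.dissolved_concentration_ng_L + state.particle_concentration_ng_g * tss == (
        pytest.approx(total, rel=1e-12, abs=1e-300)
    )


# ------------------------------------------------------- species multipliers

def test_species_split_is_proportional_and_exact():
    ratios = SpeciesRatios(water=(0.02, 0.05, 0.93))
    split = apply_species_multipliers(100.0, ratios, "water")
    assert split == {"Hg0": 2.0, "MeHg": 5.0, "residual": 93.0}
    assert apply_species_multipliers(0.0, ratios, "sediment") == {s: 0.0 for s in SPECIES}


def test_evasion_is_all_elemental_mercury_in_air():
    split = apply_species_multipliers(11_932.9, SpeciesRatios(), "air")
    assert split["Hg0"] == pytest.approx(11_932.9)
    assert split["MeHg"] == 0.0 and split["residual"] == 0.0


def test_unknown_compartment_rejected():
    with pytest.raises(Exception, match="compartment"):
        apply_species_multipliers(1.0, SpeciesRatios(), "soil")


@given(total=st.floats(min_value=0, max_value=1e6))
def test_species_rates_sum_to_total(total):
    split = apply_species_multipliers(total, SpeciesRatios(), "water")
    assert sum(split.values()) == pytest.approx(total, rel=1e-12, abs=1e-300)


# ------------------------------------------------------------------ D-values

def test_settling_and_burial_solids_flows(soa):
    site, _inputs, params = soa
    d = build_d_values(site, params)
    # 1.66 g/m^2/day x 365 x 3.9e10 m^2
    assert d.gross_settling_g_yr == pytest.approx(2.363e13, rel=1e-3)
    assert d.burial_g_yr == pytest.approx(0.36 * d.gross_settling_g_yr, rel=1e-12)
    assert d.resuspension_g_yr + d.burial_g_yr == pytest.approx(
        d.gross_settling_g_yr, rel=1e-12
    )
    assert d.outflow_m3_yr == pytest.approx(54.4e9, rel=1e-9)


def test_full_resuspension_means_no_burial(soa):
    site, _inputs, params = soa
    d = build_d_values(site.model_copy(update={"resuspension_fraction": 1.0}), params)
    assert d.burial_g_yr == 0.0


def test_dvalueset_rejects_unbalanced_solids():
    with pytest.raises(DomainError):
        DValueSet(
            outflow_m3_yr=1.0,
            net_evasion_m3_yr=1.0,
            gross_settling_g_yr=10.0,
            resuspension_g_yr=3.0,
            burial_g_yr=3.0,
        )


# -------------------------------------------------------------------- solver

def _simple_loads(total_kg_yr: float) -> LoadingBudget:
    return LoadingBudget(wet_deposition_kg_yr=total_kg_yr, riverine_total_kg_yr=0.0)


def test_zero_loads_give_zero_state(soa):
    site, _inputs, params = soa
    d = build_d_values(site, params)
    sol = solve_steady_state(_simple_loads(0.0), d, site, params)
    assert sol.water_thg_ng_L == 0.0
    assert sol.sediment_thg_ng_g == 0.0
    assert all(v == 0.0 for p, v in sol.flux_table.items() if p != "wet_deposition")


def test_pure_dilution_box_is_exact():
    site = soa_site().model_copy(update={"sedimentation_rate_g_m2_day": 0.0})
    from hgbalance import ModelParameters

    params = ModelParameters(kd_L_g=0.0, k_vol_m_h=0.0, scavenging_ratio=1.0)
    d = build_d_values(site, params)
    sol = solve_steady_state(_simple_loads(544.0), d, site, params)
    # C_w = L / Q: 544 kg/yr over 54.4 km^3/yr -> 10 ng/L
    assert sol.water_thg_ng_L == pytest.approx(10.0, rel=1e-12)
    assert sol.sediment_thg_ng_g == 0.0


def test_no_loss_pathway_has_no_steady_state():
    from hgbalance import ModelParameters

    site = soa_site().model_copy(
        update={"sedimentation_rate_g_m2_day": 0.0, "seawater_outflow_km3_yr": 0.0}
    )
    params = ModelParameters(kd_L_g=0.0, k_vol_m_h=0.0, scavenging_ratio=1.0)
    d = build_d_values(site, params)
    with pytest.raises(SteadyStateError):
        solve_steady_state(_simple_loads(1.0), d, site, params)


def test_sediment_concentration_equals_settling_particle_concentration(soa_solution):
    sol, _loads, _d = soa_solution
    # at steady state the sediment solids carry the settling particles' concentration
    assert sol.sediment_thg_ng_g == pytest.approx(
        sol.partition.particle_concentration_ng_g, rel=1e-12
    )


def test_mass_conservation(soa_solution):
    sol, _loads, _d = soa_solution
    assert abs(sol.closure_residual_relative) < 1e-9


def test_species_concentrations_sum_to_total(soa_solution):
    sol, _loads, _d = soa_solution
    assert sum(sol.species_ng["water"].values()) == pytest.approx(
        sol.water_thg_ng_L, rel=1e-9
    )
    assert sum(sol.species_ng["sediment"].values()) == pytest.approx(
        sol.sediment_thg_ng_g, rel=1e-9
    )


def test_linearity_doubling_loads_doubles_everything(soa):
    site, inputs, params = soa
    from hgbalance import compute_loading_budget

    loads = compute_loading_budget(site, inputs, params)
    d = build_d_values(site, params)
    sol1 = solve_steady_state(loads, d, site, params)
    doubled = dataclasses.replace(
        loads,
        wet_deposition_kg_yr=2 * loads.wet_deposition_kg_yr,
        riverine_total_kg_yr=2 * loads.riverine_total_kg_yr,
    )
    sol2 = solve_steady_state(doubled, d, site, params)
    assert sol2.water_thg_ng_L == pytest.approx(2 * sol1.water_thg_ng_L, rel=1e-12)
    assert sol2.sediment_thg_ng_g == pytest.approx(2 * sol1.sediment_thg_ng_g, rel=1e-12)
    for p in EXTERNAL_EFFLUXES:
        assert sol2.flux_table[p] == pytest.approx(2 * sol1.flux_table[p], rel=1e-12)


def test_monotonicity_in_kvol_and_kd(soa):
    site, inputs, params = soa
    from hgbalance import compute_loading_budget

    loads = compute_loading_budget(site, inputs, params)
    base = solve_steady_state(loads, build_d_values(site, params), site, params)

    faster = params.model_copy(update={"k_vol_m_h": 2 * params.k_vol_m_h})
    sol_f = solve_steady_state(loads, build_d_values(site, faster), site, faster)
    assert sol_f.water_thg_ng_L < base.water_thg_ng_L
    assert sol_f.sediment_thg_ng_g < base.sediment_thg_ng_g

    stickier = params.model_copy(update={"kd_L_g": 2 * params.kd_L_g})
    sol_k = solve_steady_state(loads, build_d_values(site, stickier), site, stickier)
    share = lambda s: -s.flux_table["burial"] / s.total_efflux_kg_yr
    assert share(sol_k) > share(base)


def test_optional_sediment_diffusion_preserves_conservation(soa):
    site, inputs, params = soa
    from hgbalance import compute_loading_budget

    loads = compute_loading_budget(site, inputs, params)
    with_diff = params.model_copy(update={"sediment_diffusion_m3_yr": 1e9})
    sol = solve_steady_state(loads, build_d_values(site, with_diff), site, with_diff)
    assert abs(sol.closure_residual_relative) < 1e-9
    assert sol.water_thg_ng_L > 0
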