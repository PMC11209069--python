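"""Random, physically valid sites with known ground-truth steady states.

The generator emulates the structure the balance assumes: a shallow,
well-mixed water column over an active sediment layer, loaded by rivers and
wet deposition, losing mercury through outflow, net evasion and burial.
Concentration-like quantities and Kd are drawn log-uniformly (the regional
literature spans orders of magnitude); fractions are drawn uniformly.  The
outflow is sampled as a specific drainage velocity times the surface area so
that the water-column and sediment turnover times stay within a few orders of
magnitude of each other — the regime the fixed-step explicit oracle is built
for.

Ground truth comes from :func:`oracle_solve`, a brute-force fixed-step Euler
integration of the two compartment mass ODEs, entirely independent of the
closed-form solver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from numba import njit

from . import units
from .config import (
    HgInputs,
    ModelParameters,
    River,
    SiteParametrization,
    SpeciesRatios,
    config_to_dict,
    _parse_site,
    _parse_inputs,
    _parse_params,
)
from .core import DValueSet, SteadyStateSolution, assemble_solution, build_d_values, _system_coefficients
from .errors import ConvergenceError, DomainError, SteadyStateError
from .loadings import LoadingBudget, compute_loading_budget
from .calibration import (
    kd_from_concentrations,
    kvol_from_evasion,
    scavenging_from_concentrations,
)

#: (low, high, sampling) — sampling is "log" or "uniform"
DEFAULT_RANGES: dict[str, tuple[float, float, str]] = {
    "area_km2": (3.9e3, 3.9e5, "log"),
    "mean_depth_m": (2.0, 25.0, "log"),
    "outflow_velocity_m_yr": (0.5, 5.0, "log"),
    "precipitation_mm_yr": (100.0, 1500.0, "log"),
    "rain_thg_ng_L": (24.0, 2400.0, "log"),
    "river_discharge_fraction": (0.1, 0.6, "uniform"),
    "river_thg_ng_L": (10.0, 5000.0, "log"),
    "river_tss_mg_L": (5.0, 200.0, "log"),
    "river_oc_fraction": (0.01, 0.2, "uniform"),
    "water_tss_mg_L": (5.0, 60.0, "log"),
    "water_tss_oc_fraction": (0.05, 0.3, "uniform"),
    "sedimentation_rate_g_m2_day": (0.5, 5.0, "log"),
    "resuspension_fraction": (0.1, 0.9, "uniform"),
    "sediment_oc_fraction": (0.005, 0.05, "uniform"),
    "mean_temperature_c": (5.0, 20.0, "uniform"),
    "wind_speed_m_s": (3.0, 10.0, "uniform"),
    "kd_L_g": (2.0, 50.0, "log"),
    "k_vol_m_h": (0.1, 1.0, "log"),
    "scavenging_ratio": (1.0e4, 1.6e5, "log"),
    "f_hg0_water": (0.01, 0.05, "uniform"),
    "f_mehg_water": (0.01, 0.1, "uniform"),
    "f_mehg_sediment": (0.005, 0.05, "uniform"),
    "seawater_thg_ng_L": (1.0, 20.0, "log"),
    "seawater_inflow_fraction": (0.3, 0.8, "uniform"),
    "sediment_active_depth_m": (0.03, 0.03, "uniform"),
    "sediment_porosity": (0.75, 0.75, "uniform"),
    "sediment_solids_density_g_cm3": (2.4, 2.4, "uniform"),
}


@dataclass(frozen=True)
class SyntheticScenario:
    """A generated site with its brute-force ground-truth steady state."""

    seed: int
    site: SiteParametrization
    inputs: HgInputs
    params: ModelParameters
    loads: LoadingBudget
    ground_truth: SteadyStateSolution


def _merge_ranges(ranges: dict | None) -> dict[str, tuple[float, float, str]]:
    merged = dict(DEFAULT_RANGES)
    for key, value in (ranges or {}).items():
        if key not in DEFAULT_RANGES:
            raise DomainError(f"unknown range key {key!r}")
        low, high = float(value[0]), float(value[1])
        sampling = value[2] if len(value) > 2 else DEFAULT_RANGES[key][2]
        merged[key] = (low, high, sampling)
    for key, (low, high, sampling) in merged.items():
        if not (np.isfinite(low) and np.isfinite(high)) or low > high or low < 0:
            raise DomainError(f"range for {key!r} must satisfy 0 <= low <= high, got ({low}, {high})")
        if sampling == "log" and low <= 0 and low < high:
            raise DomainError(f"log-uniform range for {key!r} requires low > 0")
        if key.startswith("f_") or key.endswith("fraction") or key == "sediment_porosity":
            if high > 1:
                raise DomainError(f"range for {key!r} must stay within [0, 1]")
    return merged


def _sample(rng: np.random.Generator, rng_spec: tuple[float, float, str]) -> float:
    low, high, sampling = rng_spec
    if low == high:
        return low
    if sampling == "log":
        return float(np.exp(rng.uniform(np.log(low), np.log(high))))
    return float(rng.uniform(low, high))


def generate_site(seed: int, ranges: dict | None = None) -> SyntheticScenario:
    """Generate one scenario, deterministic in ``seed``.

    ``ranges`` overrides entries of :data:`DEFAULT_RANGES`; a degenerate
    (point-mass) range pins a parameter exactly.
    """
    merged = _merge_ranges(ranges)
    rng = np.random.default_rng(seed)
    v = {key: _sample(rng, merged[key]) for key in DEFAULT_RANGES}  # fixed draw order

    outflow_km3 = v["outflow_velocity_m_yr"] * v["area_km2"] * 1e-3  # m/yr * km2 -> km3/yr
    river_q = v["river_discharge_fraction"] * outflow_km3
    precip_km3 = units.convert(
        v["precipitation_mm_yr"], "mm/yr", "m/yr"
    ) * units.convert(v["area_km2"], "km^2", "m^2") / 1e9
    inflow_km3 = v["seawater_inflow_fraction"] * outflow_km3
    evaporation = max(river_q + precip_km3 + inflow_km3 - outflow_km3, 0.0)

    site = SiteParametrization(
        area_km2=v["area_km2"],
        mean_depth_m=v["mean_depth_m"],
        rivers=(
            River(
                name="synthetic-river",
                discharge_km3_yr=river_q,
                tss_mg_L=v["river_tss_mg_L"],
                oc_fraction=v["river_oc_fraction"],
            ),
        ),
        precipitation_mm_yr=v["precipitation_mm_yr"],
        evaporation_km3_yr=evaporation,
        seawater_outflow_km3_yr=outflow_km3,
        seawater_inflow_km3_yr=inflow_km3,
        water_tss_mg_L=v["water_tss_mg_L"],
        water_tss_oc_fraction=v["water_tss_oc_fraction"],
        sedimentation_rate_g_m2_day=v["sedimentation_rate_g_m2_day"],
        resuspension_fraction=v["resuspension_fraction"],
        sediment_oc_fraction=v["sediment_oc_fraction"],
        mean_temperature_c=v["mean_temperature_c"],
        wind_speed_m_s=v["wind_speed_m_s"],
    )
    inputs = HgInputs(
        rain_thg_ng_L=v["rain_thg_ng_L"],
        river_thg_ng_L={"synthetic-river": v["river_thg_ng_L"]},
        seawater_thg_ng_L=v["seawater_thg_ng_L"],
        atmospheric_thg_ng_m3=v["rain_thg_ng_L"] * 1e3 / v["scavenging_ratio"],
    )
    f_hg0, f_mehg = v["f_hg0_water"], v["f_mehg_water"]
    params = ModelParameters(
        kd_L_g=v["kd_L_g"],
        k_vol_m_h=v["k_vol_m_h"],
        scavenging_ratio=v["scavenging_ratio"],
        species_ratios=SpeciesRatios(
            water=(f_hg0, f_mehg, 1.0 - f_hg0 - f_mehg),
            sediment=(0.0, v["f_mehg_sediment"], 1.0 - v["f_mehg_sediment"]),
        ),
        sediment_active_depth_m=v["sediment_active_depth_m"],
        sediment_porosity=v["sediment_porosity"],
        sediment_solids_density_g_cm3=v["sediment_solids_density_g_cm3"],
        provenance={"all": "synthetic"},
    )
    loads = compute_loading_budget(site, inputs, params)
    d = build_d_values(site, params)
    truth = oracle_solve(loads, d, site, params)
    return SyntheticScenario(
        seed=seed, site=site, inputs=inputs, params=params, loads=loads, ground_truth=truth
    )


# --------------------------------------------------------------------------
# Brute-force ODE oracle
# --------------------------------------------------------------------------

@njit(cache=False)
def _euler_kernel(L, V, Md, a_ww, a_ws, a_sw, a_ss, dt, tol, max_steps):  # pragma: no cover
    m_w = 0.0
    m_s = 0.0
    for step in range(max_steps):
        c_w = m_w / V
        c_s = m_s / Md if Md > 0.0 else 0.0
        dm_w = L - a_ww * c_w + a_ws * c_s
        dm_s = a_sw * c_w - a_ss * c_s
        if abs(dm_w) <= tol and abs(dm_s) <= tol:
            return c_w, c_s, step
        m_w += dt * dm_w
        m_s += dt * dm_s
    return -1.0, -1.0, max_steps


def oracle_solve(
    loads: LoadingBudget,
    d: DValueSet,
    site: SiteParametrization,
    params: ModelParameters,
    tol_rel: float = 1e-10,
    max_steps: int = 200_000_000,
) -> SteadyStateSolution:
    """Steady state by fixed-step explicit time integration of the mass ODEs.

    Integrates ``dM/dt = influx − Σ D·C`` from an empty system with a step of
    one tenth of the fastest compartment turnover time, until both
    compartments' net rates fall below ``tol_rel`` times the external load.
    Independent of the closed-form solver; used as its oracle.
    """
    load_g_yr = units.convert(loads.external_total_kg_yr, "kg/yr", "g/yr")
    a_ww, a_ws, a_sw, a_ss, _fd = _system_coefficients(d, params, site)
    if load_g_yr == 0.0:
        return assemble_solution(0.0, 0.0, loads, d, site, params)
    if a_ww <= 0.0 or (a_ss > 0.0 and a_ww * a_ss - a_ws * a_sw <= 0.0):
        raise SteadyStateError("no steady state: loss conductances vanish for a nonzero load")

    volume = site.water_volume_m3
    md = params.sediment_dry_mass_m2() * site.area_m2
    t_water = volume / a_ww
    t_sed = md / a_ss if a_ss > 0.0 else np.inf
    dt = 0.1 * min(t_water, t_sed)
    tol = tol_rel * load_g_yr

    cw, cs, steps = _euler_kernel(
        load_g_yr, volume, md, a_ww, a_ws, a_sw, a_ss, dt, tol, max_steps
    )
    if cw < 0.0:
        raise ConvergenceError(
            f"oracle did not converge within {max_steps} steps "
            f"(dt={dt:.3e} yr, turnover water={t_water:.3e} yr, sediment={t_sed:.3e} yr)"
        )
    return assemble_solution(cw, cs, loads, d, site, params)


def oracle_steady_state(scenario: SyntheticScenario, **kwargs) -> SteadyStateSolution:
    """Recompute the scenario's ground truth with the time-stepping oracle."""
    d = build_d_values(scenario.site, scenario.params)
    return oracle_solve(scenario.loads, d, scenario.site, scenario.params, **kwargs)


# --------------------------------------------------------------------------
# Parameter recovery
# --------------------------------------------------------------------------

def recovery_experiment(
    n_scenarios: int,
    seed: int,
    noise_sd: float = 0.0,
    ranges: dict | None = None,
):
    """Hide-one-parameter recovery across generated scenarios.

    For each scenario the observables a field calibration would use (water and
    sediment concentrations, the net evasion flux, rain and air
    concentrations) are taken from the ground truth, optionally perturbed by
    multiplicative Gaussian noise, and each of Kd, k_vol and the scavenging
    ratio is recovered by the package's closed-form calibration inversions.

    Returns ``(table, summary)`` where ``table`` is a pandas DataFrame of
    per-scenario relative errors and ``summary`` maps parameter name to the
    median absolute relative error.
    """
    import pandas as pd

    if n_scenarios < 1:
        raise DomainError("n_scenarios must be >= 1")
    rng = np.random.default_rng(seed)
    scenario_seeds = rng.integers(0, 2**31 - 1, size=n_scenarios)

    rows = []
    for s_seed in scenario_seeds:
        sc = generate_site(int(s_seed), ranges)
        truth = sc.ground_truth

        def observe(x: float) -> float:
            if noise_sd == 0.0:
                return x
            return x * max(1.0 + noise_sd * rng.standard_normal(), 1e-6)

        cw = observe(truth.water_thg_ng_L)
        cs = observe(truth.sediment_thg_ng_g)
        evasion = observe(-truth.flux_table["net_evasion"])
        rain = observe(sc.inputs.rain_thg_ng_L)
        air = observe(sc.inputs.atmospheric_thg_ng_m3)
        tss = sc.site.water_tss_g_L
        fd = 1.0 / (1.0 + sc.params.kd_L_g * tss)

        recovered = {}
        try:
            recovered["kd_L_g"] = kd_from_concentrations(cw, cs, tss)
        except DomainError:
            recovered["kd_L_g"] = np.nan
        recovered["k_vol_m_h"] = kvol_from_evasion(
            evasion, cw, sc.site.area_km2,
            sc.params.species_ratios.fraction_hg0_water, fd,
        )
        recovered["scavenging_ratio"] = scavenging_from_concentrations(rain, air)

        truths = {
            "kd_L_g": sc.params.kd_L_g,
            "k_vol_m_h": sc.params.k_vol_m_h,
            "scavenging_ratio": sc.params.scavenging_ratio,
        }
        for name, value in recovered.items():
            rows.append(
                {
                    "seed": int(s_seed),
                    "parameter": name,
                    "truth": truths[name],
                    "recovered": value,
                    "rel_error": abs(value - truths[name]) / truths[name],
                }
            )

    table = pd.DataFrame(rows)
    summary = table.groupby("parameter")["rel_error"].median().to_dict()
    return table, summary


# --------------------------------------------------------------------------
# Scenario (de)serialisation
# --------------------------------------------------------------------------

def scenario_to_json(scenario: SyntheticScenario, path: str | Path) -> None:
    payload = {
        "seed": scenario.seed,
        "config": config_to_dict(scenario.site, scenario.inputs, scenario.params),
        "loads": asdict(scenario.loads),
        "ground_truth": asdict(scenario.ground_truth),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def scenario_from_json(path: str | Path) -> SyntheticScenario:
    payload = json.loads(Path(path).read_text())
    cfg = payload["config"]
    site = _parse_site(cfg["site"])
    inputs = _parse_inputs(cfg["hg_inputs"])
    params = _parse_params(cfg["model_parameters"])
    loads = LoadingBudget(**payload["loads"])
    gt = payload["ground_truth"]
    from .core import PartitionState

    gt["partition"] = PartitionState(**gt["partition"])
    truth = SteadyStateSolution(**gt)
    return SyntheticScenario(
        seed=int(payload["seed"]), site=site, inputs=inputs, params=params,
        loads=loads, ground_truth=truth,
    )
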