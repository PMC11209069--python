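"""Two-compartment steady-state total-mercury mass balance.

The model is an aquivalence-style box model: a well-mixed water column over an
active sediment layer, with the atmosphere as a prescribed boundary.  Each
transport process is a D-value — a conductance expressed as a volume-equivalent
flow per unit concentration — so the flux through a process is ``N = D * C``.
With linear solid–water partitioning (fixed Kd on suspended solids) the
total-mercury balance of the two compartments is a 2x2 linear system and the
steady state is available in closed form.

Processes
---------
water losses
    outflow to the adjacent sea (``Q_out * C_w``), net gas evasion of the
    dissolved elemental fraction (``k_vol * A * f_Hg0 * f_diss * C_w``) and
    gross particle settling (``S_g * Kd * f_diss * C_w``).
sediment
    receives gross settling; loses resuspension back to the water column and
    burial to deep sediment (``S_r + S_b = S_g`` on the solids-mass basis).
optional
    sediment–water porewater diffusion (off by default).

Interconverting mercury species (Hg0, MeHg, residual) are handled by the
constant-ratio multiplier scheme: per-species rates are fixed fractions of the
total-mercury rate in each compartment, so the total budget is solved once and
species breakdowns are proportional splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import units
from .config import HgInputs, ModelParameters, SiteParametrization, SpeciesRatios
from .errors import DomainError, SteadyStateError
from .loadings import LoadingBudget

__all__ = [
    "PartitionState",
    "DValueSet",
    "SteadyStateSolution",
    "partition_water",
    "apply_species_multipliers",
    "build_d_values",
    "solve_steady_state",
    "SpeciesRatios",
]

SPECIES = ("Hg0", "MeHg", "residual")

#: compartment whose species ratios apportion each process flux
PROCESS_COMPARTMENT = {
    "wet_deposition": "water",
    "riverine": "water",
    "seawater_inflow": "water",
    "outflow": "water",
    "net_evasion": "air",
    "gross_settling": "water",
    "resuspension": "sediment",
    "burial": "sediment",
    "sediment_water_diffusion": "water",
}

EXTERNAL_INFLUXES = ("wet_deposition", "riverine", "seawater_inflow")
EXTERNAL_EFFLUXES = ("outflow", "net_evasion", "burial")
INTERNAL_PROCESSES = ("gross_settling", "resuspension", "sediment_water_diffusion")


@dataclass(frozen=True)
class PartitionState:
    """Dissolved/particulate split of total Hg in the water column."""

    fraction_dissolved: float
    fraction_particulate: float
    particle_concentration_ng_g: float
    dissolved_concentration_ng_L: float


def partition_water(total_conc_ng_L: float, kd_L_g: float, tss_g_L: float) -> PartitionState:
    """Linear-isotherm partitioning of total Hg between water and suspended solids.

    ``fraction_dissolved = 1 / (1 + Kd * TSS)`` and the particle concentration
    is ``Kd`` times the dissolved concentration.

    Parameters are total concentration [ng/L], Kd [L/g] and TSS [g/L].
    """
    for name, value in (
        ("total_conc_ng_L", total_conc_ng_L),
        ("kd_L_g", kd_L_g),
        ("tss_g_L", tss_g_L),
    ):
        if value < 0:
            raise DomainError(f"{name} must be >= 0, got {value}")
    fd = 1.0 / (1.0 + kd_L_g * tss_g_L)
    dissolved = fd * total_conc_ng_L
    return PartitionState(
        fraction_dissolved=fd,
        fraction_particulate=1.0 - fd,
        particle_concentration_ng_g=kd_L_g * dissolved,
        dissolved_concentration_ng_L=dissolved,
    )


def apply_species_multipliers(
    total_rate: float, ratios: SpeciesRatios, compartment: str
) -> dict[str, float]:
    """Split a total-Hg rate into per-species rates by the compartment's fixed ratios.

    The constant-ratio scheme makes every species rate a fixed multiple of the
    total rate, so the split is exactly proportional and sums back to the
    total.
    """
    fracs = ratios.fractions(compartment)
    return dict(zip(SPECIES, (f * total_rate for f in fracs)))


@dataclass(frozen=True)
class DValueSet:
    """Transport conductances of the balance.

    Water-phase processes (outflow, net evasion, diffusion) are
    volume-equivalent flows [m³/yr] applied to the *total* water concentration
    [g/m³].  Solids processes are dry-mass flows [g/yr] applied to particle
    concentrations [g/g].
    """

    outflow_m3_yr: float
    net_evasion_m3_yr: float
    gross_settling_g_yr: float
    resuspension_g_yr: float
    burial_g_yr: float
    sediment_water_diffusion_m3_yr: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "outflow_m3_yr",
            "net_evasion_m3_yr",
            "gross_settling_g_yr",
            "resuspension_g_yr",
            "burial_g_yr",
            "sediment_water_diffusion_m3_yr",
        ):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0, got {getattr(self, name)}")
        settled = self.resuspension_g_yr + self.burial_g_yr
        if self.gross_settling_g_yr > 0 and not np.isclose(
            settled, self.gross_settling_g_yr, rtol=1e-12, atol=0.0
        ):
            raise DomainError(
                "resuspension + burial must equal gross settling on the solids basis"
            )


def build_d_values(site: SiteParametrization, params: ModelParameters) -> DValueSet:
    """Assemble all transport conductances from the site and process constants.

    Gross settling is ``sedimentation_rate × area``; the resuspension fraction
    routes settled solids back to the water column and the remainder is buried.
    The net-evasion conductance acts on the dissolved Hg0 share of the total
    water concentration.
    """
    if not 0.0 <= site.resuspension_fraction <= 1.0:
        raise DomainError("resuspension_fraction must be in [0, 1]")
    area = site.area_m2
    settling = units.convert(site.sedimentation_rate_g_m2_day, "g/m^2/day", "g/m^2/yr") * area
    resusp = site.resuspension_fraction * settling
    burial = settling - resusp
    part = partition_water(1.0, params.kd_L_g, site.water_tss_g_L)
    evasion = (
        params.k_vol_m_yr
        * area
        * params.species_ratios.fraction_hg0_water
        * part.fraction_dissolved
    )
    return DValueSet(
        outflow_m3_yr=units.convert(site.seawater_outflow_km3_yr, "km^3/yr", "m^3/yr"),
        net_evasion_m3_yr=evasion,
        gross_settling_g_yr=settling,
        resuspension_g_yr=resusp,
        burial_g_yr=burial,
        sediment_water_diffusion_m3_yr=params.sediment_diffusion_m3_yr,
    )


@dataclass(frozen=True)
class SteadyStateSolution:
    """Steady state of the two-compartment balance.

    ``flux_table`` is signed in kg/yr: external influxes positive, external
    effluxes negative; internal exchanges (settling, resuspension, diffusion)
    are reported as the water-column sign convention (settling negative,
    resuspension positive).
    """

    water_thg_ng_L: float
    sediment_thg_ng_g: float
    air_thg_ng_m3: float
    partition: PartitionState
    species_ng: dict[str, dict[str, float]]
    flux_table: dict[str, float]
    inventories_kg: dict[str, float]
    closure_residual_kg_yr: float
    total_influx_kg_yr: float
    total_efflux_kg_yr: float
    aquivalence_water_g_m3: float = 0.0

    @property
    def closure_residual_relative(self) -> float:
        if self.total_influx_kg_yr == 0.0:
            return 0.0
        return self.closure_residual_kg_yr / self.total_influx_kg_yr


def _system_coefficients(
    d: DValueSet, params: ModelParameters, site: SiteParametrization
) -> tuple[float, float, float, float, float]:
    """Linear-system coefficients; unknowns are C_w [g/m³ total] and C_s [g/g dw]."""
    kdm = params.kd_m3_g
    fd = 1.0 / (1.0 + kdm * units.convert(site.water_tss_mg_L, "mg/L", "g/m^3"))
    ddiff = d.sediment_water_diffusion_m3_yr
    if ddiff > 0.0 and kdm == 0.0:
        raise DomainError("sediment-water diffusion requires a nonzero Kd")
    pore_return = ddiff / kdm if ddiff > 0.0 else 0.0  # g/yr per unit C_s [g/g]
    settle = d.gross_settling_g_yr * kdm * fd  # m3/yr equivalent on total C_w
    a_ww = d.outflow_m3_yr + d.net_evasion_m3_yr + settle + ddiff * fd
    a_ws = d.resuspension_g_yr + pore_return
    a_sw = settle + ddiff * fd
    a_ss = d.resuspension_g_yr + d.burial_g_yr + pore_return
    return a_ww, a_ws, a_sw, a_ss, fd


def solve_steady_state(
    loads: LoadingBudget,
    d: DValueSet,
    site: SiteParametrization,
    params: ModelParameters,
) -> SteadyStateSolution:
    """Closed-form steady state of the water/sediment total-Hg balance.

    Solves the coupled balance: external loads enter the water column, which
    loses Hg to outflow, net evasion and gross settling; the sediment returns
    the resuspended share and buries the rest.  Raises
    :class:`~hgbalance.errors.SteadyStateError` when a nonzero load meets zero
    loss conductance (no steady state exists).
    """
    load_g_yr = units.convert(loads.external_total_kg_yr, "kg/yr", "g/yr")
    a_ww, a_ws, a_sw, a_ss, fd = _system_coefficients(d, params, site)

    if a_ss > 0.0:
        A = np.array([[a_ww, -a_ws], [-a_sw, a_ss]], dtype=float)
        b = np.array([load_g_yr, 0.0], dtype=float)
        det = a_ww * a_ss - a_ws * a_sw
        if det <= 0.0 or not np.isfinite(det):
            if load_g_yr == 0.0:
                cw, cs = 0.0, 0.0
            else:
                raise SteadyStateError(
                    "no steady state: loss conductances vanish for a nonzero load"
                )
        else:
            cw, cs = np.linalg.solve(A, b)
    else:
        # no particle throughput in the sediment: decoupled water balance
        if a_ww <= 0.0:
            if load_g_yr == 0.0:
                cw = 0.0
            else:
                raise SteadyStateError(
                    "no steady state: loss conductances vanish for a nonzero load"
                )
        else:
            cw = load_g_yr / a_ww
        cs = 0.0

    return assemble_solution(cw, cs, loads, d, site, params)


def assemble_solution(
    cw_g_m3: float,
    cs_g_g: float,
    loads: LoadingBudget,
    d: DValueSet,
    site: SiteParametrization,
    params: ModelParameters,
    air_thg_ng_m3: float | None = None,
) -> SteadyStateSolution:
    """Build the full reported solution from compartment concentrations.

    Shared by the analytic solver and the time-stepping oracle so that both
    report fluxes, inventories and species breakdowns identically from their
    respective concentration pairs.
    """
    cw = float(max(cw_g_m3, 0.0))
    cs = float(max(cs_g_g, 0.0))
    cw_ng_L = units.convert(cw, "g/m^3", "ng/L")
    cs_ng_g = units.convert(cs, "g/g", "ng/g")
    part = partition_water(cw_ng_L, params.kd_L_g, site.water_tss_g_L)
    _, _, _, _, fd = _system_coefficients(d, params, site)
    kdm = params.kd_m3_g

    to_kg = lambda g_yr: units.convert(g_yr, "g/yr", "kg/yr")
    flux: dict[str, float] = {
        "wet_deposition": loads.wet_deposition_kg_yr,
        "riverine": loads.riverine_total_kg_yr,
        "seawater_inflow": loads.seawater_inflow_kg_yr if loads.include_seawater else 0.0,
        "outflow": -to_kg(d.outflow_m3_yr * cw),
        "net_evasion": -to_kg(d.net_evasion_m3_yr * cw),
        "burial": -to_kg(d.burial_g_yr * cs),
        "gross_settling": -to_kg(d.gross_settling_g_yr * kdm * fd * cw),
        "resuspension": to_kg(d.resuspension_g_yr * cs),
        "sediment_water_diffusion": -to_kg(
            d.sediment_water_diffusion_m3_yr * fd * cw
            - (d.sediment_water_diffusion_m3_yr / kdm * cs if kdm > 0.0 else 0.0)
        )
        if d.sediment_water_diffusion_m3_yr > 0.0
        else 0.0,
    }

    total_in = sum(flux[p] for p in EXTERNAL_INFLUXES)
    total_out = -sum(flux[p] for p in EXTERNAL_EFFLUXES)
    residual = total_in - total_out

    ratios = params.species_ratios
    species = {
        "water": apply_species_multipliers(cw_ng_L, ratios, "water"),
        "sediment": apply_species_multipliers(cs_ng_g, ratios, "sediment"),
        "air": apply_species_multipliers(
            air_thg_ng_m3 if air_thg_ng_m3 is not None else 0.0, ratios, "air"
        ),
    }

    inv_water = cw * site.water_volume_m3 / 1e3  # g -> kg
    sed_dry_mass_g = params.sediment_dry_mass_m2() * site.area_m2
    inv_sed = cs * sed_dry_mass_g / 1e3

    return SteadyStateSolution(
        water_thg_ng_L=cw_ng_L,
        sediment_thg_ng_g=cs_ng_g,
        air_thg_ng_m3=air_thg_ng_m3 if air_thg_ng_m3 is not None else 0.0,
        partition=part,
        species_ng=species,
        flux_table=flux,
        inventories_kg={"water": inv_water, "sediment": inv_sed},
        closure_residual_kg_yr=residual,
        total_influx_kg_yr=total_in,
        total_efflux_kg_yr=total_out,
        aquivalence_water_g_m3=fd * cw,
    )
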