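"""External mercury loading terms of the balance.

All loads are reported in kg/yr.  The wet-deposition load is rain
concentration × rainfall × surface area; riverine loads are discharge ×
concentration per river.  A reported precipitation share of the total influx
(28 % for the Sea of Azov, from the regional deposition literature) converts
the wet load into an implied total influx, and the difference between that
total and the explicitly quantified terms is carried as an unaccounted
residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import units
from .config import HgInputs, ModelParameters, SiteParametrization
from .errors import DomainError

logger = logging.getLogger(__name__)

#: reported share of the total Hg influx arriving via precipitation
DEFAULT_PRECIPITATION_SHARE = 0.28


def _require_nonnegative(**values: float) -> None:
    for name, value in values.items():
        if value < 0:
            raise DomainError(f"{name} must be >= 0, got {value}")


def wet_deposition_load(rain_conc_ng_L: float, precipitation_mm_yr: float, area_km2: float) -> float:
    """Wet-deposition Hg load [kg/yr] from rain concentration, rainfall and area."""
    _require_nonnegative(
        rain_conc_ng_L=rain_conc_ng_L,
        precipitation_mm_yr=precipitation_mm_yr,
        area_km2=area_km2,
    )
    conc_g_m3 = units.convert(rain_conc_ng_L, "ng/L", "g/m^3")
    rain_m3_yr = units.convert(precipitation_mm_yr, "mm/yr", "m/yr") * units.convert(
        area_km2, "km^2", "m^2"
    )
    return units.convert(conc_g_m3 * rain_m3_yr, "g/yr", "kg/yr")


def annual_water_influx_from_precip(precipitation_mm_yr: float, area_km2: float) -> float:
    """Volumetric water influx [km³/yr] delivered by rainfall over the surface."""
    _require_nonnegative(precipitation_mm_yr=precipitation_mm_yr, area_km2=area_km2)
    m3 = units.convert(precipitation_mm_yr, "mm/yr", "m/yr") * units.convert(
        area_km2, "km^2", "m^2"
    )
    return units.convert(m3, "m^3/yr", "km^3/yr")


def river_load(discharge_km3_yr: float, conc_ng_L: float) -> float:
    """Riverine Hg load [kg/yr] from discharge [km³/yr] and concentration [ng/L]."""
    _require_nonnegative(discharge_km3_yr=discharge_km3_yr, conc_ng_L=conc_ng_L)
    q_m3 = units.convert(discharge_km3_yr, "km^3/yr", "m^3/yr")
    conc = units.convert(conc_ng_L, "ng/L", "g/m^3")
    return units.convert(q_m3 * conc, "g/yr", "kg/yr")


def total_influx_from_precip_fraction(wet_load_kg_yr: float, fraction: float) -> float:
    """Total influx implied by a wet load that represents a known share of it."""
    _require_nonnegative(wet_load_kg_yr=wet_load_kg_yr)
    if not 0.0 < fraction <= 1.0:
        raise DomainError(f"fraction must be in (0, 1], got {fraction}")
    return wet_load_kg_yr / fraction


def unaccounted_residual(total_kg_yr: float, wet_kg_yr: float, riverine_kg_yr: float) -> float:
    """Signed difference between the implied total and the quantified terms."""
    return total_kg_yr - wet_kg_yr - riverine_kg_yr


def calibrate_atmospheric_concentration(rain_conc_ng_L: float, scavenging_ratio: float) -> float:
    """Air concentration [ng/m³] consistent with the rain concentration.

    Uses the volumetric washout relation ``C_rain = scavenging_ratio × C_air``
    so that modelled wet deposition reproduces the rain-derived flux.
    """
    _require_nonnegative(rain_conc_ng_L=rain_conc_ng_L)
    if scavenging_ratio <= 0:
        raise DomainError(f"scavenging_ratio must be > 0, got {scavenging_ratio}")
    rain_ng_m3 = units.convert(rain_conc_ng_L, "ng/L", "g/m^3") / units.convert(
        1.0, "ng/m^3", "g/m^3"
    )
    return rain_ng_m3 / scavenging_ratio


@dataclass(frozen=True)
class LoadingBudget:
    """Named external influx terms [kg/yr].

    ``riverine_provenance`` records whether the riverine total was summed from
    per-river loads or supplied as a reported constant; the two are never
    silently reconciled.
    """

    wet_deposition_kg_yr: float
    riverine_total_kg_yr: float
    river_loads_kg_yr: dict[str, float] = field(default_factory=dict)
    seawater_inflow_kg_yr: float = 0.0
    include_seawater: bool = False
    precip_fraction_total_kg_yr: float = 0.0
    residual_unaccounted_kg_yr: float = 0.0
    riverine_provenance: str = "computed-from-rivers"

    def __post_init__(self) -> None:
        _require_nonnegative(
            wet_deposition_kg_yr=self.wet_deposition_kg_yr,
            riverine_total_kg_yr=self.riverine_total_kg_yr,
            seawater_inflow_kg_yr=self.seawater_inflow_kg_yr,
        )

    @property
    def external_total_kg_yr(self) -> float:
        """Total load entering the solver (seawater term only when toggled on)."""
        total = self.wet_deposition_kg_yr + self.riverine_total_kg_yr
        if self.include_seawater:
            total += self.seawater_inflow_kg_yr
        return total


def compute_loading_budget(
    site: SiteParametrization,
    inputs: HgInputs,
    params: ModelParameters,
    precipitation_share: float = DEFAULT_PRECIPITATION_SHARE,
) -> LoadingBudget:
    """Assemble every external loading term for a site.

    The per-river loads are always computed; if the inputs carry a reported
    riverine total it takes precedence and any disagreement beyond 1 % is
    logged as a warning.
    """
    wet = wet_deposition_load(inputs.rain_thg_ng_L, site.precipitation_mm_yr, site.area_km2)

    river_loads = {}
    for river in site.rivers:
        conc = inputs.river_thg_ng_L.get(river.name, 0.0)
        river_loads[river.name] = river_load(river.discharge_km3_yr, conc)
    river_sum = sum(river_loads.values())

    if inputs.riverine_total_override_kg_yr is not None:
        riverine = inputs.riverine_total_override_kg_yr
        provenance = inputs.riverine_provenance
        if river_sum > 0 and abs(river_sum - riverine) > 0.01 * max(riverine, 1e-12):
            logger.warning(
                "riverine total %.1f kg/yr (%s) differs from the per-river sum "
                "%.1f kg/yr; keeping the provided total",
                riverine,
                provenance,
                river_sum,
            )
    else:
        riverine = river_sum
        provenance = "computed-from-rivers"

    seawater = river_load(site.seawater_inflow_km3_yr, inputs.seawater_thg_ng_L)
    total_implied = total_influx_from_precip_fraction(wet, precipitation_share)
    residual = unaccounted_residual(total_implied, wet, riverine)

    return LoadingBudget(
        wet_deposition_kg_yr=wet,
        riverine_total_kg_yr=riverine,
        river_loads_kg_yr=river_loads,
        seawater_inflow_kg_yr=seawater,
        include_seawater=params.include_seawater_inflow_load,
        precip_fraction_total_kg_yr=total_implied,
        residual_unaccounted_kg_yr=residual,
        riverine_provenance=provenance,
    )
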