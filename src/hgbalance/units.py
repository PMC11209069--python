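"""Exact unit conversions between reporting units and canonical model units.

The model computes internally in grams, metres and years.  Field data and the
regional literature report concentrations in ng/L (water), ng/g dry weight
(sediment solids), ng/m^3 (air), flows in km^3/yr, loads in kg/yr, rainfall in
mm/yr and sedimentation in g/m^2/day.  Every supported unit maps onto one
canonical unit per dimension through an exact multiplicative factor, so all
conversions round-trip to machine precision.

One model year is 365 days (8760 hours) throughout.
"""

from __future__ import annotations

from .errors import UnitError

DAYS_PER_YEAR = 365.0
HOURS_PER_YEAR = 24.0 * DAYS_PER_YEAR

#: unit -> (canonical unit, factor such that value_canonical = value * factor)
_UNIT_TABLE: dict[str, tuple[str, float]] = {
    # aqueous / gaseous mass concentration (canonical g/m^3)
    "g/m^3": ("g/m^3", 1.0),
    "mg/L": ("g/m^3", 1.0),
    "ug/L": ("g/m^3", 1e-3),
    "ng/L": ("g/m^3", 1e-6),
    "g/L": ("g/m^3", 1e3),
    "ng/m^3": ("g/m^3", 1e-9),
    "ug/m^3": ("g/m^3", 1e-6),
    # solids mass fraction (canonical g/g)
    "g/g": ("g/g", 1.0),
    "ng/g": ("g/g", 1e-9),
    "ug/g": ("g/g", 1e-6),
    "mg/kg": ("g/g", 1e-6),
    # solid-water partition coefficient (canonical m^3/g)
    "m^3/g": ("m^3/g", 1.0),
    "L/g": ("m^3/g", 1e-3),
    "L/kg": ("m^3/g", 1e-6),
    # volumetric flow (canonical m^3/yr)
    "m^3/yr": ("m^3/yr", 1.0),
    "km^3/yr": ("m^3/yr", 1e9),
    # area (canonical m^2)
    "m^2": ("m^2", 1.0),
    "km^2": ("m^2", 1e6),
    # length / depth (canonical m)
    "m": ("m", 1.0),
    "mm": ("m", 1e-3),
    "cm": ("m", 1e-2),
    "km": ("m", 1e3),
    # precipitation / piston velocity (canonical m/yr)
    "m/yr": ("m/yr", 1.0),
    "mm/yr": ("m/yr", 1e-3),
    "m/h": ("m/yr", HOURS_PER_YEAR),
    "m/day": ("m/yr", DAYS_PER_YEAR),
    # mass rate (canonical g/yr)
    "g/yr": ("g/yr", 1.0),
    "kg/yr": ("g/yr", 1e3),
    "t/yr": ("g/yr", 1e6),
    # areal solids flux (canonical g/m^2/yr)
    "g/m^2/yr": ("g/m^2/yr", 1.0),
    "g/m^2/day": ("g/m^2/yr", DAYS_PER_YEAR),
    # solids density (canonical g/m^3)
    "g/cm^3": ("g/m^3(solid)", 1e6),
    "kg/m^3": ("g/m^3(solid)", 1e3),
    "g/m^3(solid)": ("g/m^3(solid)", 1.0),
    # dimensionless / pass-through
    "fraction": ("fraction", 1.0),
    "dimensionless": ("dimensionless", 1.0),
    "degC": ("degC", 1.0),
    "m/s": ("m/s", 1.0),
}


def canonical_unit(unit: str) -> str:
    """Return the canonical unit for ``unit``; raise :class:`UnitError` if unknown."""
    try:
        return _UNIT_TABLE[unit][0]
    except KeyError:
        raise UnitError(f"unknown unit {unit!r}") from None


def convert(value: float, src: str, dst: str) -> float:
    """Convert ``value`` from unit ``src`` to unit ``dst``.

    Raises :class:`UnitError` when either unit is unknown or the two units
    measure different dimensions.
    """
    try:
        canon_src, f_src = _UNIT_TABLE[src]
    except KeyError:
        raise UnitError(f"unknown unit {src!r}") from None
    try:
        canon_dst, f_dst = _UNIT_TABLE[dst]
    except KeyError:
        raise UnitError(f"unknown unit {dst!r}") from None
    if canon_src != canon_dst:
        raise UnitError(f"cannot convert {src!r} to {dst!r}: incompatible dimensions")
    if src == dst:
        return value
    return value * (f_src / f_dst)


def compatible(src: str, dst: str) -> bool:
    """True if the two units share a dimension (conversion is possible)."""
    try:
        return canonical_unit(src) == canonical_unit(dst)
    except UnitError:
        return False
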