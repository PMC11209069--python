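"""Flux budget assembly, closure diagnostics, residence time and literature comparison."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .config import ModelParameters, SiteParametrization
from .core import (
    EXTERNAL_EFFLUXES,
    EXTERNAL_INFLUXES,
    INTERNAL_PROCESSES,
    PROCESS_COMPARTMENT,
    SteadyStateSolution,
    apply_species_multipliers,
)
from .errors import DomainError, UnitError

#: processes a structurally complete budget must contain
REQUIRED_PROCESSES = ("wet_deposition", "riverine", "outflow", "net_evasion", "burial")


@dataclass(frozen=True)
class FluxRecord:
    process: str
    direction: str  # "in", "out" or "internal"
    species: str  # "tHg", "Hg0", "MeHg" or "residual"
    kg_yr: float


@dataclass(frozen=True)
class FluxBudget:
    """Ordered flux records with closure totals.

    Totals are computed over the total-mercury rows of external processes;
    species rows are proportional splits and internal exchanges cancel by
    construction.
    """

    records: tuple[FluxRecord, ...]
    total_in_kg_yr: float
    total_out_kg_yr: float
    closure_residual_kg_yr: float

    @property
    def closure_residual_relative(self) -> float:
        if self.total_in_kg_yr == 0.0:
            return 0.0
        return self.closure_residual_kg_yr / self.total_in_kg_yr

    def processes(self) -> set[str]:
        return {r.process for r in self.records}

    @classmethod
    def from_records(cls, records: Iterable[FluxRecord]) -> "FluxBudget":
        records = tuple(records)
        total_in = sum(r.kg_yr for r in records if r.direction == "in" and r.species == "tHg")
        total_out = sum(r.kg_yr for r in records if r.direction == "out" and r.species == "tHg")
        return cls(
            records=records,
            total_in_kg_yr=total_in,
            total_out_kg_yr=total_out,
            closure_residual_kg_yr=total_in - total_out,
        )

    @classmethod
    def from_terms(
        cls, inflows: dict[str, float], outflows: dict[str, float]
    ) -> "FluxBudget":
        """Budget from bare named terms (e.g. published rounded values), tHg only."""
        records = [FluxRecord(p, "in", "tHg", v) for p, v in inflows.items()]
        records += [FluxRecord(p, "out", "tHg", v) for p, v in outflows.items()]
        return cls.from_records(records)


def build_flux_budget(solution: SteadyStateSolution, params: ModelParameters) -> FluxBudget:
    """Flux table of a solution as ordered records, with per-species splits."""
    records: list[FluxRecord] = []
    for process in EXTERNAL_INFLUXES + EXTERNAL_EFFLUXES + INTERNAL_PROCESSES:
        signed = solution.flux_table[process]
        direction = (
            "in" if process in EXTERNAL_INFLUXES
            else "out" if process in EXTERNAL_EFFLUXES
            else "internal"
        )
        magnitude = abs(signed) if direction != "internal" else signed
        records.append(FluxRecord(process, direction, "tHg", magnitude))
        split = apply_species_multipliers(
            magnitude, params.species_ratios, PROCESS_COMPARTMENT[process]
        )
        records.extend(FluxRecord(process, direction, sp, v) for sp, v in split.items())
    return FluxBudget.from_records(records)


@dataclass(frozen=True)
class ClosureReport:
    residual_kg_yr: float
    residual_relative: float
    tolerance: float
    passed: bool
    structural_ok: bool
    missing_processes: tuple[str, ...] = ()


def closure_check(budget: FluxBudget, tolerance: float = 1e-6) -> ClosureReport:
    """Check mass closure of a budget at a relative tolerance.

    Use the default tight tolerance for solver output; a looser one (0.5 %)
    absorbs rounding when the terms are published values quoted to 0.1 kg/yr.
    A budget missing any required process fails structurally regardless of the
    residual.
    """
    missing = tuple(p for p in REQUIRED_PROCESSES if p not in budget.processes())
    structural_ok = not missing
    rel = abs(budget.closure_residual_relative)
    return ClosureReport(
        residual_kg_yr=budget.closure_residual_kg_yr,
        residual_relative=budget.closure_residual_relative,
        tolerance=tolerance,
        passed=structural_ok and rel <= tolerance,
        structural_ok=structural_ok,
        missing_processes=missing,
    )


def residence_time(
    solution: SteadyStateSolution,
    site: Optional[SiteParametrization] = None,
    params: Optional[ModelParameters] = None,
) -> float:
    """Residence time [yr] of mercury loadings: system inventory over total efflux.

    The inventory is the water-column burden plus the active sediment-layer
    burden (concentration times layer dry mass).  Inventories are recomputed
    from ``site``/``params`` when given, otherwise taken from the solution.
    """
    if solution.total_efflux_kg_yr <= 0:
        raise DomainError("residence time is undefined at zero total efflux")
    if site is not None and params is not None:
        inv_water = (
            solution.water_thg_ng_L * 1e-6 * site.water_volume_m3 / 1e3
        )  # ng/L -> g/m3, g -> kg
        inv_sed = (
            solution.sediment_thg_ng_g * 1e-9 * params.sediment_dry_mass_m2() * site.area_m2 / 1e3
        )
    else:
        inv_water = solution.inventories_kg["water"]
        inv_sed = solution.inventories_kg["sediment"]
    return (inv_water + inv_sed) / solution.total_efflux_kg_yr


# --------------------------------------------------------------------------
# Literature comparison
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LiteratureRecord:
    """A reported concentration (or range) for a region and matrix."""

    region: str
    matrix: str  # "water" (ng/L) or "sediment" (ng/g dw)
    low: float
    high: float
    reference: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.matrix not in ("water", "sediment"):
            raise UnitError(f"matrix must be 'water' or 'sediment', got {self.matrix!r}")
        if self.low > self.high:
            raise DomainError("range low must be <= high")


#: reported Sea-of-Azov-region concentrations (water ng/L, sediment ng/g dw)
AZOV_LITERATURE: tuple[LiteratureRecord, ...] = (
    LiteratureRecord("Taganrog Bay", "water", 100.0, 100.0, "regional survey (a)"),
    LiteratureRecord("Taganrog Bay", "water", 260.0, 260.0, "regional survey (b)"),
    LiteratureRecord("Sea of Azov (offshore)", "water", 10.0, 10.0, "Korablina et al. 2018"),
    LiteratureRecord(
        "Sea of Azov (offshore)", "sediment", 100.0, 300.0, "Korablina et al. 2018",
        note="lower bound reported as '<100'",
    ),
    LiteratureRecord(
        "Sea of Azov (offshore)", "sediment", 25.0, 280.0, "Kuznetsov et al.",
        note="mean 67",
    ),
    LiteratureRecord("Sea of Azov (offshore)", "water", 170.0, 690.0, "1986-1992 average"),
    LiteratureRecord("Sea of Azov (offshore)", "water", 160.0, 520.0, "1993-2005 average"),
    LiteratureRecord("Syvash Lake", "water", 200.0, 600.0, "regional survey"),
    LiteratureRecord("Syvash Lake", "sediment", 13.8, 13.8, "regional survey"),
    LiteratureRecord("Don River mouth", "sediment", 20_000.0, 1_100_000.0, "regional survey"),
    LiteratureRecord("Temryuk port (Kuban mouth)", "sediment", 149_000.0, 149_000.0, "regional survey"),
)


def compare_to_literature(
    solution: SteadyStateSolution,
    records: Iterable[LiteratureRecord] = AZOV_LITERATURE,
) -> pd.DataFrame:
    """Tabulate the modelled concentrations against reported values.

    For each record: the modelled value in the record's matrix, the reported
    value or range, an inside-range flag and the modelled/reported ratio
    (midpoint for ranges).  No aggregation beyond that.
    """
    rows = []
    for rec in records:
        modelled = (
            solution.water_thg_ng_L if rec.matrix == "water" else solution.sediment_thg_ng_g
        )
        mid = 0.5 * (rec.low + rec.high)
        if modelled < rec.low:
            status = "below"
        elif modelled > rec.high:
            status = "above"
        else:
            status = "inside"
        rows.append(
            {
                "region": rec.region,
                "matrix": rec.matrix,
                "unit": "ng/L" if rec.matrix == "water" else "ng/g dw",
                "reported_low": rec.low,
                "reported_high": rec.high,
                "modelled": modelled,
                "status": status,
                "ratio_to_reported": modelled / mid if mid > 0 else float("nan"),
                "reference": rec.reference,
                "note": rec.note,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Serialisation
# --------------------------------------------------------------------------

def budget_to_csv(budget: FluxBudget, path: str | Path) -> None:
    """Write the budget as CSV: full-precision values plus a one-decimal column."""
    df = pd.DataFrame([asdict(r) for r in budget.records])
    df["kg_yr_printed"] = df["kg_yr"].round(1)
    df["kg_yr"] = df["kg_yr"].map(repr)  # shortest exact representation
    df.to_csv(path, index=False)


def budget_from_csv(path: str | Path) -> FluxBudget:
    """Re-read a budget CSV; reproduces the records exactly (full-precision column)."""
    df = pd.read_csv(path, float_precision="round_trip")
    records = [
        FluxRecord(row.process, row.direction, row.species, float(row.kg_yr))
        for row in df.itertuples()
    ]
    return FluxBudget.from_records(records)


def solution_to_json(solution: SteadyStateSolution, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(solution), indent=2, sort_keys=True))
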