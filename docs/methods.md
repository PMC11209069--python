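# Methods

## Model

The balance treats the water body as one well-mixed water column over one
active sediment layer, with the atmosphere as a prescribed boundary (a fixed
gaseous-elemental-mercury concentration; the model never solves an air
compartment). This is the aquivalence variant of the fugacity framework:
mercury has no useful vapour-pressure-based fugacity in water, so the
water-referenced equilibrium criterion replaces it, and in practice the model
works directly with concentrations and empirical partition coefficients —
each phase capacity ratio (Z-value ratio) is realised as a measurable
coefficient (K_d for solids–water, the scavenging ratio for rain–air).

Each transport process is a D-value, a conductance such that flux = D ×
concentration. On a total-mercury basis:

| process | conductance | acts on |
| --- | --- | --- |
| outflow | Q_out [m³/yr] | total water conc. C_w [g/m³] |
| net gas evasion | k_vol · A · f_Hg0 · f_diss [m³/yr] | C_w |
| gross settling | S_g · K_d · f_diss [m³/yr-equivalent] | C_w |
| resuspension | S_r [g dry/yr] | sediment conc. C_s [g/g dw] |
| burial | S_b = S_g − S_r [g dry/yr] | C_s |
| porewater diffusion (optional, default 0) | D_diff [m³/yr] | dissolved conc. |

with f_diss = 1/(1 + K_d·TSS) the dissolved fraction and f_Hg0 the elemental
share of total mercury in water. Steady state is the 2×2 linear system

```
(Q_out + D_ev + S_g K_d f_diss) C_w − S_r C_s = L
 S_g K_d f_diss C_w − (S_r + S_b) C_s        = 0
```

solved with a direct linear solve; a non-positive determinant with a nonzero
load raises an explicit no-steady-state error rather than returning
non-physical values. The sediment equation implies C_s equals the
concentration on settling particles (K_d f_diss C_w expressed per gram), so
the effective water-column loss through the sediment route is burial only —
resuspension returns the rest.

Species (Hg⁰, MeHg, residual = tHg − Hg⁰ − MeHg) are handled with the
constant-ratio multiplier scheme: per-compartment species fractions are fixed,
every species rate is that fraction of the total rate, and the combined
multiplier R_tot = 1 + ΣR_i reproduces a consistent multi-species balance from
the single total-mercury solve. Consequence: the total-mercury budget depends
on the species ratios only through f_Hg0 in the evasion conductance; the
MeHg/residual split affects reported breakdowns, never the budget.

## Assumptions

- hydrodynamic and chemical steady state; no seasonality, no spatial
  gradients (bays and river-mouth hotspots are outside scope by design);
- linear sorption with a single K_d for total mercury on suspended solids;
- reported evasion is *net*: gross air-to-water absorption is folded into the
  net piston velocity (the reported budget closes without a separate
  absorption term, which fixes this interpretation);
- evaporation removes water but no mercury (Hg⁰ loss is inside net evasion);
- the atmospheric compartment is gaseous elemental mercury only;
  particulate-bound atmospheric mercury is not modelled.

## Parameters and defaults (Sea of Azov)

Site geometry, hydrology and particle dynamics are regional literature
values: area 39,000 km², mean depth 7 m, precipitation 397 mm/yr, TSS
19.1 mg/L, sedimentation 1.66 g/m²/day with 64 % resuspension, Don
22 km³/yr @ 520 ng/L, Kuban 11 km³/yr @ 10 ng/L, rain 240 ng/L, air
6.0 ng/m³.

The riverine mercury total is carried as the reported constant 9059.7 kg/yr
(provenance `reported-total`): the per-river product of the reported
concentrations and discharges gives 11,550 kg/yr instead, the difference
cannot be reconstructed from the available inputs, and the package therefore
keeps both paths and logs a warning rather than reconciling them. The
reported 28 % precipitation share converts the wet load into an implied total
influx; the residual against the quantified terms (~495 kg/yr) is reported as
unaccounted. The Black-Sea inflow load (37 km³/yr × 9.5 ng/L ≈ 351.5 kg/yr)
is computed but excluded from the default budget — it is absent from the
closed reported budget — behind the `include_seawater_inflow_load` toggle.

Process constants are *calibrated reconstructions*: the source model's
internal values are unpublished, but each is exactly recoverable from the
reported steady state because every forward relation is a product.
`calibrate_parameters` derives, and `soa_fixture()` regenerates at call time:

- K_d = C_s/(C_w − C_s·TSS) ≈ 9.69 L/g (from 55.6 ng/g, 6.8 ng/L, 19.1 mg/L);
- Q_out = outflow flux / C_w ≈ 54.35, reported as 54.4 km³/yr (0.1 km³/yr,
  the precision of the reported 53–55 km³/yr water-balance range);
- net-evasion piston velocity k_vol = evasion flux/(C_w·A·f_Hg0·f_diss) ≈
  0.30 m/h on the dissolved-Hg⁰ basis with f_Hg0 = 0.02 — consistent with a
  volatilisation coefficient raised for a large, windy (7.5–9 m/s) surface;
- scavenging ratio = C_rain/C_air = 40,000 (240 ng/L vs 6.0 ng/m³).

Species-ratio defaults (water 2 % Hg⁰ / 5 % MeHg; sediment 1 % MeHg; air
100 % Hg⁰) are placeholders exposed in configuration; only f_Hg0(water)
enters the budget. The active sediment layer (0.03 m, porosity 0.75, solids
density 2.4 g/cm³ → 1.8·10⁴ g dry/m²) is a conventional mixing-layer
parametrisation chosen for consistency of the inventory-based residence time;
it affects inventories and the oracle's sediment timescale, never the steady
state.

One model year is 365 days (8760 h) in all conversions; internal units are
g, m³, yr, with exact factor tables for all I/O units (round-trip tested).

## Residence time

τ = (water inventory + active-sediment inventory) / total efflux — the
standard turnover definition (the inventory-over-throughput method used for
lake mercury budgets). With the defaults above the Sea-of-Azov value is
≈ 3.2 yr, dominated by the sediment burden (~39,000 kg vs ~1,860 kg in
water). τ is invariant under uniform load scaling (linearity) and decreases
with the evasion velocity.

## Synthetic sites and the oracle

The generator emulates the structure the model assumes — shallow well-mixed
water over an active sediment layer, riverine plus wet-deposition loading,
three loss pathways — with known ground truth; it does not emulate spatial
heterogeneity, seasonality, or measurement error, so passing tests establish
the internal correctness of the solver and calibration, not fidelity to any
real survey. Concentration-like quantities, K_d and rates are log-uniform
(the regional literature spans orders of magnitude: 10–690 ng/L water,
13.8–1.1·10⁶ ng/g sediment); fractions are uniform. The outflow is sampled
as a specific drainage velocity (0.5–5 m/yr) times the area, keeping the
water-column and sediment turnover times within a few orders of magnitude —
the regime where a fixed-step explicit integrator is a sound oracle. All
draws come from one `numpy` Generator per scenario seed; no global state.

The oracle integrates dM/dt = influx − Σ D·C with explicit Euler steps of
0.1 × the fastest compartment turnover time (numba-compiled), declaring
convergence when both compartments' net rates fall below 10⁻¹⁰ × the external
load — a flux-residual criterion, chosen over per-step state change because
the latter can trigger prematurely on slow sediment modes. Across 100 seeded
scenarios the closed-form solver agrees with the oracle to better than 0.1 %
in concentrations and external fluxes (typically ~10⁻⁸).

Parameter recovery: hiding K_d, k_vol or the scavenging ratio and inverting
the noise-free synthetic observables recovers them to machine/rounding
precision (the inversions are exact); with 1 % multiplicative observation
noise the median relative error stays of order 1 % (no amplification in the
realistic regime).

## Numerical and design choices

- Closed-form (direct) solve, no iteration; singular systems raise.
- Degenerate inputs: zero area/depth are validation errors; K_d = 0 gives a
  pure-dilution water column with an inert (zero-concentration) sediment;
  zero load yields the zero state for both solver and oracle.
- Budget closure tolerances: 10⁻⁶ relative (default) for solver output —
  actual residuals are at machine precision — and 0.5 % when checking
  published terms quoted to 0.1 kg/yr.
- The two reported sediment figures (55.6 and 55.7 ng/g dw in different parts
  of the source inventory) are treated as rounding of one underlying value;
  the calibration targets 55.6.
- Budget CSVs carry a shortest-exact-representation value column (re-read
  reproduces the budget bit-for-bit) plus a one-decimal display column.

## Limitations

Single-box resolution cannot represent the strong observed gradients
(Taganrog Bay, river mouths exceed the basin average by orders of magnitude);
methylation/demethylation kinetics are replaced by fixed species ratios;
legacy sediment contamination below the active layer is invisible to the
steady state; all calibrated constants inherit the uncertainty of the
reported budget they are derived from.
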